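"""Parent-offspring detection from opposing-homozygote counts.

A locus where one individual is homozygous reference and the other homozygous
alternate is a pedigree inconsistency: Mendelian transmission forbids it for
a true parent-offspring pair, so error-free pairs score zero and real pairs
score only as high as the genotyping error rate allows.  Unrelated pairs
score at the Hardy-Weinberg background rate, so the all-pairs distribution of
per-locus inconsistency rates provides an empirical null; putative
parent-offspring pairs are low-side outliers below median - k * MAD.

Full siblings also depress the count, so flagged pairs should be read as
"parent-offspring-like"; the synthetic-data generator can plant full sibs to
demonstrate the ambiguity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import NamedTuple

import numpy as np
import pandas as pd

from .snp_data import MISSING, GenotypeMatrix, InputError

logger = logging.getLogger("otukit")


class OpposingHomozygotes(NamedTuple):
    count: int
    loci_compared: int


def opposing_homozygote_count(gm: GenotypeMatrix, ind_a: str,
                              ind_b: str) -> OpposingHomozygotes:
    """Count loci where the pair is {hom-ref, hom-alt}; missing loci skipped."""
    ia, ib = gm.index_of(ind_a), gm.index_of(ind_b)
    a, b = gm.genotypes[ia], gm.genotypes[ib]
    both = (a != MISSING) & (b != MISSING)
    opposing = ((a == 0) & (b == 2)) | ((a == 2) & (b == 0))
    return OpposingHomozygotes(int((opposing & both).sum()), int(both.sum()))


@dataclass
class KinshipScan:
    pairs: pd.DataFrame  # id_a, id_b, count, loci_compared, rate, score
    median_rate: float
    mad_rate: float

    def flagged(self, threshold_mads: float = 5.0) -> pd.DataFrame:
        """Low-side outliers: rate < median - k * MAD.

        With MAD = 0 (all rates equal) nothing can be flagged; a warning is
        emitted and an empty frame returned.
        """
        if self.mad_rate == 0:
            warnings.warn("opposing-homozygote rates have zero MAD; "
                          "no outliers can be flagged", stacklevel=2)
            return self.pairs.iloc[0:0]
        cut = self.median_rate - threshold_mads * self.mad_rate
        return self.pairs[self.pairs["rate"] < cut].reset_index(drop=True)


def pairwise_inconsistency_null(gm: GenotypeMatrix) -> KinshipScan:
    """Opposing-homozygote counts and rates for all C(n, 2) pairs.

    The null centre/scale are the median and the normalized MAD (scaled by
    1.4826 so it estimates the standard deviation for near-normal rates) of
    the per-pair rates; the standardized score is (rate - median) / MAD.
    """
    if gm.n_individuals < 3:
        raise InputError("need at least 3 individuals for an all-pairs null")
    g = gm.genotypes
    hom_ref = (g == 0).astype(np.float64)
    hom_alt = (g == 2).astype(np.float64)
    called = (g != MISSING).astype(np.float64)
    counts = hom_ref @ hom_alt.T + hom_alt @ hom_ref.T
    compared = called @ called.T
    ids = gm.individual_ids
    rows = []
    for i, j in combinations(range(gm.n_individuals), 2):
        c, m = counts[i, j], compared[i, j]
        rows.append((ids[i], ids[j], int(c), int(m), c / m if m > 0 else np.nan))
    df = pd.DataFrame(rows, columns=["id_a", "id_b", "count", "loci_compared", "rate"])
    median = float(np.nanmedian(df["rate"]))
    mad = 1.4826 * float(np.nanmedian(np.abs(df["rate"] - median)))
    df["score"] = (df["rate"] - median) / mad if mad > 0 else np.nan
    return KinshipScan(df, median, mad)


def detect_parent_offspring(scan: KinshipScan,
                            threshold_mads: float = 5.0) -> pd.DataFrame:
    """Flag putative parent-offspring pairs as low-side rate outliers."""
    return scan.flagged(threshold_mads)
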