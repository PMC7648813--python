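"""Expected heterozygosity per population and pairwise randomization tests.

He = mean over callable loci of 2p(1-p) is used as a relative measure of
genetic diversity.  Differences between populations are tested by randomly
reassigning the pooled individuals to two groups of the original sizes and
recomputing |delta He| each replicate; the p-value uses the add-one rule so
it is never exactly zero.  The randomization unit is the individual, which
preserves within-individual genotype structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .snp_data import MISSING, ConfigurationError, GenotypeMatrix, InputError


def _pop_rows(gm: GenotypeMatrix, population: str) -> np.ndarray:
    rows = np.asarray([p == population for p in gm.populations])
    if not rows.any():
        raise InputError(f"population '{population}' has no individuals")
    return rows


def _he_from_counts(alt_sum: np.ndarray, called_n: np.ndarray,
                    unbiased: bool) -> float:
    """Mean 2p(1-p) over loci with called_n > 0 (NaN-safe vectorized core)."""
    callable_ = called_n > 0
    if not callable_.any():
        raise InputError("no callable loci in population")
    n = called_n[callable_].astype(float)
    p = alt_sum[callable_] / (2.0 * n)
    he = 2.0 * p * (1.0 - p)
    if unbiased:
        he = he * (2.0 * n) / np.maximum(2.0 * n - 1.0, 1.0)
    return float(he.mean())


def expected_heterozygosity(gm: GenotypeMatrix, population: str,
                            unbiased: bool = False) -> float:
    """He for one population: mean over callable loci of 2p(1-p).

    ``unbiased`` applies the small-sample 2n/(2n-1) correction per locus
    (off by default, matching common usage).
    """
    rows = _pop_rows(gm, population)
    g = gm.genotypes[rows]
    called = g != MISSING
    alt = np.where(called, g, 0).sum(axis=0)
    return _he_from_counts(alt, called.sum(axis=0), unbiased)


class HetTest(NamedTuple):
    delta_he: float
    pvalue: float
    replicates: int


def heterozygosity_randomization_test(gm: GenotypeMatrix, pop_a: str, pop_b: str,
                                      reps: int = 10000, seed=None,
                                      unbiased: bool = False) -> HetTest:
    """Two-sided randomization test of He difference between two populations.

    Individuals of A union B are randomly reassigned to groups of the original
    sizes; each replicate recomputes |He_A - He_B|.  p = (1 + #{replicate >=
    observed}) / (reps + 1).
    """
    if reps < 1:
        raise ConfigurationError(f"reps must be >= 1, got {reps}")
    rows_a = _pop_rows(gm, pop_a)
    rows_b = _pop_rows(gm, pop_b)
    sub = gm.genotypes[rows_a | rows_b]
    n_a = int(rows_a.sum())
    n_total = sub.shape[0]
    called = (sub != MISSING)
    alt = np.where(called, sub, 0).astype(float)
    calledf = called.astype(float)

    def delta(sel: np.ndarray) -> float:
        # sel: boolean (m, n_total) selection matrices for group A
        he = []
        for grp in (sel, ~sel):
            g = grp.astype(float)
            altsum = g @ alt
            n = g @ calledf
            with np.errstate(invalid="ignore", divide="ignore"):
                p = np.where(n > 0, altsum / (2 * n), np.nan)
            he.append(np.nanmean(2 * p * (1 - p), axis=1))
        return np.abs(he[0] - he[1])

    base_sel = np.zeros((1, n_total), dtype=bool)
    # rows of `sub` are A first then B in gm order; reconstruct A membership
    order = np.flatnonzero(rows_a | rows_b)
    base_sel[0] = rows_a[order]
    observed = float(delta(base_sel)[0])

    rng = np.random.default_rng(seed)
    exceed = 0
    chunk = max(1, int(2e6 // max(1, sub.size // n_total * 1)))
    chunk = min(chunk, 2000)
    done = 0
    while done < reps:
        m = min(chunk, reps - done)
        sel = np.zeros((m, n_total), dtype=bool)
        for r in range(m):
            sel[r, rng.permutation(n_total)[:n_a]] = True
        exceed += int((delta(sel) >= observed - 1e-15).sum())
        done += m
    pvalue = (1.0 + exceed) / (reps + 1.0)
    return HetTest(observed, float(pvalue), reps)


@dataclass
class HeterozygosityResult:
    per_population: pd.DataFrame  # population, He, n_loci, n_individuals
    pairwise: pd.DataFrame        # pop_a, pop_b, delta_he, pvalue, replicates


def heterozygosity_report(gm: GenotypeMatrix, reps: int = 10000, seed=None,
                          unbiased: bool = False) -> HeterozygosityResult:
    """He per population plus all pairwise randomization tests."""
    pops = sorted(set(gm.populations))
    rng = np.random.default_rng(seed)
    rows = []
    for pop in pops:
        mask = _pop_rows(gm, pop)
        g = gm.genotypes[mask]
        n_loci = int(((g != MISSING).sum(axis=0) > 0).sum())
        rows.append((pop, expected_heterozygosity(gm, pop, unbiased),
                     n_loci, int(mask.sum())))
    per_pop = pd.DataFrame(rows, columns=["population", "He", "n_loci",
                                          "n_individuals"])
    pair_rows = []
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            t = heterozygosity_randomization_test(
                gm, a, b, reps=reps, seed=rng.integers(2 ** 31), unbiased=unbiased)
            pair_rows.append((a, b, t.delta_he, t.pvalue, t.replicates))
    pairwise = pd.DataFrame(pair_rows, columns=["pop_a", "pop_b", "delta_he",
                                                "pvalue", "replicates"])
    return HeterozygosityResult(per_pop, pairwise)
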