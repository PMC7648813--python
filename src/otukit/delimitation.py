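"""Fixed-difference analysis and progressive amalgamation into diagnosable OTUs.

A fixed difference is a locus at which two populations share no alleles: each
population is fixed for a different allele.  Populations (or aggregations)
diagnosable by one or more fixed differences are candidate operational
taxonomic units (OTUs).  Small samples produce *apparent* fixed differences
by sampling error alone, so observed counts are tested against a simulated
false-positive null in which both samples are drawn from the pooled (panmictic)
allele-frequency profile.  Pairs with zero fixed differences, and pairs whose
count is not significantly above the false-positive expectation, are
progressively amalgamated.

Private alleles (an allele present in one population, absent in the other)
are counted per allele per locus; the private-allele count necessarily
includes the fixed-difference count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .snp_data import MISSING, ConfigurationError, GenotypeMatrix, InputError

# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------


@dataclass
class AlleleFrequencyTable:
    """Per-population, per-locus alternate-allele frequency and called count.

    ``freqs[i, l]`` is NaN where the locus is uncallable (n = 0) in
    population i.
    """

    populations: list
    freqs: np.ndarray   # n_pops x n_loci, NaN when uncallable
    counts: np.ndarray  # n_pops x n_loci called-individual counts

    def index_of(self, population: str) -> int:
        try:
            return self.populations.index(population)
        except ValueError:
            raise InputError(f"unknown population '{population}'") from None

    @property
    def n_loci(self) -> int:
        return self.freqs.shape[1]


def allele_frequencies(gm: GenotypeMatrix) -> AlleleFrequencyTable:
    """Alternate-allele frequency p = (het + 2*hom_alt) / (2n) per population."""
    if any(p in ("", None) for p in gm.populations):
        raise InputError("every individual must carry a population label")
    pops = sorted(set(gm.populations))
    labels = np.asarray(gm.populations)
    g = gm.genotypes
    called = gm.called()
    alt = np.where(called, g, 0).astype(float)
    freqs = np.full((len(pops), gm.n_loci), np.nan)
    counts = np.zeros((len(pops), gm.n_loci), dtype=int)
    for i, pop in enumerate(pops):
        rows = labels == pop
        n = called[rows].sum(axis=0)
        counts[i] = n
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[i] = np.where(n > 0, alt[rows].sum(axis=0) / (2.0 * n), np.nan)
    return AlleleFrequencyTable(pops, freqs, counts)


# ---------------------------------------------------------------------------
# Fixed differences
# ---------------------------------------------------------------------------


class FixedDiffCount(NamedTuple):
    count: int
    n_compared: int


def _fixed_mask(pa: np.ndarray, pb: np.ndarray, tolerance: float) -> np.ndarray:
    lo, hi = tolerance, 1.0 - tolerance
    return ((pa <= lo) & (pb >= hi)) | ((pa >= hi) & (pb <= lo))


def count_fixed_differences(aft: AlleleFrequencyTable, pop_a: str, pop_b: str,
                            tolerance: float = 0.0) -> FixedDiffCount:
    """Count loci fixed for different alleles in the two populations.

    With tolerance t, frequencies <= t count as fixed-reference and >= 1 - t
    as fixed-alternate (t = 0 is strict fixation).  Only loci callable in both
    populations enter the comparison; the denominator is returned alongside.
    """
    ia, ib = aft.index_of(pop_a), aft.index_of(pop_b)
    callable_both = ~np.isnan(aft.freqs[ia]) & ~np.isnan(aft.freqs[ib])
    if not callable_both.any():
        raise InputError(f"populations '{pop_a}' and '{pop_b}' share no callable loci")
    pa, pb = aft.freqs[ia, callable_both], aft.freqs[ib, callable_both]
    return FixedDiffCount(int(_fixed_mask(pa, pb, tolerance).sum()),
                          int(callable_both.sum()))


class FalsePositiveTest(NamedTuple):
    expected_fp_count: float
    pvalue: float
    observed: int


def false_positive_rate(aft: AlleleFrequencyTable, pop_a: str, pop_b: str,
                        n_a: int | None = None, n_b: int | None = None,
                        n_sim: int = 1000, seed=None,
                        tolerance: float = 0.0) -> FalsePositiveTest:
    """Simulated false-positive test for apparent fixed differences.

    Null: both samples come from one panmictic population whose per-locus
    allele frequency is the pooled (count-weighted) frequency of the pair.
    Each replicate draws n_a and n_b diploid genotypes per shared locus and
    counts apparent fixed differences.  Drawing the 2n alleles binomially and
    checking sample fixation is equivalent to a per-locus Bernoulli with the
    closed-form fixation probability, which is what is vectorized here.

    Returns the mean simulated count, the empirical p-value
    P(simulated >= observed), and the observed count.
    """
    if n_sim < 1:
        raise ConfigurationError(f"n_sim must be >= 1, got {n_sim}")
    ia, ib = aft.index_of(pop_a), aft.index_of(pop_b)
    both = ~np.isnan(aft.freqs[ia]) & ~np.isnan(aft.freqs[ib])
    if not both.any():
        raise InputError(f"populations '{pop_a}' and '{pop_b}' share no callable loci")
    na = int(n_a) if n_a is not None else max(1, int(round(aft.counts[ia, both].mean())))
    nb = int(n_b) if n_b is not None else max(1, int(round(aft.counts[ib, both].mean())))
    if na < 1 or nb < 1:
        raise ConfigurationError("sample sizes must be >= 1")
    pa, pb = aft.freqs[ia, both], aft.freqs[ib, both]
    ca, cb = aft.counts[ia, both], aft.counts[ib, both]
    pooled = (ca * pa + cb * pb) / (ca + cb)
    # P(sample frequency <= tol) and >= 1 - tol for Binomial(2n, pooled)/2n
    ka = np.floor(tolerance * 2 * na + 1e-12)
    kb = np.floor(tolerance * 2 * nb + 1e-12)
    lo_a = stats.binom.cdf(ka, 2 * na, pooled)
    hi_a = stats.binom.sf(2 * na - ka - 1, 2 * na, pooled)
    lo_b = stats.binom.cdf(kb, 2 * nb, pooled)
    hi_b = stats.binom.sf(2 * nb - kb - 1, 2 * nb, pooled)
    q = lo_a * hi_b + hi_a * lo_b
    q = np.clip(q, 0.0, 1.0)
    rng = np.random.default_rng(seed)
    observed = int(_fixed_mask(pa, pb, tolerance).sum())
    # replicate counts: sum of independent Bernoulli(q_l); chunk to bound memory
    sim_counts = np.zeros(n_sim)
    chunk = max(1, int(5e6 // max(1, q.size)))
    for start in range(0, n_sim, chunk):
        m = min(chunk, n_sim - start)
        u = rng.random((m, q.size))
        sim_counts[start:start + m] = (u < q).sum(axis=1)
    expected = float(sim_counts.mean())
    pvalue = float((sim_counts >= observed).mean())
    return FalsePositiveTest(expected, pvalue, observed)


# ---------------------------------------------------------------------------
# Progressive amalgamation
# ---------------------------------------------------------------------------


@dataclass
class FixedDiffResult:
    """Pairwise fixed-difference matrices over the input populations plus the
    final OTU partition.

    ``counts``/``percents`` are symmetric over populations; ``mean_n`` is the
    mean over shared loci of the total individuals scored (n_a + n_b);
    ``pvalues`` holds the false-positive-test p-value per pair; ``otus`` maps
    each population to its OTU label.
    """

    populations: list
    counts: np.ndarray
    percents: np.ndarray
    mean_n: np.ndarray
    pvalues: np.ndarray
    otus: dict
    merges: list = field(default_factory=list)

    @property
    def n_otus(self) -> int:
        return len(set(self.otus.values()))

    def matrix_dataframe(self) -> pd.DataFrame:
        """Table-3-style layout: percent FD below the diagonal, mean total
        individuals scored above it."""
        n = len(self.populations)
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                out[i, j] = self.percents[i, j] if i > j else self.mean_n[i, j]
        np.fill_diagonal(out, 0.0)
        return pd.DataFrame(out, index=self.populations, columns=self.populations)

    def otu_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"population": list(self.otus),
                             "otu": [self.otus[p] for p in self.otus]})


def _merged_aft(gm: GenotypeMatrix, partition: dict) -> AlleleFrequencyTable:
    relabelled = gm.with_populations(
        {i: partition[p] for i, p in zip(gm.individual_ids, gm.populations)})
    return allele_frequencies(relabelled)


def amalgamate_otus(gm: GenotypeMatrix, alpha: float = 0.05,
                    tolerance: float = 0.0, n_sim: int = 1000, seed=None,
                    exclude_individuals: Sequence[str] = ()) -> FixedDiffResult:
    """Progressively amalgamate populations into diagnosable OTUs.

    Phase 1 merges pairs with zero fixed differences (deterministic order:
    lowest count first, ties lexicographic), recomputing after each merge.
    Phase 2 tests the remaining pairs against the false-positive null and
    merges pairs with p-value > alpha, again smallest observed count first.
    Putative hybrid individuals should be passed in ``exclude_individuals``
    so they do not blur genuine fixed differences.
    """
    if exclude_individuals:
        gm = gm.drop_individuals(exclude_individuals)
    pops = sorted(set(gm.populations))
    if len(pops) < 2:
        raise InputError("need at least 2 populations to delimit")
    rng = np.random.default_rng(seed)
    partition = {p: p for p in pops}
    merges: list = []

    def cluster_names():
        return sorted(set(partition.values()))

    def pair_counts(aft):
        out = {}
        names = cluster_names()
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                out[(a, b)] = count_fixed_differences(aft, a, b, tolerance).count
        return out

    def merge(a: str, b: str, reason: str):
        new = "+".join(sorted(set(a.split("+")) | set(b.split("+"))))
        for p, c in partition.items():
            if c in (a, b):
                partition[p] = new
        merges.append((a, b, reason))

    # phase 1: zero fixed differences
    while True:
        aft = _merged_aft(gm, partition)
        zero = sorted((pair for pair, c in pair_counts(aft).items() if c == 0))
        if not zero:
            break
        merge(*zero[0], reason="zero_fixed_differences")

    # phase 2: counts not exceeding the false-positive rate
    while len(cluster_names()) > 1:
        aft = _merged_aft(gm, partition)
        candidates = []
        for (a, b), c in pair_counts(aft).items():
            test = false_positive_rate(aft, a, b, n_sim=n_sim,
                                       seed=rng.integers(2 ** 31),
                                       tolerance=tolerance)
            if test.pvalue > alpha:
                candidates.append((c, a, b))
        if not candidates:
            break
        candidates.sort()
        merge(candidates[0][1], candidates[0][2], reason="not_significant")

    # final matrices over the original populations
    aft0 = allele_frequencies(gm)
    n = len(pops)
    counts = np.zeros((n, n), dtype=int)
    percents = np.zeros((n, n))
    mean_n = np.zeros((n, n))
    pvalues = np.ones((n, n))
    for i, a in enumerate(pops):
        for j in range(i + 1, n):
            b = pops[j]
            fd = count_fixed_differences(aft0, a, b, tolerance)
            counts[i, j] = counts[j, i] = fd.count
            percents[i, j] = percents[j, i] = 100.0 * fd.count / fd.n_compared
            both = ~np.isnan(aft0.freqs[i]) & ~np.isnan(aft0.freqs[j])
            mean_n[i, j] = mean_n[j, i] = float(
                (aft0.counts[i, both] + aft0.counts[j, both]).mean())
            test = false_positive_rate(aft0, a, b, n_sim=n_sim,
                                       seed=rng.integers(2 ** 31),
                                       tolerance=tolerance)
            pvalues[i, j] = pvalues[j, i] = test.pvalue
    otu_names = {c: f"OTU_{k + 1}" for k, c in enumerate(cluster_names())}
    otus = {p: otu_names[partition[p]] for p in pops}
    return FixedDiffResult(pops, counts, percents, mean_n, pvalues, otus, merges)


# ---------------------------------------------------------------------------
# Private alleles
# ---------------------------------------------------------------------------


class PrivateAlleleCounts(NamedTuple):
    count_ab: int  # alleles private to A relative to B
    count_ba: int


def count_private_alleles(aft: AlleleFrequencyTable, pop_a: str,
                          pop_b: str) -> PrivateAlleleCounts:
    """Count alleles present in one population and absent in the other.

    Evaluated per allele per locus over loci callable in both populations:
    the alternate allele is private to A when p_A > 0 and p_B = 0; the
    reference allele when p_A < 1 and p_B = 1.  Fixed differences contribute
    one private allele to each direction.
    """
    ia, ib = aft.index_of(pop_a), aft.index_of(pop_b)
    both = ~np.isnan(aft.freqs[ia]) & ~np.isnan(aft.freqs[ib])
    if not both.any():
        raise InputError(f"populations '{pop_a}' and '{pop_b}' share no callable loci")
    pa, pb = aft.freqs[ia, both], aft.freqs[ib, both]
    ab = int(((pa > 0) & (pb == 0)).sum() + ((pa < 1) & (pb == 1)).sum())
    ba = int(((pb > 0) & (pa == 0)).sum() + ((pb < 1) & (pa == 1)).sum())
    return PrivateAlleleCounts(ab, ba)


@dataclass
class PrivateAlleleResult:
    populations: list
    counts: np.ndarray  # counts[i, j] = alleles private to pop i relative to pop j

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.populations,
                            columns=self.populations)


def private_allele_matrix(aft: AlleleFrequencyTable) -> PrivateAlleleResult:
    pops = list(aft.populations)
    n = len(pops)
    counts = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            ab, ba = count_private_alleles(aft, pops[i], pops[j])
            counts[i, j] = ab
            counts[j, i] = ba
    return PrivateAlleleResult(pops, counts)
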