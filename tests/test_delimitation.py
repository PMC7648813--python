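"""Fixed differences, false-positive testing, OTU amalgamation, private alleles."""

import numpy as np
import pytest

from otukit import MISSING, ConfigurationError, InputError
from otukit.delimitation import (AlleleFrequencyTable, allele_frequencies,
                                 amalgamate_otus, count_fixed_differences,
                                 count_private_alleles, false_positive_rate,
                                 private_allele_matrix)
from otukit.simulate import GroupSpec, SimConfig, simulate_populations

from conftest import make_gm


def aft_from_freqs(freqs, counts=None, pops=("A", "B")):
    """Construct an AlleleFrequencyTable directly from frequency rows."""
    f = np.asarray(freqs, dtype=float)
    c = (np.asarray(counts) if counts is not None
         else np.full(f.shape, 5, dtype=int))
    c = np.where(np.isnan(f), 0, c)
    return AlleleFrequencyTable(list(pops), f, c)


class TestAlleleFrequencies:
    def test_counting(self):
        gm = make_gm([[0], [1], [2]])
        aft = allele_frequencies(gm)
        assert aft.freqs[0, 0] == pytest.approx(0.5)
        assert aft.counts[0, 0] == 3

    def test_uncallable_locus_flagged_nan(self):
        gm = make_gm([[MISSING, 2], [MISSING, 2]])
        aft = allele_frequencies(gm)
        assert np.isnan(aft.freqs[0, 0])
        assert aft.freqs[0, 1] == pytest.approx(1.0)

    def test_unlabelled_individual_rejected(self):
        gm = make_gm([[0], [1]])
        gm.populations[0] = ""
        with pytest.raises(InputError, match="population label"):
            allele_frequencies(gm)


class TestFixedDifferences:
    def test_definitional_cases(self):
        aft = aft_from_freqs([[0.0], [1.0]])
        assert count_fixed_differences(aft, "A", "B").count == 1
        aft2 = aft_from_freqs([[0.25], [1.0]])
        assert count_fixed_differences(aft2, "A", "B").count == 0

    def test_five_locus_toy(self):
        # (0,1),(0,0),(1,1),(0.5,1),(1,0): fixed at loci 1 and 5
        aft = aft_from_freqs([[0, 0, 1, 0.5, 1], [1, 0, 1, 1, 0]])
        res = count_fixed_differences(aft, "A", "B")
        assert (res.count, res.n_compared) == (2, 5)

    def test_tolerance_relaxes_fixation(self):
        aft = aft_from_freqs([[0.04], [0.97]])
        assert count_fixed_differences(aft, "A", "B").count == 0
        assert count_fixed_differences(aft, "A", "B", tolerance=0.05).count == 1

    def test_matches_bruteforce_on_small_matrices(self):
        rng = np.random.default_rng(17)
        for trial in range(20):
            g = rng.integers(0, 3, (6, 10))
            g[rng.random(g.shape) < 0.15] = MISSING
            pops = ["A"] * 3 + ["B"] * 3
            gm = make_gm(g, pops=pops)
            aft = allele_frequencies(gm)
            # brute force: per-locus allele sets
            expected = 0
            compared = 0
            for j in range(10):
                a = [x for x in g[:3, j] if x != MISSING]
                b = [x for x in g[3:, j] if x != MISSING]
                if not a or not b:
                    continue
                compared += 1
                alleles_a = set()
                for x in a:
                    alleles_a |= {0} if x == 0 else {1} if x == 2 else {0, 1}
                alleles_b = set()
                for x in b:
                    alleles_b |= {0} if x == 0 else {1} if x == 2 else {0, 1}
                if not (alleles_a & alleles_b):
                    expected += 1
            res = count_fixed_differences(aft, "A", "B")
            assert (res.count, res.n_compared) == (expected, compared)


class TestFalsePositive:
    def test_single_locus_closed_form(self):
        # pooled p = 0.5, nA = nB = 1: P(apparent FD) = 2 * 0.25 * 0.25 = 0.125
        aft = aft_from_freqs([[0.0], [1.0]], counts=[[1], [1]])
        res = false_positive_rate(aft, "A", "B", n_a=1, n_b=1, n_sim=10000,
                                  seed=4)
        se = np.sqrt(0.125 * 0.875 / 10000)
        assert abs(res.expected_fp_count - 0.125) < 3 * se

    def test_monomorphic_pool_yields_zero(self):
        aft = aft_from_freqs([[0.0, 0.0], [0.0, 0.0]])
        res = false_positive_rate(aft, "A", "B", n_sim=200, seed=1)
        assert res.expected_fp_count == 0.0

    def test_extreme_observation_pvalue_bound(self):
        # many observed fixed differences, tiny sample-error null
        aft = aft_from_freqs([[0.0] * 20, [1.0] * 20],
                             counts=[[20] * 20, [20] * 20])
        res = false_positive_rate(aft, "A", "B", n_sim=500, seed=2)
        assert res.observed == 20
        assert res.pvalue <= 1 / 500

    def test_nsim_validation(self):
        aft = aft_from_freqs([[0.5], [0.5]])
        with pytest.raises(ConfigurationError):
            false_positive_rate(aft, "A", "B", n_sim=0)

    def test_expected_fp_decreases_with_sample_size(self):
        aft = aft_from_freqs([[0.4] * 50, [0.6] * 50],
                             counts=[[10] * 50, [10] * 50])
        exp = [false_positive_rate(aft, "A", "B", n_a=n, n_b=n, n_sim=3000,
                                   seed=9).expected_fp_count
               for n in (1, 3, 8)]
        assert exp[0] > exp[1] >= exp[2] - 3 * np.sqrt(max(exp[2], 1e-9) / 3000)


class TestPrivateAlleles:
    def test_one_sided_private(self):
        aft = aft_from_freqs([[0.5], [0.0]])
        assert count_private_alleles(aft, "A", "B") == (1, 0)

    def test_fixed_difference_counts_both_ways(self):
        aft = aft_from_freqs([[1.0], [0.0]])
        assert count_private_alleles(aft, "A", "B") == (1, 1)

    def test_shared_polymorphism_contributes_zero(self):
        aft = aft_from_freqs([[0.5], [0.5]])
        assert count_private_alleles(aft, "A", "B") == (0, 0)

    def test_private_at_least_fixed_on_random_matrices(self):
        rng = np.random.default_rng(33)
        for trial in range(15):
            g = rng.integers(0, 3, (10, 25))
            g[rng.random(g.shape) < 0.1] = MISSING
            gm = make_gm(g, pops=["A"] * 5 + ["B"] * 5)
            aft = allele_frequencies(gm)
            fd = count_fixed_differences(aft, "A", "B").count
            ab, ba = count_private_alleles(aft, "A", "B")
            assert ab >= fd and ba >= fd

    def test_matrix_layout(self):
        rng = np.random.default_rng(2)
        gm = make_gm(rng.integers(0, 3, (9, 30)),
                     pops=["A"] * 3 + ["B"] * 3 + ["C"] * 3)
        res = private_allele_matrix(allele_frequencies(gm))
        assert res.counts.shape == (3, 3)
        assert (np.diag(res.counts) == 0).all()


class TestAmalgamation:
    def test_identical_populations_merge(self):
        rng = np.random.default_rng(6)
        block = rng.integers(0, 3, (4, 30))
        g = np.vstack([block, block])  # two pops, identical genotypes
        gm = make_gm(g, pops=["A"] * 4 + ["B"] * 4)
        res = amalgamate_otus(gm, n_sim=100, seed=1)
        assert res.n_otus == 1
        assert res.merges[0][2] == "zero_fixed_differences"

    def test_order_independence_for_disjoint_zero_pairs(self):
        rng = np.random.default_rng(14)
        b1 = rng.integers(0, 3, (4, 40))
        b2 = np.where(b1 == 0, 2, np.where(b1 == 2, 0, 1))  # fully opposed
        g = np.vstack([b1, b1, b2, b2])
        pops = ["A"] * 4 + ["B"] * 4 + ["C"] * 4 + ["D"] * 4
        ids = [f"i{k}" for k in range(16)]
        for perm in (np.arange(16), np.arange(16)[::-1],
                     np.random.default_rng(0).permutation(16)):
            gm = make_gm(g[perm], pops=[pops[k] for k in perm],
                         ids=[ids[k] for k in perm])
            res = amalgamate_otus(gm, n_sim=100, seed=2)
            partition = {}
            for pop, otu in res.otus.items():
                partition.setdefault(otu, set()).add(pop)
            sets = {frozenset(s) for s in partition.values()}
            assert sets == {frozenset({"A", "B"}), frozenset({"C", "D"})}

    def test_small_sample_apparent_differences_merged_by_test(self):
        # two tiny samples (n=2, n=3) from one panmictic balanced pool show
        # apparent fixed differences at the rate the null simulation also
        # produces, so the significance phase amalgamates them
        cfg = SimConfig(groups=[GroupSpec("P", {"X": 2, "Y": 3},
                                          ("uniform", 0.3, 0.7))],
                        divergence={}, n_loci=600, seed=1, error_rate=0.0,
                        missing_rate=0.0, drift_sd=0.0)
        gm, _ = simulate_populations(cfg)
        aft = allele_frequencies(gm)
        observed = count_fixed_differences(aft, "X", "Y").count
        assert observed > 0  # sampling error alone fakes fixed differences
        res = amalgamate_otus(gm, n_sim=400, seed=3)
        assert res.n_otus == 1
        assert res.merges[-1][2] == "not_significant"

    def test_study_design_recovers_three_otus(self, study):
        gm, truth = study
        res = amalgamate_otus(gm, n_sim=300, seed=5,
                              exclude_individuals=list(truth.hybrid_class))
        assert res.n_otus == 3
        by_otu = {}
        for pop, otu in res.otus.items():
            by_otu.setdefault(otu, set()).add(pop)
        assert {frozenset(s) for s in by_otu.values()} == {
            frozenset({"Taravale", "Blackbraes"}),
            frozenset({"RedcliffeVale"}),
            frozenset({"Bendoc", "Wombat"})}

    def test_result_invariants(self, study):
        gm, truth = study
        res = amalgamate_otus(gm, n_sim=200, seed=8,
                              exclude_individuals=list(truth.hybrid_class))
        assert np.array_equal(res.counts, res.counts.T)
        assert (np.diag(res.counts) == 0).all()
        assert ((res.percents >= 0) & (res.percents <= 100)).all()
        assert set(res.otus) == set(res.populations)
        tab = res.matrix_dataframe()
        # upper triangle holds mean total individuals scored
        i, j = res.populations.index("Bendoc"), res.populations.index("Wombat")
        lo, hi = min(i, j), max(i, j)
        assert tab.iloc[lo, hi] == pytest.approx(res.mean_n[i, j])
        assert res.mean_n[i, j] <= 15  # Bendoc 9 + Wombat 6
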