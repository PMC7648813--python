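"""Genotype-matrix I/O and the staged quality-filter chain."""

import numpy as np
import pytest

from otukit import (MISSING, ConfigurationError, FilterConfig, GenotypeMatrix,
                    InputError, LocusMeta)
from otukit.snp_data import (DartEncoding, filter_by_locus_callrate,
                             filter_by_read_depth, filter_by_repeatability,
                             filter_individuals_by_callrate, read_dart_csv,
                             read_genotype_csv, read_vcf,
                             remove_monomorphic_loci, run_filter_pipeline,
                             select_one_snp_per_tag, write_dart_csv)
from otukit.simulate import (ArtifactSpec, default_study, inject_artifacts,
                             simulate_populations)

from conftest import make_gm


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestDartCsv:
    HEADER = "CloneID,SnpPosition,RepAvg,CallRate,ReadDepth,ind1,ind2\n"

    def test_direct_transcription(self, tmp_path):
        path = _write(tmp_path, "toy.csv", self.HEADER
                      + "c1,5,1.0,1.0,20,0,1\nc2,7,0.99,1.0,30,2,0\n")
        gm = read_dart_csv(path)
        assert gm.genotypes.tolist() == [[0, 2], [1, 0]]
        assert gm.individual_ids == ["ind1", "ind2"]
        assert gm.loci[0].clone_id == "c1" and gm.loci[1].rep_avg == 0.99

    def test_missing_token(self, tmp_path):
        path = _write(tmp_path, "toy.csv", self.HEADER
                      + "c1,5,1.0,1.0,20,-,1\n")
        gm = read_dart_csv(path)
        assert gm.genotypes[0, 0] == MISSING

    def test_unparseable_cell_becomes_missing(self, tmp_path):
        path = _write(tmp_path, "toy.csv", self.HEADER
                      + "c1,5,1.0,1.0,20,xyz,1\n")
        gm = read_dart_csv(path)
        assert gm.genotypes[0, 0] == MISSING

    def test_duplicate_individual_column(self, tmp_path):
        path = _write(tmp_path, "dup.csv",
                      "CloneID,SnpPosition,RepAvg,CallRate,ReadDepth,ind1,ind1\n"
                      "c1,5,1.0,1.0,20,0,1\n")
        with pytest.raises(InputError, match="duplicate"):
            read_dart_csv(path)

    def test_missing_metadata_column(self, tmp_path):
        path = _write(tmp_path, "bad.csv",
                      "CloneID,SnpPosition,CallRate,ReadDepth,ind1\nc1,5,1.0,20,0\n")
        with pytest.raises(ConfigurationError, match="rep_avg"):
            read_dart_csv(path)

    def test_roundtrip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, (4, 6))
        g[0, 0] = MISSING
        loci = [LocusMeta(f"c{j}", j, 0.991 + j / 1000, 0.9, 10.5 + j)
                for j in range(6)]
        gm = make_gm(g, loci=loci)
        path = tmp_path / "rt.csv"
        write_dart_csv(gm, path)
        back = read_dart_csv(path)
        assert np.array_equal(back.genotypes, gm.genotypes)
        assert back.individual_ids == gm.individual_ids
        assert back.loci == gm.loci


class TestVcf:
    VCF = ("##fileformat=VCFv4.2\n"
           '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
           "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
           "chr1\t100\t.\tA\tG\t.\t.\t.\tGT\t0/1\t1/1\n"
           "chr1\t200\t.\tC\tT\t.\t.\t.\tGT\t./.\t0/0\n"
           "chr1\t300\t.\tG\tA,T\t.\t.\t.\tGT\t0/1\t0/2\n")

    def test_gt_conventions_and_multiallelic_skip(self, tmp_path):
        path = _write(tmp_path, "toy.vcf", self.VCF)
        gm = read_vcf(path)
        assert gm.n_loci == 2  # triallelic record skipped
        assert gm.genotypes.tolist() == [[1, MISSING], [2, 0]]
        assert gm.loci[0].clone_id == "chr1:100"
        assert gm.loci[0].rep_avg is None

    def test_unknown_metadata_passes_filters(self, tmp_path):
        path = _write(tmp_path, "toy.vcf", self.VCF)
        gm = read_vcf(path)
        assert filter_by_read_depth(gm).n_loci == gm.n_loci
        assert filter_by_repeatability(gm).n_loci == gm.n_loci
        assert filter_by_read_depth(gm, strict=True).n_loci == 0

    def test_malformed_vcf_reports_line(self, tmp_path):
        path = _write(tmp_path, "bad.vcf",
                      "##fileformat=VCFv4.2\n#CHROM\tPOS\n" "chr1\t100\n")
        with pytest.raises(InputError, match="malformed VCF"):
            read_vcf(path)


def test_generic_csv_orientations(tmp_path):
    rows = "id,l1,l2\na,0,1\nb,2,-\n"
    path = _write(tmp_path, "g.csv", rows)
    gm = read_genotype_csv(path, orientation="individuals_as_rows")
    assert gm.genotypes.tolist() == [[0, 1], [2, MISSING]]
    cols = "locus,a,b\nl1,0,2\nl2,1,-\n"
    path2 = _write(tmp_path, "g2.csv", cols)
    gm2 = read_genotype_csv(path2, orientation="individuals_as_columns")
    assert np.array_equal(gm2.genotypes, gm.genotypes)


def test_invalid_genotype_values_rejected():
    with pytest.raises(InputError, match="invalid genotype"):
        make_gm([[0, 5]])


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


class TestSecondarySnps:
    def test_one_per_tag(self):
        loci = [LocusMeta("c1", 5, 0.99, 1, 20), LocusMeta("c1", 9, 1.0, 1, 20),
                LocusMeta("c2", 3, 0.995, 1, 20)]
        gm = make_gm([[0, 1, 2], [1, 1, 0]], loci=loci)
        out = select_one_snp_per_tag(gm)
        assert out.n_loci == 2
        # highest rep_avg wins within c1
        assert [l.snp_position for l in out.loci] == [9, 3]

    def test_tie_broken_by_position(self):
        loci = [LocusMeta("c1", 9, 1.0, 1, 20), LocusMeta("c1", 5, 1.0, 1, 20)]
        gm = make_gm([[0, 1]], loci=loci)
        assert select_one_snp_per_tag(gm).loci[0].snp_position == 5

    def test_unique_tags_identity(self):
        gm = make_gm([[0, 1, 2]])
        assert select_one_snp_per_tag(gm).n_loci == 3


class TestDepthFilter:
    def test_inclusive_bounds(self):
        loci = [LocusMeta(f"c{j}", 0, 1.0, 1, d)
                for j, d in enumerate((4, 5, 100, 101))]
        gm = make_gm([[0, 1, 2, 1]], loci=loci)
        out = filter_by_read_depth(gm)
        assert [l.read_depth for l in out.loci] == [5, 100]

    def test_identity(self):
        gm = make_gm([[0, 1]], read_depth=50.0)
        assert filter_by_read_depth(gm).n_loci == 2

    def test_inverted_bounds_error(self):
        gm = make_gm([[0]])
        with pytest.raises(ConfigurationError):
            filter_by_read_depth(gm, min_depth=100, max_depth=5)


class TestIndividualCallrate:
    def test_below_threshold_removed_at_boundary_kept(self):
        g = np.ones((3, 10), dtype=int)
        g[0, :6] = MISSING   # 40% called -> removed
        g[1, :5] = MISSING   # exactly 50% called -> retained (strict less-than)
        gm = make_gm(g)
        out = filter_individuals_by_callrate(gm)
        assert out.individual_ids == ["ind1", "ind2"]

    def test_complete_identity(self):
        gm = make_gm(np.ones((3, 4), dtype=int))
        assert filter_individuals_by_callrate(gm).n_individuals == 3


class TestMonomorphic:
    def test_examples(self):
        g = np.array([[0, 1, MISSING, 2],
                      [0, 1, MISSING, 2],
                      [0, 1, MISSING, 2]])
        out = remove_monomorphic_loci(make_gm(g))
        # all-ref removed, all-het kept, all-missing removed, all-alt removed
        assert out.n_loci == 1
        assert out.genotypes[:, 0].tolist() == [1, 1, 1]


class TestRepeatability:
    def test_threshold_strictness(self):
        loci = [LocusMeta("a", 0, 0.98, 1, 20), LocusMeta("b", 0, 0.99, 1, 20)]
        gm = make_gm([[0, 1]], loci=loci)
        out = filter_by_repeatability(gm)
        assert [l.clone_id for l in out.loci] == ["b"]

    def test_min_rep_zero_identity(self):
        gm = make_gm([[0, 1]], rep_avg=0.5)
        assert filter_by_repeatability(gm, min_rep=0).n_loci == 2


class TestLocusCallrate:
    def test_recomputed_rate_boundary(self):
        g = np.ones((20, 2), dtype=int)
        g[0, 0] = MISSING           # 19/20 = 0.95 -> retained
        g[:2, 1] = MISSING          # 18/20 = 0.90 -> removed
        out = filter_by_locus_callrate(make_gm(g))
        assert out.n_loci == 1

    def test_complete_identity(self):
        gm = make_gm(np.ones((4, 3), dtype=int))
        assert filter_by_locus_callrate(gm).n_loci == 3


FILTERS = [select_one_snp_per_tag, filter_by_read_depth,
           filter_individuals_by_callrate, remove_monomorphic_loci,
           filter_by_repeatability, filter_by_locus_callrate]


@pytest.mark.parametrize("filt", FILTERS, ids=lambda f: f.__name__)
def test_filter_idempotence(filt):
    rng = np.random.default_rng(42)
    g = rng.integers(0, 3, (12, 30))
    g[rng.random(g.shape) < 0.2] = MISSING
    loci = [LocusMeta(f"c{j // 2}", j % 2, float(rng.uniform(0.97, 1.0)), 0.9,
                      float(rng.uniform(2, 120))) for j in range(30)]
    gm = make_gm(g, loci=loci)
    once = filt(gm)
    twice = filt(once)
    assert np.array_equal(once.genotypes, twice.genotypes)
    assert once.loci == twice.loci and once.individual_ids == twice.individual_ids


class TestPipeline:
    def test_planted_violations_reconcile(self):
        # balanced-frequency base: no incidental monomorphic or low-callrate
        # loci, so the report must equal the planted counts exactly
        from otukit.simulate import GroupSpec, SimConfig
        cfg = SimConfig(groups=[GroupSpec("P", {"S": 20}, ("uniform", 0.3, 0.7))],
                        divergence={}, n_loci=300, seed=5, error_rate=0.0,
                        missing_rate=0.0, drift_sd=0.0)
        gm, truth = simulate_populations(cfg)
        spec = ArtifactSpec(n_secondary=7, n_bad_depth=5, n_monomorphic=4,
                            n_low_rep=6, n_low_callrate_loci=3,
                            n_bad_individuals=2)
        dirty, truth = inject_artifacts(gm, truth, spec, seed=1)
        filtered, report = run_filter_pipeline(dirty)
        removed = {s.name: s.loci_removed for s in report.stages}
        assert removed == {"one_snp_per_tag": 7, "read_depth": 5,
                           "individual_callrate": 0, "monomorphic": 4,
                           "repeatability": 6, "locus_callrate": 3}
        ind_removed = {s.name: s.individuals_removed for s in report.stages}
        assert ind_removed["individual_callrate"] == 2
        assert filtered.n_loci == gm.n_loci
        assert filtered.n_individuals == gm.n_individuals

    def test_clean_matrix_removes_nothing(self):
        g = np.array([[0, 1], [2, 1], [1, 0]])
        gm = make_gm(g)
        out, report = run_filter_pipeline(gm)
        assert all(s.loci_removed == 0 and s.individuals_removed == 0
                   for s in report.stages)

    def test_report_totals_reconcile(self, study):
        gm, _ = study
        out, report = run_filter_pipeline(gm)
        total_loci = sum(s.loci_removed for s in report.stages)
        total_ind = sum(s.individuals_removed for s in report.stages)
        assert report.initial_loci - total_loci == out.n_loci
        assert report.initial_individuals - total_ind == out.n_individuals
        remaining = [s.loci_remaining for s in report.stages]
        assert remaining == sorted(remaining, reverse=True)

    def test_report_serialization(self, tmp_path, study):
        gm, _ = study
        _, report = run_filter_pipeline(gm)
        report.to_csv(tmp_path / "r.csv")
        text = report.to_json(tmp_path / "r.json")
        assert (tmp_path / "r.csv").exists() and "stages" in text
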