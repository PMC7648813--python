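"""Config-driven end-to-end orchestration of the full analysis.

Stage order mirrors the analysis workflow: filter -> ordinate -> hybrids ->
delimit (with hybrid-flagged individuals excluded) -> diversity ->
relatedness -> morphometrics.  A single global seed is forked into named
per-stage streams so toggling one stage never perturbs another's randomness.
Every emitted file is listed in a JSON manifest with a checksum.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import delimitation, diversity, hybridization, morphometrics, ordination
from . import relatedness as kin
from . import simulate, snp_data
from .snp_data import ConfigurationError, FilterConfig, GenotypeMatrix

logger = logging.getLogger("otukit")

STAGES = ("filter", "ordination", "hybrids", "delimitation", "diversity",
          "relatedness", "morphometrics")


@dataclass
class RunConfig:
    """Top-level run configuration (YAML-loadable).

    Exactly one of ``input`` (paths) or ``simulate`` (scenario) must be set.
    """

    seed: int
    output_dir: str = "otukit_out"
    input: dict | None = None       # {dart_csv, individuals} or {vcf, individuals}
    simulate: dict | None = None    # {scenario: default_study, n_loci: ...}
    morphology: dict | None = None  # {csv: path} or {simulate: true}
    stages: dict = field(default_factory=dict)
    filtering: dict = field(default_factory=dict)
    ordination: dict = field(default_factory=dict)
    delimitation: dict = field(default_factory=dict)
    diversity: dict = field(default_factory=dict)
    hybrids: dict = field(default_factory=dict)
    relatedness: dict = field(default_factory=dict)

    def __post_init__(self):
        if (self.input is None) == (self.simulate is None):
            raise ConfigurationError("exactly one of 'input' or 'simulate' required")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ConfigurationError("config must set a seed")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, True))


def _stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def _load_input(cfg: RunConfig) -> GenotypeMatrix:
    spec = cfg.input or {}
    pops = None
    if "individuals" in spec:
        pops = snp_data.read_individual_metadata(spec["individuals"])
    if "dart_csv" in spec:
        return snp_data.read_dart_csv(spec["dart_csv"], populations=pops)
    if "vcf" in spec:
        return snp_data.read_vcf(spec["vcf"], populations=pops)
    if "genotype_csv" in spec:
        return snp_data.read_genotype_csv(
            spec["genotype_csv"],
            orientation=spec.get("orientation", "individuals_as_rows"),
            populations=pops)
    raise ConfigurationError("input block needs dart_csv, vcf or genotype_csv")


def _simulated_input(cfg: RunConfig):
    spec = dict(cfg.simulate or {})
    scenario = spec.pop("scenario", "default_study")
    seed = _stage_seed(cfg.seed, "simulate")
    factories = {"default_study": simulate.default_study,
                 "hybrid_study": simulate.hybrid_study,
                 "kinship_study": simulate.kinship_study}
    if scenario not in factories:
        raise ConfigurationError(f"unknown scenario '{scenario}'")
    sim_cfg = factories[scenario](seed=seed, **spec)
    return simulate.simulate_populations(sim_cfg)


def run_full_analysis(cfg: RunConfig) -> dict:
    """Run every enabled stage, write outputs and return the manifest."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}, "files": {},
                      "config": json.loads(json.dumps(vars(cfg), default=str))}
    written: list[Path] = []

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        written.append(path)

    truth = None
    if cfg.simulate is not None:
        gm, truth = _simulated_input(cfg)
        emit("sim_truth.json", lambda p: truth.to_json(p))
        emit("sim_genotypes.csv", lambda p: snp_data.write_dart_csv(gm, p))
    else:
        gm = _load_input(cfg)

    t0 = time.time()
    if cfg.enabled("filter"):
        fcfg = FilterConfig(**cfg.filtering) if cfg.filtering else FilterConfig()
        gm, report = snp_data.run_filter_pipeline(gm, fcfg)
        emit("filter_report.csv", report.to_csv)
        emit("filter_report.json", lambda p: report.to_json(p))
        manifest["stages"]["filter"] = {
            "loci": gm.n_loci, "individuals": gm.n_individuals,
            "seconds": round(time.time() - t0, 3)}

    if cfg.enabled("ordination"):
        t0 = time.time()
        k = int(cfg.ordination.get("k", 2))
        res = ordination.pcoa_genotypes(gm, k=k)
        emit("pcoa_coordinates.csv", lambda p: res.to_dataframe().to_csv(p, index=False))
        emit("pcoa_scree.csv", lambda p: ordination.scree(res).to_csv(p, index=False))
        if cfg.ordination.get("plot", False):
            emit("pcoa_plot.png", lambda p: ordination.plot_ordination(res, p))
        manifest["stages"]["ordination"] = {
            "percent_axis1": float(res.percent_variance[0]),
            "percent_axis2": float(res.percent_variance[1]) if len(res.percent_variance) > 1 else None,
            "seconds": round(time.time() - t0, 3)}

    hybrid_excluded: list = []
    if cfg.enabled("hybrids"):
        t0 = time.time()
        post = hybridization.classify_hybrids(
            gm,
            burnin=int(cfg.hybrids.get("burnin", 10000)),
            sweeps=int(cfg.hybrids.get("sweeps", 10000)),
            seed=_stage_seed(cfg.seed, "hybrids"))
        emit("hybrid_posteriors.csv",
             lambda p: post.to_dataframe().to_csv(p, index=False))
        emit("hybrid_assignments.csv",
             lambda p: hybridization.assignment_table(post).to_csv(p, index=False))
        hybrid_excluded = hybridization.hybrid_flags(
            post, threshold=float(cfg.hybrids.get("exclusion_threshold", 0.5)))
        manifest["stages"]["hybrids"] = {
            "class_counts": post.class_counts(),
            "excluded_from_delimitation": hybrid_excluded,
            "seconds": round(time.time() - t0, 3)}

    if cfg.enabled("delimitation"):
        t0 = time.time()
        dcfg = cfg.delimitation
        exclude = list(dcfg.get("exclude_individuals", [])) + hybrid_excluded
        exclude = [i for i in dict.fromkeys(exclude) if i in gm.individual_ids]
        fd = delimitation.amalgamate_otus(
            gm, alpha=float(dcfg.get("alpha", 0.05)),
            tolerance=float(dcfg.get("tolerance", 0.0)),
            n_sim=int(dcfg.get("n_sim", 1000)),
            seed=_stage_seed(cfg.seed, "delimitation"),
            exclude_individuals=exclude)
        emit("fixed_differences.csv", lambda p: fd.matrix_dataframe().to_csv(p))
        emit("otus.csv", lambda p: fd.otu_dataframe().to_csv(p, index=False))
        aft = delimitation.allele_frequencies(
            gm.drop_individuals(exclude).with_populations(
                {i: fd.otus[pop] for i, pop in
                 zip(gm.drop_individuals(exclude).individual_ids,
                     gm.drop_individuals(exclude).populations)}))
        pa = delimitation.private_allele_matrix(aft)
        emit("private_alleles.csv", lambda p: pa.to_dataframe().to_csv(p))
        manifest["stages"]["delimitation"] = {
            "n_otus": fd.n_otus, "otus": fd.otus, "excluded": exclude,
            "seconds": round(time.time() - t0, 3)}

    if cfg.enabled("diversity"):
        t0 = time.time()
        het = diversity.heterozygosity_report(
            gm, reps=int(cfg.diversity.get("reps", 10000)),
            seed=_stage_seed(cfg.seed, "diversity"),
            unbiased=bool(cfg.diversity.get("unbiased", False)))
        emit("heterozygosity.csv",
             lambda p: het.per_population.to_csv(p, index=False))
        emit("heterozygosity_tests.csv",
             lambda p: het.pairwise.to_csv(p, index=False))
        manifest["stages"]["diversity"] = {
            "He": dict(zip(het.per_population["population"],
                           het.per_population["He"].round(6))),
            "seconds": round(time.time() - t0, 3)}

    if cfg.enabled("relatedness"):
        t0 = time.time()
        k_mads = float(cfg.relatedness.get("threshold_mads", 5.0))
        # per-population scope by default: the all-pairs null over strongly
        # structured data is dominated by between-group rates, whose spread
        # swamps any low-side outlier
        scope = cfg.relatedness.get("scope", "per_population")
        scans = []
        if scope == "per_population":
            for pop in sorted(set(gm.populations)):
                idx = [i for i, p in enumerate(gm.populations) if p == pop]
                if len(idx) < 3:
                    continue
                scans.append((pop, kin.pairwise_inconsistency_null(
                    gm.take_individuals(idx))))
        else:
            scans.append(("all", kin.pairwise_inconsistency_null(gm)))
        all_pairs = []
        flagged = []
        for pop, scan in scans:
            flags = kin.detect_parent_offspring(scan, threshold_mads=k_mads)
            keys = set(zip(flags["id_a"], flags["id_b"]))
            frame = scan.pairs.assign(
                scope=pop,
                flagged=[(a, b) in keys for a, b in
                         zip(scan.pairs["id_a"], scan.pairs["id_b"])])
            all_pairs.append(frame)
            flagged += [tuple(r) for r in flags[["id_a", "id_b"]].to_numpy()]
        pairs = pd.concat(all_pairs, ignore_index=True)
        emit("kinship_pairs.csv", lambda p: pairs.to_csv(p, index=False))
        manifest["stages"]["relatedness"] = {
            "flagged_pairs": flagged,
            "seconds": round(time.time() - t0, 3)}

    if cfg.enabled("morphometrics"):
        t0 = time.time()
        mcfg = cfg.morphology or {"simulate": True}
        if "csv" in mcfg:
            morph = pd.read_csv(mcfg["csv"])
        else:
            morph = simulate.simulate_morphology(
                seed=_stage_seed(cfg.seed, "morphology"))
        emit("morph_summary.csv",
             lambda p: morphometrics.region_summary(morph).to_csv(p, index=False))
        comps = morphometrics.tukey_kramer(morph)
        emit("morph_comparisons.csv",
             lambda p: morphometrics.comparisons_dataframe(comps).to_csv(p, index=False))
        cva_res = morphometrics.cva(morph)
        emit("morph_cva_scores.csv", lambda p: pd.DataFrame(
            cva_res.scores, columns=[f"CV{i+1}" for i in range(cva_res.scores.shape[1])]
        ).assign(group=cva_res.group_labels).to_csv(p, index=False))
        pca_res = morphometrics.pca_morph(morph)
        emit("morph_pca_scores.csv", lambda p: pd.DataFrame(
            pca_res.scores[:, :2], columns=["PC1", "PC2"]).to_csv(p, index=False))
        manifest["stages"]["morphometrics"] = {
            "cva_percent": [round(float(x), 2) for x in cva_res.percent],
            "pca_percent": [round(float(x), 2) for x in pca_res.percent[:2]],
            "seconds": round(time.time() - t0, 3)}

    for path in written:
        manifest["files"][path.name] = _sha256(path)
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    logger.info("run complete: %d stages, outputs in %s",
                len(manifest["stages"]), out)
    return manifest
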