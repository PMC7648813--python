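"""Synthetic SNP and morphometric data with planted, recorded truth.

The generator emulates the statistical structure the analyses assume: several
sampling sites drawn from a small number of deeply diverged groups, with

* group-level allele-frequency laws calibrated to a target expected
  heterozygosity (symmetric Beta reparameterized by He, or a uniform law for
  balanced panels),
* planted fixed differences between groups (frequencies set to exactly 0/1),
* comonotone coupling of the group draws at non-planted loci (one shared
  uniform quantile per locus) so accidental between-group fixation does not
  contaminate the planted fractions,
* small site-level drift noise within groups,
* hybrid individuals built from Mendelian gamete draws (F1, F2, backcrosses),
* planted parent-offspring / full-sib pairs (zero opposing homozygotes before
  error injection),
* per-genotype error and missingness, and per-locus DArT-style metadata,
* morphometric tables drawn from configurable per-region means/SDs.

Every generator emits a :class:`SimTruth` recording exactly what was planted,
so downstream stages can be scored without re-deriving the truth.  All
randomness flows from the single config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .snp_data import (MISSING, ConfigurationError, GenotypeMatrix, InputError,
                       LocusMeta)

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSpec:
    """One divergent group: its sites with sample sizes and a frequency law.

    ``law`` is ``("beta_he", target_he)`` — symmetric Beta with shape chosen
    so the group's OVERALL expected He (including planted-fixed loci, which
    contribute zero) equals the target — or ``("uniform", lo, hi)``.
    """

    name: str
    sites: Mapping[str, int]
    law: tuple = ("beta_he", 0.10)


@dataclass(frozen=True)
class HybridSpec:
    individual_id: str
    hclass: str            # F1, F2, F1xP0 or F1xP1
    pool0: str             # group names
    pool1: str
    site: str


@dataclass(frozen=True)
class KinSpec:
    parent_id: str
    offspring_id: str
    group: str
    site: str
    relation: str = "parent_offspring"  # or "full_sib"
    #: true genotype-frequency class of the offspring, when the cross makes it
    #: a hybrid class (e.g. the child of an F1 and a pool-0 site is an F1xP0)
    offspring_class: str | None = None


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of the genetic generator.  ``seed`` is mandatory."""

    groups: Sequence[GroupSpec]
    divergence: Mapping[tuple, float]  # (groupA, groupB) -> fixed fraction
    n_loci: int
    seed: int
    hybrids: Sequence[HybridSpec] = ()
    kin: Sequence[KinSpec] = ()
    error_rate: float = 0.002
    missing_rate: float = 0.02
    drift_sd: float = 0.005


@dataclass
class SimTruth:
    """Planted ground truth paired with a generated dataset."""

    group_of: dict                 # individual id -> group name
    hybrid_class: dict             # individual id -> class name
    kin_pairs: list                # (parent_id, offspring_id, relation)
    site_freqs: dict               # site -> per-locus frequency array
    group_freqs: dict              # group -> per-locus frequency array
    fixed_loci: dict               # (groupA, groupB) -> locus index array
    artifact_loci: dict = field(default_factory=dict)   # stage -> planted count
    artifact_individuals: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = {
            "group_of": self.group_of,
            "hybrid_class": self.hybrid_class,
            "kin_pairs": [list(k) for k in self.kin_pairs],
            "fixed_loci": {"|".join(k): np.asarray(v).tolist()
                           for k, v in self.fixed_loci.items()},
            "artifact_loci": self.artifact_loci,
            "artifact_individuals": self.artifact_individuals,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _beta_shape_for_he(target_he: float, fixed_fraction: float) -> float:
    """Symmetric-Beta shape a with E[2p(1-p)] * (1 - fixed_fraction) = target.

    For Beta(a, a), E[2p(1-p)] = a / (2a + 1), so the variable-locus target
    h' = target / (1 - fixed_fraction) needs a = h' / (1 - 2 h'); h' >= 0.5
    is infeasible.
    """
    if not (0.0 <= fixed_fraction < 1.0):
        raise ConfigurationError("fixed fraction must lie in [0, 1)")
    h = target_he / (1.0 - fixed_fraction)
    if h <= 0 or h >= 0.5:
        raise ConfigurationError(
            f"infeasible constraints: He target {target_he} with fixed "
            f"fraction {fixed_fraction} needs per-variable-locus He {h:.3f}, "
            "which a symmetric Beta law cannot reach (must be in (0, 0.5))")
    return h / (1.0 - 2.0 * h)


# ---------------------------------------------------------------------------
# Core generator
# ---------------------------------------------------------------------------


def _gamete_from_freq(rng, p: np.ndarray) -> np.ndarray:
    return (rng.random(p.size) < p).astype(np.int16)


def _gamete_from_genotype(rng, g: np.ndarray) -> np.ndarray:
    """Mendelian gamete: hom transmits its allele, het transmits either."""
    out = (g == 2).astype(np.int16)
    het = g == 1
    out[het] = (rng.random(int(het.sum())) < 0.5).astype(np.int16)
    return out


def simulate_populations(config: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Generate the genotype matrix and its planted truth.

    Planted fixed-difference loci are disjoint blocks with frequencies set to
    exactly 0 and 1 in the two groups (orientation random), so the realized
    population-level fixed fraction equals the request.  Site drift noise is
    applied only at non-planted loci.
    """
    rng = np.random.default_rng(config.seed)
    L = int(config.n_loci)
    groups = {g.name: g for g in config.groups}
    if len(groups) != len(config.groups):
        raise ConfigurationError("duplicate group names")
    for spec in config.groups:
        if any(n < 1 for n in spec.sites.values()):
            raise ConfigurationError(f"sample sizes must be >= 1 in group {spec.name}")

    # planted fixed-difference blocks (disjoint)
    div_items = sorted(((tuple(sorted(k)), v) for k, v in config.divergence.items()))
    for (a, b), frac in div_items:
        if a not in groups or b not in groups:
            raise ConfigurationError(f"divergence names unknown group: {(a, b)}")
        if not (0.0 <= frac <= 1.0):
            raise ConfigurationError("divergence fractions must lie in [0, 1]")
    counts = {pair: int(round(frac * L)) for pair, frac in div_items}
    if sum(counts.values()) > L:
        raise ConfigurationError(
            "infeasible constraints: planted fixed-difference fractions sum "
            f"to more than 1 ({sum(counts.values())} of {L} loci)")
    fixed_loci: dict = {}
    cursor = 0
    for pair, _ in div_items:
        fixed_loci[pair] = np.arange(cursor, cursor + counts[pair])
        cursor += counts[pair]
    fixed_frac_of = {name: 0.0 for name in groups}
    for (a, b), frac in div_items:
        fixed_frac_of[a] += counts[(a, b)] / L
        fixed_frac_of[b] += counts[(a, b)] / L

    # comonotone group frequencies
    u = rng.random(L)
    group_freqs: dict = {}
    for name, spec in groups.items():
        kind = spec.law[0]
        if kind == "beta_he":
            a = _beta_shape_for_he(spec.law[1], fixed_frac_of[name])
            group_freqs[name] = stats.beta.ppf(u, a, a)
        elif kind == "uniform":
            lo, hi = spec.law[1], spec.law[2]
            group_freqs[name] = lo + u * (hi - lo)
        else:
            raise ConfigurationError(f"unknown frequency law '{kind}'")
    for (a, b), idx in fixed_loci.items():
        orient = rng.random(idx.size) < 0.5
        group_freqs[a][idx] = np.where(orient, 0.0, 1.0)
        group_freqs[b][idx] = np.where(orient, 1.0, 0.0)

    planted_any = np.zeros(L, dtype=bool)
    for idx in fixed_loci.values():
        planted_any[idx] = True

    # site frequencies = group + drift at non-planted loci
    site_freqs: dict = {}
    site_group: dict = {}
    for name, spec in groups.items():
        for site in spec.sites:
            if site in site_freqs:
                raise ConfigurationError(f"site '{site}' listed twice")
            p = group_freqs[name].copy()
            if config.drift_sd > 0:
                noise = rng.normal(0.0, config.drift_sd, L)
                p = np.where(planted_any, p, np.clip(p + noise, 0.0, 1.0))
            site_freqs[site] = p
            site_group[site] = name

    # genotypes: HWE binomial draws per individual
    ids: list = []
    pops: list = []
    rows: list = []
    group_of: dict = {}
    for name, spec in groups.items():
        for site, n in spec.sites.items():
            p = site_freqs[site]
            for k in range(n):
                iid = f"{site}_{k + 1:02d}"
                ids.append(iid)
                pops.append(site)
                rows.append(rng.binomial(2, p).astype(np.int16))
                group_of[iid] = name

    # hybrids (Mendelian gamete draws from group-level frequencies)
    hybrid_class: dict = {}
    realized: dict = dict(zip(ids, rows))
    for h in config.hybrids:
        p0 = group_freqs[h.pool0]
        p1 = group_freqs[h.pool1]
        if h.hclass == "F1":
            row = _gamete_from_freq(rng, p0) + _gamete_from_freq(rng, p1)
        elif h.hclass == "F2":
            f1a = _gamete_from_freq(rng, p0) + _gamete_from_freq(rng, p1)
            f1b = _gamete_from_freq(rng, p0) + _gamete_from_freq(rng, p1)
            row = _gamete_from_genotype(rng, f1a) + _gamete_from_genotype(rng, f1b)
        elif h.hclass in ("F1xP0", "F1xP1"):
            f1 = realized.get(f"{h.individual_id}~parent")
            if f1 is None:
                f1 = _gamete_from_freq(rng, p0) + _gamete_from_freq(rng, p1)
            pool = p0 if h.hclass == "F1xP0" else p1
            row = _gamete_from_genotype(rng, f1) + _gamete_from_freq(rng, pool)
        else:
            raise ConfigurationError(f"unknown hybrid class '{h.hclass}'")
        ids.append(h.individual_id)
        pops.append(h.site)
        rows.append(row)
        realized[h.individual_id] = row
        hybrid_class[h.individual_id] = h.hclass
        group_of[h.individual_id] = site_group.get(h.site, h.pool0)

    # planted kin (offspring of an existing or fresh parent)
    kin_pairs: list = []
    for kin in config.kin:
        p = site_freqs.get(kin.site)
        if p is None:
            raise ConfigurationError(f"kin site '{kin.site}' unknown")
        if kin.parent_id in realized:
            parent = realized[kin.parent_id]
        else:
            parent = rng.binomial(2, p).astype(np.int16)
            ids.append(kin.parent_id)
            pops.append(kin.site)
            rows.append(parent)
            realized[kin.parent_id] = parent
            group_of[kin.parent_id] = kin.group
        if kin.relation == "parent_offspring":
            child = _gamete_from_genotype(rng, parent) + _gamete_from_freq(rng, p)
        elif kin.relation == "full_sib":
            other = realized.get(f"{kin.parent_id}~mate")
            if other is None:
                other = rng.binomial(2, p).astype(np.int16)
                realized[f"{kin.parent_id}~mate"] = other
            child = (_gamete_from_genotype(rng, parent)
                     + _gamete_from_genotype(rng, other))
        else:
            raise ConfigurationError(f"unknown kin relation '{kin.relation}'")
        ids.append(kin.offspring_id)
        pops.append(kin.site)
        rows.append(child)
        realized[kin.offspring_id] = child
        group_of[kin.offspring_id] = kin.group
        if kin.offspring_class:
            hybrid_class[kin.offspring_id] = kin.offspring_class
        kin_pairs.append((kin.parent_id, kin.offspring_id, kin.relation))

    g = np.vstack(rows)

    # genotyping error: replace with one of the two other states
    if config.error_rate > 0:
        err = rng.random(g.shape) < config.error_rate
        shift = rng.integers(1, 3, size=g.shape)
        g = np.where(err, (g + shift) % 3, g).astype(np.int16)
    if config.missing_rate > 0:
        g = np.where(rng.random(g.shape) < config.missing_rate, MISSING, g)
    g = g.astype(np.int16)

    loci = _simulate_locus_meta(rng, g)
    gm = GenotypeMatrix(g, ids, pops, loci)
    truth = SimTruth(group_of, hybrid_class, kin_pairs, site_freqs,
                     group_freqs, fixed_loci)
    return gm, truth


def _simulate_locus_meta(rng, g: np.ndarray) -> list:
    """DArT-style metadata that passes the default filter chain."""
    n, L = g.shape
    rep = 0.992 + 0.008 * rng.random(L)
    depth = np.clip(np.exp(rng.normal(3.0, 0.35, L)), 5.5, 95.0)
    callrate = (g != MISSING).mean(axis=0) if n else np.ones(L)
    return [LocusMeta(clone_id=f"tag{j:06d}",
                      snp_position=int(rng.integers(5, 60)),
                      rep_avg=float(rep[j]),
                      call_rate=float(callrate[j]),
                      read_depth=float(depth[j])) for j in range(L)]


# ---------------------------------------------------------------------------
# Hybrid / kin one-off draws (exposed for direct use in tests)
# ---------------------------------------------------------------------------


def simulate_hybrid(truth: SimTruth, hclass: str, pool0: str, pool1: str,
                    seed=None) -> np.ndarray:
    """One hybrid genotype row from the recorded group frequencies."""
    rng = np.random.default_rng(seed)
    p0, p1 = truth.group_freqs[pool0], truth.group_freqs[pool1]
    if hclass == "F1":
        return _gamete_from_freq(rng, p0) + _gamete_from_freq(rng, p1)
    if hclass == "F2":
        f1a = _gamete_from_freq(rng, p0) + _gamete_from_freq(rng, p1)
        f1b = _gamete_from_freq(rng, p0) + _gamete_from_freq(rng, p1)
        return _gamete_from_genotype(rng, f1a) + _gamete_from_genotype(rng, f1b)
    if hclass in ("F1xP0", "F1xP1"):
        f1 = _gamete_from_freq(rng, p0) + _gamete_from_freq(rng, p1)
        pool = p0 if hclass == "F1xP0" else p1
        return _gamete_from_genotype(rng, f1) + _gamete_from_freq(rng, pool)
    raise ConfigurationError(f"unknown hybrid class '{hclass}'")


def simulate_parent_offspring(truth: SimTruth, site: str, seed=None) -> tuple:
    """A parent drawn HWE from the site frequencies and its offspring (one
    parental gamete + one population gamete).  Zero opposing homozygotes by
    construction."""
    rng = np.random.default_rng(seed)
    p = truth.site_freqs[site]
    parent = rng.binomial(2, p).astype(np.int16)
    child = _gamete_from_genotype(rng, parent) + _gamete_from_freq(rng, p)
    return parent, child


# ---------------------------------------------------------------------------
# Filter-stage artifacts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArtifactSpec:
    """Counts of planted quality violations, one filter stage each."""

    n_secondary: int = 0        # extra SNPs on existing sequence tags
    n_bad_depth: int = 0        # depth outside [5, 100]
    n_monomorphic: int = 0
    n_low_rep: int = 0          # repeatability < 0.99
    n_low_callrate_loci: int = 0
    n_bad_individuals: int = 0  # individual call rate < 0.5


def inject_artifacts(gm: GenotypeMatrix, truth: SimTruth, spec: ArtifactSpec,
                     seed=None) -> tuple[GenotypeMatrix, SimTruth]:
    """Append loci/individuals violating exactly one filter stage each.

    On an otherwise clean matrix the later filter report reconciles exactly
    with the planted counts; when violations overlap they are attributed to
    the first pipeline stage that removes them.
    """
    rng = np.random.default_rng(seed)
    n, L = gm.genotypes.shape
    if spec.n_secondary > L:
        raise ConfigurationError("more secondary SNPs requested than loci available")
    g = gm.genotypes.copy()
    loci = list(gm.loci)
    new_cols: list = []
    new_loci: list = []

    def _clean_meta(clone_id, rep=None):
        return LocusMeta(clone_id=clone_id,
                         snp_position=int(rng.integers(5, 60)),
                         rep_avg=float(rep if rep is not None
                                       else 0.992 + 0.008 * rng.random()),
                         call_rate=1.0,
                         read_depth=float(rng.uniform(10, 60)))

    targets = rng.choice(L, size=spec.n_secondary, replace=False) if spec.n_secondary else []
    for j in targets:
        src = loci[j]
        rep = (src.rep_avg if src.rep_avg is not None else 1.0) - 0.001
        new_loci.append(LocusMeta(clone_id=src.clone_id,
                                  snp_position=src.snp_position + 1,
                                  rep_avg=float(min(max(rep, 0.99), 1.0)),
                                  call_rate=src.call_rate,
                                  read_depth=src.read_depth))
        new_cols.append(g[:, j].copy())
    for k in range(spec.n_bad_depth):
        meta = _clean_meta(f"baddepth{k:04d}")
        depth = 3.0 if k % 2 == 0 else 150.0
        new_loci.append(LocusMeta(meta.clone_id, meta.snp_position,
                                  meta.rep_avg, meta.call_rate, depth))
        new_cols.append(rng.binomial(2, 0.5, n).astype(np.int16))
    for k in range(spec.n_monomorphic):
        new_loci.append(_clean_meta(f"mono{k:04d}"))
        new_cols.append(np.full(n, 0 if k % 2 == 0 else 2, dtype=np.int16))
    for k in range(spec.n_low_rep):
        meta = _clean_meta(f"lowrep{k:04d}", rep=0.95)
        new_loci.append(meta)
        new_cols.append(rng.binomial(2, 0.5, n).astype(np.int16))
    for k in range(spec.n_low_callrate_loci):
        new_loci.append(_clean_meta(f"lowcall{k:04d}"))
        col = rng.binomial(2, 0.5, n).astype(np.int16)
        n_miss = max(1, int(np.ceil(0.10 * n)))
        col[rng.choice(n, size=n_miss, replace=False)] = MISSING
        new_cols.append(col)

    if new_cols:
        g = np.hstack([g, np.stack(new_cols, axis=1)])
        loci = loci + new_loci

    ids = list(gm.individual_ids)
    pops = list(gm.populations)
    bad_ids = []
    for k in range(spec.n_bad_individuals):
        row = rng.binomial(2, 0.5, g.shape[1]).astype(np.int16)
        miss = rng.random(g.shape[1]) < 0.7
        row[miss] = MISSING
        iid = f"badind{k:02d}"
        ids.append(iid)
        pops.append(pops[0] if pops else "unassigned")
        g = np.vstack([g, row])
        bad_ids.append(iid)

    truth.artifact_loci = {
        "one_snp_per_tag": int(spec.n_secondary),
        "read_depth": int(spec.n_bad_depth),
        "monomorphic": int(spec.n_monomorphic),
        "repeatability": int(spec.n_low_rep),
        "locus_callrate": int(spec.n_low_callrate_loci),
    }
    truth.artifact_individuals = bad_ids
    return GenotypeMatrix(g, ids, pops, loci), truth


# ---------------------------------------------------------------------------
# Morphometrics generator
# ---------------------------------------------------------------------------

#: Default per-region (mean, SD) for the eight traits and region sample sizes
#: used by the packaged study emulation.
MORPH_PARAMS: dict = {
    "Northern": {"mass": (0.68, 0.06), "head_length": (57.21, 2.99),
                 "head_width": (34.19, 1.61), "body_length": (27.89, 2.47),
                 "tail_length": (40.78, 3.23), "knee_to_heel": (104.19, 4.91),
                 "ear_length": (35.9, 2.06), "ear_width": (26.57, 3.49)},
    "Central": {"mass": (0.87, 0.09), "head_length": (64.17, 3.21),
                "head_width": (37.26, 1.51), "body_length": (28.27, 3.31),
                "tail_length": (45.02, 2.13), "knee_to_heel": (112.59, 5.02),
                "ear_length": (40.37, 4.02), "ear_width": (29.88, 2.87)},
    "Southern": {"mass": (1.36, 0.16), "head_length": (67.05, 2.34),
                 "head_width": (39.14, 2.79), "body_length": (36.11, 2.95),
                 "tail_length": (51.75, 2.82), "knee_to_heel": (121.04, 3.82),
                 "ear_length": (41.62, 3.28), "ear_width": (31.0, 2.46)},
}

MORPH_SITES: dict = {"Taravale": ("Northern", 14), "Blackbraes": ("Northern", 13),
                     "RedcliffeVale": ("Central", 15), "Bendoc": ("Southern", 8),
                     "Wombat": ("Southern", 6)}


def simulate_morphology(seed=None, params: Mapping | None = None,
                        sites: Mapping | None = None,
                        sex_effects: Mapping[str, float] | None = None,
                        exact_moments: bool = False) -> pd.DataFrame:
    """Per-region normal draws of the eight traits.

    ``sex_effects`` maps trait -> additive female offset (applied after the
    draws).  ``exact_moments`` rescales each region x trait sample to hit the
    configured mean and SD exactly (used for arithmetic checks against the
    configured table); sex effects are not applied in that mode.
    """
    rng = np.random.default_rng(seed)
    params = dict(params or MORPH_PARAMS)
    sites = dict(sites or MORPH_SITES)
    from .morphometrics import TRAITS

    rows = []
    counter = 0
    for site, (region, n) in sites.items():
        for _ in range(n):
            counter += 1
            rows.append({"id": f"M{counter:03d}", "site": site, "region": region,
                         "sex": "F" if rng.random() < 0.5 else "M", "adult": True})
    df = pd.DataFrame(rows)
    for trait in TRAITS:
        vals = np.empty(len(df))
        for region in df["region"].unique():
            mean, sd = params[region][trait]
            mask = (df["region"] == region).to_numpy()
            draw = rng.normal(mean, sd, int(mask.sum()))
            if exact_moments and mask.sum() >= 2:
                z = (draw - draw.mean()) / draw.std(ddof=1)
                draw = mean + sd * z
            vals[mask] = draw
        df[trait] = vals
    if sex_effects and not exact_moments:
        female = (df["sex"] == "F").to_numpy()
        for trait, delta in sex_effects.items():
            df.loc[female, trait] = df.loc[female, trait] + delta
    return df


# ---------------------------------------------------------------------------
# Canned study scenarios
# ---------------------------------------------------------------------------


def default_study(n_loci: int = 1000, seed: int = 0, drift_sd: float = 0.005,
                  error_rate: float = 0.002, missing_rate: float = 0.02) -> SimConfig:
    """Five sampling sites from three divergent groups, with one F1 and one
    F1xP0 backcross (also a parent-offspring pair) sampled at the first
    northern site.  Divergence fractions and He targets are on the scale the
    three-group study design exhibits."""
    groups = [
        GroupSpec("North", {"Taravale": 18, "Blackbraes": 15}, ("beta_he", 0.04)),
        GroupSpec("Central", {"RedcliffeVale": 18}, ("beta_he", 0.10)),
        GroupSpec("South", {"Bendoc": 9, "Wombat": 6}, ("beta_he", 0.11)),
    ]
    divergence = {("Central", "North"): 0.25, ("North", "South"): 0.40,
                  ("Central", "South"): 0.16}
    hybrids = [HybridSpec("T1", "F1", "North", "Central", "Taravale")]
    # T5 = gamete(T1) + North gamete, i.e. a genuine F1xP0 backcross
    kin = [KinSpec("T1", "T5", "North", "Taravale", "parent_offspring",
                   offspring_class="F1xP0")]
    return SimConfig(groups=groups, divergence=divergence, n_loci=n_loci,
                     seed=seed, hybrids=hybrids, kin=kin,
                     error_rate=error_rate, missing_rate=missing_rate,
                     drift_sd=drift_sd)


def hybrid_study(n_loci: int = 1000, seed: int = 0,
                 divergence: float = 0.30) -> SimConfig:
    """Two parental pools (32 and 26 individuals) plus one F1 and one F1xP0
    backcross, for hybrid-classification power checks."""
    groups = [GroupSpec("North", {"NorthSite": 32}, ("beta_he", 0.08)),
              GroupSpec("Central", {"CentralSite": 26}, ("beta_he", 0.10))]
    hybrids = [HybridSpec("T1", "F1", "North", "Central", "NorthSite")]
    kin = [KinSpec("T1", "T5", "North", "NorthSite", "parent_offspring",
                   offspring_class="F1xP0")]
    return SimConfig(groups=groups,
                     divergence={("Central", "North"): divergence},
                     n_loci=n_loci, seed=seed, hybrids=hybrids, kin=kin,
                     error_rate=0.002, missing_rate=0.02, drift_sd=0.0)


def kinship_study(n_unrelated: int = 50, n_loci: int = 1000, seed: int = 0,
                  error_rate: float = 0.002) -> SimConfig:
    """One balanced-frequency pool of unrelated individuals plus a planted
    parent-offspring pair, for the opposing-homozygote outlier scan."""
    groups = [GroupSpec("Pool", {"PoolSite": n_unrelated}, ("uniform", 0.3, 0.7))]
    kin = [KinSpec("par", "off", "Pool", "PoolSite", "parent_offspring")]
    return SimConfig(groups=groups, divergence={}, n_loci=n_loci, seed=seed,
                     kin=kin, error_rate=error_rate, missing_rate=0.0,
                     drift_sd=0.0)
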