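"""Genotype-matrix data model, readers/writers and the staged SNP quality filters.

The substrate of every genetic analysis in this package is a diploid SNP
genotype matrix (individuals x loci) coded on the allele-dosage scale:

    0 = homozygous reference, 1 = heterozygous, 2 = homozygous alternate,
    MISSING = no call.

Reduced-representation (DArTseq-style) data arrive with per-locus metadata —
the sequence-tag identity (CloneID), the SNP's offset within the tag
(SnpPosition), technical-replicate repeatability (RepAvg), call rate and mean
read depth — which drive the six-stage quality-filter chain implemented here:

    1. one SNP per sequence tag        4. remove monomorphic loci
    2. read depth within [5x, 100x]    5. repeatability >= 0.99
    3. individual call rate >= 0.5     6. locus call rate >= 0.95

Throughout, allele frequency p refers to the alternate allele.
"""

from __future__ import annotations

import csv
import io
import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("otukit")

#: Sentinel for a missing genotype call.  Never a valid dosage.
MISSING: int = -9

#: Metadata value meaning "the source format did not provide this field".
#: Loci with unknown depth/repeatability pass the corresponding filters
#: unless strict mode is requested.
UNKNOWN = None


class InputError(ValueError):
    """Malformed or inconsistent input data."""


class ConfigurationError(ValueError):
    """Invalid analysis configuration (thresholds, column maps, ...)."""


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LocusMeta:
    """Per-locus metadata attached to one genotype-matrix column.

    ``rep_avg`` and ``read_depth`` may be ``None`` (unknown) for sources such
    as generic VCF that do not carry them.
    """

    clone_id: str
    snp_position: int = 0
    rep_avg: float | None = None
    call_rate: float | None = None
    read_depth: float | None = None

    def __post_init__(self) -> None:
        if self.snp_position < 0:
            raise InputError(f"snp_position must be >= 0, got {self.snp_position}")
        for name in ("rep_avg", "call_rate"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise InputError(f"{name} must lie in [0, 1], got {v}")
        if self.read_depth is not None and self.read_depth < 0:
            raise InputError(f"read_depth must be >= 0, got {self.read_depth}")


@dataclass(frozen=True)
class FilterStage:
    name: str
    loci_removed: int
    individuals_removed: int
    loci_remaining: int
    individuals_remaining: int


@dataclass
class FilterReport:
    """Ordered per-stage accounting of the filter chain."""

    initial_loci: int
    initial_individuals: int
    stages: list[FilterStage] = field(default_factory=list)

    def add(self, name: str, loci_removed: int, individuals_removed: int,
            loci_remaining: int, individuals_remaining: int) -> None:
        prev_l, prev_i = self._current()
        if loci_removed < 0 or individuals_removed < 0:
            raise ValueError("removed counts must be non-negative")
        if prev_l - loci_removed != loci_remaining or prev_i - individuals_removed != individuals_remaining:
            raise ValueError(f"stage '{name}' counts do not reconcile")
        self.stages.append(FilterStage(name, loci_removed, individuals_removed,
                                       loci_remaining, individuals_remaining))

    def _current(self) -> tuple[int, int]:
        if self.stages:
            last = self.stages[-1]
            return last.loci_remaining, last.individuals_remaining
        return self.initial_loci, self.initial_individuals

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.name, s.loci_removed, s.individuals_removed,
              s.loci_remaining, s.individuals_remaining) for s in self.stages],
            columns=["stage", "loci_removed", "individuals_removed",
                     "loci_remaining", "individuals_remaining"],
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_json(self, path=None) -> str:
        payload = {
            "initial_loci": self.initial_loci,
            "initial_individuals": self.initial_individuals,
            "stages": [vars(s) for s in self.stages],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


class GenotypeMatrix:
    """Individuals x loci diploid SNP genotypes plus metadata.

    Parameters
    ----------
    genotypes
        Integer array, shape (n_individuals, n_loci), values in
        {0, 1, 2, MISSING}.
    individual_ids
        Unique identifiers, one per row.
    populations
        Population / sampling-site label, one per individual.
    loci
        One :class:`LocusMeta` per column.
    """

    def __init__(self, genotypes, individual_ids: Sequence[str],
                 populations: Sequence[str], loci: Sequence[LocusMeta]):
        g = np.asarray(genotypes, dtype=np.int16)
        if g.ndim != 2:
            raise InputError("genotypes must be a 2-D array")
        valid = np.isin(g, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(g[~valid])
            raise InputError(f"invalid genotype values {bad.tolist()}; "
                             f"allowed are 0, 1, 2, MISSING ({MISSING})")
        ids = [str(i) for i in individual_ids]
        if len(ids) != g.shape[0]:
            raise InputError("individual_ids length does not match genotype rows")
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise InputError(f"duplicate individual ids: {dupes}")
        pops = [str(p) for p in populations]
        if len(pops) != len(ids):
            raise InputError("populations length does not match individuals")
        loci = list(loci)
        if len(loci) != g.shape[1]:
            raise InputError("loci length does not match genotype columns")
        self.genotypes = g
        self.individual_ids = ids
        self.populations = pops
        self.loci = loci

    # -- basic introspection ------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    def called(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.genotypes != MISSING

    def individual_call_rates(self) -> np.ndarray:
        if self.n_loci == 0:
            return np.ones(self.n_individuals)
        return self.called().mean(axis=1)

    def locus_call_rates(self) -> np.ndarray:
        if self.n_individuals == 0:
            return np.ones(self.n_loci)
        return self.called().mean(axis=0)

    def index_of(self, individual_id: str) -> int:
        try:
            return self.individual_ids.index(individual_id)
        except ValueError:
            raise InputError(f"unknown individual id '{individual_id}'") from None

    # -- subsetting ---------------------------------------------------------

    def take_individuals(self, idx: Iterable[int]) -> "GenotypeMatrix":
        idx = list(idx)
        return GenotypeMatrix(self.genotypes[idx, :],
                              [self.individual_ids[i] for i in idx],
                              [self.populations[i] for i in idx],
                              self.loci)

    def take_loci(self, idx: Iterable[int]) -> "GenotypeMatrix":
        idx = list(idx)
        return GenotypeMatrix(self.genotypes[:, idx],
                              self.individual_ids, self.populations,
                              [self.loci[i] for i in idx])

    def drop_individuals(self, ids: Iterable[str]) -> "GenotypeMatrix":
        drop = set(ids)
        unknown = drop - set(self.individual_ids)
        if unknown:
            raise InputError(f"unknown individual ids {sorted(unknown)}")
        keep = [i for i, name in enumerate(self.individual_ids) if name not in drop]
        return self.take_individuals(keep)

    def with_populations(self, mapping: Mapping[str, str]) -> "GenotypeMatrix":
        missing = [i for i in self.individual_ids if i not in mapping]
        if missing:
            raise InputError(f"no population label for individuals {missing}")
        return GenotypeMatrix(self.genotypes, self.individual_ids,
                              [mapping[i] for i in self.individual_ids], self.loci)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"GenotypeMatrix({self.n_individuals} individuals x "
                f"{self.n_loci} loci, {len(set(self.populations))} populations)")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DartEncoding:
    """Column map and genotype encoding for one-row-per-locus DArT-style CSV.

    ``genotype_map`` translates cell text to dosage codes; anything not in the
    map and not a ``missing_token`` is treated as missing with a warning.
    """

    column_map: Mapping[str, str] = field(default_factory=lambda: {
        "clone_id": "CloneID",
        "snp_position": "SnpPosition",
        "rep_avg": "RepAvg",
        "call_rate": "CallRate",
        "read_depth": "ReadDepth",
    })
    genotype_map: Mapping[str, int] = field(default_factory=lambda: {"0": 0, "1": 1, "2": 2})
    missing_tokens: frozenset = frozenset({"-", "", "NA"})


def read_dart_csv(path, encoding: DartEncoding | None = None,
                  populations: Mapping[str, str] | None = None) -> GenotypeMatrix:
    """Read a one-row-per-locus DArT-style CSV.

    Metadata columns are located via ``encoding.column_map``; every other
    column is an individual.  Unparseable genotype cells become MISSING and
    are counted in a logged warning.
    """
    enc = encoding or DartEncoding()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    colmap = dict(enc.column_map)
    for key in ("clone_id", "snp_position", "rep_avg", "call_rate", "read_depth"):
        col = colmap.get(key)
        if col is None or col not in df.columns:
            raise ConfigurationError(
                f"mandatory metadata column for '{key}' "
                f"({col!r}) not found in {path}")
    meta_cols = [colmap[k] for k in colmap]
    ind_cols = [c for c in df.columns if c not in meta_cols]
    if len(set(ind_cols)) != len(ind_cols):
        # pandas mangles duplicates to name.1; detect the mangled pattern too
        raise InputError("duplicate individual id columns")
    mangled = [c for c in ind_cols if "." in c and c.rsplit(".", 1)[0] in ind_cols
               and c.rsplit(".", 1)[1].isdigit()]
    if mangled:
        raise InputError(f"duplicate individual id columns: "
                         f"{sorted(c.rsplit('.', 1)[0] for c in mangled)}")

    def _meta_float(text: str) -> float | None:
        if text in enc.missing_tokens:
            return None
        return float(text)

    loci = []
    for _, row in df.iterrows():
        loci.append(LocusMeta(
            clone_id=str(row[colmap["clone_id"]]),
            snp_position=int(float(row[colmap["snp_position"]] or 0)),
            rep_avg=_meta_float(row[colmap["rep_avg"]]),
            call_rate=_meta_float(row[colmap["call_rate"]]),
            read_depth=_meta_float(row[colmap["read_depth"]]),
        ))

    cells = df[ind_cols].to_numpy(dtype=object).T  # individuals x loci
    g = np.full(cells.shape, MISSING, dtype=np.int16)
    unparseable = 0
    gmap = dict(enc.genotype_map)
    for (i, j), val in np.ndenumerate(cells):
        text = str(val).strip()
        if text in gmap:
            g[i, j] = gmap[text]
        elif text not in enc.missing_tokens:
            unparseable += 1
    if unparseable:
        logger.warning("read_dart_csv: %d unparseable genotype cells set to MISSING",
                       unparseable)
    pops = [populations.get(i, "unassigned") if populations else "unassigned"
            for i in ind_cols]
    return GenotypeMatrix(g, ind_cols, pops, loci)


def write_dart_csv(gm: GenotypeMatrix, path, encoding: DartEncoding | None = None) -> None:
    """Write a GenotypeMatrix in the one-row-per-locus CSV layout read back by
    :func:`read_dart_csv` (bit-exact round trip for valid inputs)."""
    enc = encoding or DartEncoding()
    colmap = dict(enc.column_map)
    inverse = {v: k for k, v in enc.genotype_map.items()}
    missing_token = "-"
    header = [colmap["clone_id"], colmap["snp_position"], colmap["rep_avg"],
              colmap["call_rate"], colmap["read_depth"]] + list(gm.individual_ids)

    def _fmt(v):
        if v is None:
            return "NA"
        return repr(float(v))

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for j, loc in enumerate(gm.loci):
            row = [loc.clone_id, loc.snp_position, _fmt(loc.rep_avg),
                   _fmt(loc.call_rate), _fmt(loc.read_depth)]
            for i in range(gm.n_individuals):
                v = int(gm.genotypes[i, j])
                row.append(missing_token if v == MISSING else inverse[v])
            w.writerow(row)


def read_genotype_csv(path, orientation: str = "individuals_as_rows",
                      missing_tokens: Iterable[str] = ("-", "", "NA"),
                      populations: Mapping[str, str] | None = None) -> GenotypeMatrix:
    """Read a generic genotype CSV with no locus metadata.

    ``orientation`` declares whether individuals are rows or columns; the
    first column (or row) holds identifiers.  Locus metadata is unknown, so
    those loci pass metadata-based filters (decision: unknown passes).
    """
    if orientation not in ("individuals_as_rows", "individuals_as_columns"):
        raise ConfigurationError(f"unknown orientation '{orientation}'")
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    if orientation == "individuals_as_columns":
        df = df.T
    ids = [str(i) for i in df.index]
    locus_names = [str(c) for c in df.columns]
    tokens = set(missing_tokens)
    g = np.full(df.shape, MISSING, dtype=np.int16)
    bad = 0
    for (i, j), val in np.ndenumerate(df.to_numpy(dtype=object)):
        text = str(val).strip()
        if text in ("0", "1", "2"):
            g[i, j] = int(text)
        elif text not in tokens:
            bad += 1
    if bad:
        logger.warning("read_genotype_csv: %d unparseable cells set to MISSING", bad)
    loci = [LocusMeta(clone_id=name) for name in locus_names]
    pops = [populations.get(i, "unassigned") if populations else "unassigned" for i in ids]
    return GenotypeMatrix(g, ids, pops, loci)


def read_individual_metadata(path) -> dict[str, str]:
    """Read an individual metadata CSV (columns: id, population[, lat, lon])."""
    df = pd.read_csv(path, dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "id" not in cols or "population" not in cols:
        raise ConfigurationError("individual metadata CSV needs 'id' and 'population' columns")
    ids = df[cols["id"]].tolist()
    if len(set(ids)) != len(ids):
        raise InputError("duplicate ids in individual metadata")
    return dict(zip(ids, df[cols["population"]].tolist()))


def read_vcf(path, populations: Mapping[str, str] | None = None) -> GenotypeMatrix:
    """Read genotypes from a VCF (GT field), biallelic records only.

    GT 0/0 -> 0, 0/1 -> 1, 1/1 -> 2, missing -> MISSING.  Multiallelic records
    are skipped with a warning count.  clone_id defaults to CHROM:POS;
    repeatability/depth come from INFO/FORMAT when present, else unknown.
    """
    import pysam

    try:
        vf = pysam.VariantFile(str(path))
    except Exception as exc:
        raise InputError(f"malformed VCF {path}: {_vcf_error_line(path)}: {exc}") from exc
    ids = list(vf.header.samples)
    if len(set(ids)) != len(ids):
        raise InputError("duplicate sample ids in VCF header")
    columns: list[np.ndarray] = []
    loci: list[LocusMeta] = []
    skipped = 0
    try:
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                skipped += 1
                continue
            col = np.full(len(ids), MISSING, dtype=np.int16)
            depths = []
            for i, sample in enumerate(ids):
                call = rec.samples[sample]
                gt = call.get("GT")
                if gt is not None and None not in gt:
                    col[i] = int(sum(1 for a in gt if a != 0))
                dp = call.get("DP")
                if dp is not None:
                    depths.append(dp)
            depth = float(np.mean(depths)) if depths else None
            rep = rec.info.get("REPAVG") if "REPAVG" in rec.info else None
            if isinstance(rep, tuple):
                rep = rep[0]
            loci.append(LocusMeta(clone_id=f"{rec.chrom}:{rec.pos}",
                                  snp_position=0,
                                  rep_avg=float(rep) if rep is not None else None,
                                  call_rate=None,
                                  read_depth=depth))
            columns.append(col)
    except Exception as exc:
        raise InputError(f"malformed VCF {path}: {_vcf_error_line(path)}: {exc}") from exc
    if skipped:
        logger.warning("read_vcf: skipped %d non-biallelic records", skipped)
    g = (np.stack(columns, axis=1) if columns
         else np.empty((len(ids), 0), dtype=np.int16))
    pops = [populations.get(i, "unassigned") if populations else "unassigned" for i in ids]
    return GenotypeMatrix(g, ids, pops, loci)


def _vcf_error_line(path) -> str:
    """Best-effort location of the first structurally bad VCF data line."""
    try:
        with open(path) as fh:
            for n, line in enumerate(fh, start=1):
                if line.startswith("#") or not line.strip():
                    continue
                if len(line.rstrip("\n").split("\t")) < 8:
                    return f"line {n}"
    except OSError:
        pass
    return "line unknown"


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def select_one_snp_per_tag(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Retain one SNP per sequence tag (clone_id).

    The retained SNP is the one with highest repeatability; ties broken by
    lowest snp_position, then input order.  Unknown repeatability sorts below
    any known value.
    """
    best: dict[str, tuple] = {}
    for j, loc in enumerate(gm.loci):
        rep = loc.rep_avg if loc.rep_avg is not None else -1.0
        key = (-rep, loc.snp_position, j)
        if loc.clone_id not in best or key < best[loc.clone_id]:
            best[loc.clone_id] = key
    keep = sorted(key[2] for key in best.values())
    return gm.take_loci(keep)


def filter_by_read_depth(gm: GenotypeMatrix, min_depth: float = 5,
                         max_depth: float = 100, strict: bool = False) -> GenotypeMatrix:
    """Keep loci with mean read depth in [min_depth, max_depth] (inclusive).

    Loci with unknown depth pass unless ``strict``.
    """
    if min_depth > max_depth:
        raise ConfigurationError(f"min_depth {min_depth} > max_depth {max_depth}")
    keep = []
    for j, loc in enumerate(gm.loci):
        if loc.read_depth is None:
            if not strict:
                keep.append(j)
            continue
        if min_depth <= loc.read_depth <= max_depth:
            keep.append(j)
    return gm.take_loci(keep)


def filter_individuals_by_callrate(gm: GenotypeMatrix,
                                   min_ind_callrate: float = 0.5) -> GenotypeMatrix:
    """Remove individuals whose call rate is strictly below the threshold."""
    rates = gm.individual_call_rates()
    keep = [i for i in range(gm.n_individuals) if rates[i] >= min_ind_callrate]
    removed = [gm.individual_ids[i] for i in range(gm.n_individuals)
               if rates[i] < min_ind_callrate]
    if removed:
        logger.info("removed %d individuals with call rate < %g: %s",
                    len(removed), min_ind_callrate, removed)
    return gm.take_individuals(keep)


def remove_monomorphic_loci(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Remove loci where all non-missing genotypes are 0, or all are 2.

    A single heterozygote means both alleles segregate, so the locus is kept.
    All-missing columns count as monomorphic and are removed.
    """
    g = gm.genotypes
    called = g != MISSING
    any_alt = ((g == 1) | (g == 2)).any(axis=0)
    any_ref = ((g == 1) | (g == 0)).any(axis=0)
    polymorphic = called.any(axis=0) & any_alt & any_ref
    return gm.take_loci(np.flatnonzero(polymorphic))


def filter_by_repeatability(gm: GenotypeMatrix, min_rep: float = 0.99,
                            strict: bool = False) -> GenotypeMatrix:
    """Remove loci with repeatability strictly below ``min_rep``.

    Unknown repeatability passes unless ``strict``.
    """
    keep = []
    for j, loc in enumerate(gm.loci):
        if loc.rep_avg is None:
            if not strict:
                keep.append(j)
            continue
        if loc.rep_avg >= min_rep:
            keep.append(j)
    return gm.take_loci(keep)


def filter_by_locus_callrate(gm: GenotypeMatrix,
                             min_callrate: float = 0.95) -> GenotypeMatrix:
    """Remove loci whose call rate, recomputed on the current individuals, is
    strictly below the threshold.  The vendor CallRate column is retained in
    metadata for provenance but not trusted here."""
    rates = gm.locus_call_rates()
    keep = np.flatnonzero(rates >= min_callrate)
    return gm.take_loci(keep)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the six-stage filter chain (the `filtering:` config block)."""

    min_depth: float = 5.0
    max_depth: float = 100.0
    min_ind_callrate: float = 0.5
    min_rep: float = 0.99
    min_locus_callrate: float = 0.95
    strict_metadata: bool = False


def run_filter_pipeline(gm: GenotypeMatrix,
                        config: FilterConfig | None = None) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the six filter stages in their canonical order.

    Order: one SNP per tag -> read depth -> individual call rate ->
    monomorphic -> repeatability -> locus call rate.  Locus call rate is
    recomputed after individual removal.
    """
    cfg = config or FilterConfig()
    report = FilterReport(gm.n_loci, gm.n_individuals)
    stages = [
        ("one_snp_per_tag", lambda m: select_one_snp_per_tag(m)),
        ("read_depth", lambda m: filter_by_read_depth(
            m, cfg.min_depth, cfg.max_depth, cfg.strict_metadata)),
        ("individual_callrate", lambda m: filter_individuals_by_callrate(
            m, cfg.min_ind_callrate)),
        ("monomorphic", lambda m: remove_monomorphic_loci(m)),
        ("repeatability", lambda m: filter_by_repeatability(
            m, cfg.min_rep, cfg.strict_metadata)),
        ("locus_callrate", lambda m: filter_by_locus_callrate(
            m, cfg.min_locus_callrate)),
    ]
    for name, fn in stages:
        before_l, before_i = gm.n_loci, gm.n_individuals
        gm = fn(gm)
        report.add(name, before_l - gm.n_loci, before_i - gm.n_individuals,
                   gm.n_loci, gm.n_individuals)
    logger.info("filter pipeline: %d loci x %d individuals retained",
                gm.n_loci, gm.n_individuals)
    return gm, report
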