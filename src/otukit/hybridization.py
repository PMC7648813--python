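"""Bayesian assignment of individuals to genotype-frequency classes.

Two parental gene pools (0 and 1) and six classes defined by the probability
that a random locus of an individual carries (both copies from pool 0, one
from each, both from pool 1):

    P0 = (1, 0, 0)        F2    = (1/4, 1/2, 1/4)
    P1 = (0, 0, 1)        F1xP0 = (1/2, 1/2, 0)
    F1 = (0, 1, 0)        F1xP1 = (0, 1/2, 1/2)

Neither parental pool is specified in advance: a Gibbs sampler jointly infers
per-individual class labels z, per-pool per-locus allele frequencies theta
(Jeffreys Beta(1/2,1/2) priors), and class mixing proportions pi (Jeffreys
Dirichlet(1/2,...)).  The genotype likelihood given class c is

    P(g) = w00 f00(g) + w01 f01(g) + w11 f11(g)

with f_xy the genotype distribution of one gene from pool x and one from
pool y.  Data augmentation with the latent gene-pair origin at each
(individual, locus) — and, for heterozygotes of mixed origin, which copy
came from which pool — makes every conditional conjugate.

Missing genotypes contribute likelihood 1.  Posterior class probabilities
are label frequencies over the post-burn-in sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .snp_data import MISSING, ConfigurationError, GenotypeMatrix, InputError

CLASSES: tuple = ("P0", "P1", "F1", "F2", "F1xP0", "F1xP1")

#: gene-pair origin weights (w00, w01, w11) per class, canonical order
CLASS_WEIGHTS = np.array([
    [1.00, 0.00, 0.00],   # P0
    [0.00, 0.00, 1.00],   # P1
    [0.00, 1.00, 0.00],   # F1
    [0.25, 0.50, 0.25],   # F2
    [0.50, 0.50, 0.00],   # F1xP0
    [0.00, 0.50, 0.50],   # F1xP1
])

_SWAP = [1, 0, 2, 3, 5, 4]  # P0<->P1, F1xP0<->F1xP1 under a pool-label swap


def class_genotype_frequencies(hclass: str, p0: float, p1: float) -> tuple:
    """Genotype distribution (P(g=0), P(g=1), P(g=2)) for one class at a locus
    with pool alternate-allele frequencies p0, p1."""
    if not (0.0 <= p0 <= 1.0 and 0.0 <= p1 <= 1.0):
        raise InputError(f"allele frequencies must lie in [0, 1], got {p0}, {p1}")
    try:
        w = CLASS_WEIGHTS[CLASSES.index(hclass)]
    except ValueError:
        raise InputError(f"unknown class '{hclass}'; valid: {CLASSES}") from None
    f00 = np.array([(1 - p0) ** 2, 2 * p0 * (1 - p0), p0 ** 2])
    f01 = np.array([(1 - p0) * (1 - p1), p0 * (1 - p1) + p1 * (1 - p0), p0 * p1])
    f11 = np.array([(1 - p1) ** 2, 2 * p1 * (1 - p1), p1 ** 2])
    out = w[0] * f00 + w[1] * f01 + w[2] * f11
    return tuple(float(x) for x in out)


@dataclass
class HybridPosterior:
    individual_ids: list
    populations: list
    probs: np.ndarray      # individuals x 6, rows sum to 1
    map_class: list        # argmax with canonical-order tie-break
    #: max across-chain spread of any posterior entry (multi-chain runs only);
    #: large values signal non-convergence or an unidentifiable model
    chain_spread: float | None = None

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probs, columns=list(CLASSES))
        df.insert(0, "id", self.individual_ids)
        df.insert(1, "population", self.populations)
        df["map_class"] = self.map_class
        return df

    def class_counts(self) -> dict:
        out = {c: 0 for c in CLASSES}
        for c in self.map_class:
            out[c] += 1
        return out


def _genotype_tables(theta0: np.ndarray, theta1: np.ndarray) -> np.ndarray:
    """Stack of f00, f01, f11 genotype tables, each (L, 3)."""
    t0, t1 = theta0, theta1
    f = np.empty((3, t0.size, 3))
    f[0, :, 0] = (1 - t0) ** 2
    f[0, :, 1] = 2 * t0 * (1 - t0)
    f[0, :, 2] = t0 ** 2
    f[1, :, 0] = (1 - t0) * (1 - t1)
    f[1, :, 1] = t0 * (1 - t1) + t1 * (1 - t0)
    f[1, :, 2] = t0 * t1
    f[2, :, 0] = (1 - t1) ** 2
    f[2, :, 1] = 2 * t1 * (1 - t1)
    f[2, :, 2] = t1 ** 2
    return f


def classify_hybrids(gm: GenotypeMatrix, burnin: int = 10000,
                     sweeps: int = 10000, seed=None,
                     n_chains: int = 1) -> HybridPosterior:
    """Run the six-class Gibbs sampler and return posterior class membership.

    Single chain; ``burnin`` sweeps are discarded, ``sweeps`` retained.  The
    chain is initialized by splitting individuals into two provisional pools
    on the sign of the leading eigenvector of the centred genotype matrix,
    which avoids the symmetric theta0 = theta1 stationary point of a cold
    start.  Pool labels are anchored after the run: if the first individual's
    P1 posterior exceeds its P0 posterior, pool labels are swapped
    (P0<->P1, F1xP0<->F1xP1) for all individuals.

    ``n_chains > 1`` runs independent chains on forked seeds and averages
    their (anchored) posteriors; the reported ``chain_spread`` is a cheap
    convergence/identifiability diagnostic (off by default).
    """
    if gm.n_individuals < 2:
        raise InputError("need at least 2 individuals")
    if burnin < 0 or sweeps < 1:
        raise ConfigurationError("burnin must be >= 0 and sweeps >= 1")
    if n_chains > 1:
        seeds = np.random.SeedSequence(seed).spawn(n_chains)
        runs = [classify_hybrids(gm, burnin, sweeps, seed=s, n_chains=1)
                for s in seeds]
        stacked = np.stack([r.probs for r in runs])
        probs = stacked.mean(axis=0)
        spread = float((stacked.max(axis=0) - stacked.min(axis=0)).max())
        map_class = [CLASSES[int(np.argmax(row))] for row in probs]
        return HybridPosterior(list(gm.individual_ids), list(gm.populations),
                               probs, map_class, chain_spread=spread)
    g = gm.genotypes
    called = g != MISSING
    gidx = np.where(called, g, 0).astype(np.int64)
    # identifiability requires at least one polymorphic locus
    any_ref = (((g == 0) | (g == 1)) & called).any(axis=0)
    any_alt = (((g == 2) | (g == 1)) & called).any(axis=0)
    if not (any_ref & any_alt).any():
        raise InputError("all loci monomorphic: no information to separate pools")

    n, L = g.shape
    rng = np.random.default_rng(seed)
    arange_l = np.arange(L)

    # --- initialization: leading-eigenvector split into two pools
    x = np.where(called, g, np.nan).astype(float)
    mu = np.nanmean(x, axis=0)
    xc = np.where(called, x - mu, 0.0)
    cov = xc @ xc.T
    evals, evecs = np.linalg.eigh(cov)
    lead = evecs[:, -1]
    pool1 = lead >= np.median(lead)
    z = np.where(pool1, 1, 0)  # class indices: P0=0, P1=1
    alt0 = np.where(~pool1[:, None] & called, g, 0).sum(axis=0)
    ref0 = np.where(~pool1[:, None] & called, 2 - g, 0).sum(axis=0)
    alt1 = np.where(pool1[:, None] & called, g, 0).sum(axis=0)
    ref1 = np.where(pool1[:, None] & called, 2 - g, 0).sum(axis=0)
    theta0 = rng.beta(0.5 + alt0, 0.5 + ref0)
    theta1 = rng.beta(0.5 + alt1, 0.5 + ref1)
    pi = np.full(6, 1.0 / 6.0)

    eps = 1e-12
    occupancy = np.zeros((n, 6))
    w_t = CLASS_WEIGHTS.T  # (3, 6)

    for sweep in range(burnin + sweeps):
        theta0 = np.clip(theta0, eps, 1 - eps)
        theta1 = np.clip(theta1, eps, 1 - eps)
        f = _genotype_tables(theta0, theta1)  # (3, L, 3)

        # per-class genotype mixture tables and log-likelihood per individual
        m = np.einsum("wc,wlg->clg", w_t, f)  # (6, L, 3)
        logm = np.log(np.clip(m, 1e-300, None))
        ll = np.empty((n, 6))
        for c in range(6):
            vals = logm[c][arange_l, gidx]  # (n, L) via broadcast gather
            ll[:, c] = np.where(called, vals, 0.0).sum(axis=1)
        logits = ll + np.log(np.clip(pi, 1e-300, None))
        gumbel = -np.log(-np.log(rng.random((n, 6)) + eps) + eps)
        z = np.argmax(logits + gumbel, axis=1)

        # latent gene-pair origin per (individual, locus)
        fg = f[:, arange_l, :][:, :, :]  # (3, L, 3) -> gather at genotypes
        fgath = fg[:, arange_l[None, :].repeat(n, 0), gidx]  # (3, n, L)
        wz = CLASS_WEIGHTS[z]  # (n, 3)
        probs = wz.T[:, :, None] * fgath  # (3, n, L)
        total = probs.sum(axis=0)
        total = np.clip(total, 1e-300, None)
        u = rng.random((n, L)) * total
        w_idx = (u > probs[0]).astype(np.int8) + (u > probs[0] + probs[1])

        both0 = (w_idx == 0) & called
        mixed = (w_idx == 1) & called
        both1 = (w_idx == 2) & called
        alt0 = (gidx * both0).sum(axis=0).astype(float)
        ref0 = ((2 - gidx) * both0).sum(axis=0).astype(float)
        alt1 = (gidx * both1).sum(axis=0).astype(float)
        ref1 = ((2 - gidx) * both1).sum(axis=0).astype(float)
        hom_ref = mixed & (gidx == 0)
        hom_alt = mixed & (gidx == 2)
        ref0 += hom_ref.sum(axis=0)
        ref1 += hom_ref.sum(axis=0)
        alt0 += hom_alt.sum(axis=0)
        alt1 += hom_alt.sum(axis=0)
        het = mixed & (gidx == 1)
        if het.any():
            # which copy of the heterozygote came from pool 0?
            p_alt0 = theta0 * (1 - theta1)
            denom = p_alt0 + (1 - theta0) * theta1
            prob = p_alt0 / np.clip(denom, 1e-300, None)
            draw = (rng.random((n, L)) < prob[None, :]) & het
            other = het & ~draw
            alt0 += draw.sum(axis=0)
            ref1 += draw.sum(axis=0)
            ref0 += other.sum(axis=0)
            alt1 += other.sum(axis=0)

        theta0 = rng.beta(0.5 + alt0, 0.5 + ref0)
        theta1 = rng.beta(0.5 + alt1, 0.5 + ref1)
        pi = rng.dirichlet(0.5 + np.bincount(z, minlength=6))

        if sweep >= burnin:
            occupancy[np.arange(n), z] += 1.0

    probs = occupancy / sweeps
    if probs[0, 1] > probs[0, 0]:  # anchor pool 0 to the first individual
        probs = probs[:, _SWAP]
    map_class = [CLASSES[int(np.argmax(row))] for row in probs]
    return HybridPosterior(list(gm.individual_ids), list(gm.populations),
                           probs, map_class)


def assignment_table(posterior: HybridPosterior) -> pd.DataFrame:
    """Group individuals by population and MAP class with counts and mean
    posteriors (one row per population x class, deterministic order)."""
    df = posterior.to_dataframe()
    rows = []
    for (pop, cls), grp in df.groupby(["population", "map_class"], sort=False):
        ids = ", ".join(sorted(grp["id"]))
        row = {"ids": ids, "population": pop, "count": len(grp), "map_class": cls}
        for c in CLASSES:
            row[c] = float(grp[c].mean())
        rows.append(row)
    out = pd.DataFrame(rows)
    class_rank = {c: i for i, c in enumerate(CLASSES)}
    out = out.sort_values(["map_class", "population", "ids"],
                          key=lambda s: s.map(class_rank) if s.name == "map_class" else s)
    return out.reset_index(drop=True)


def hybrid_flags(posterior: HybridPosterior, threshold: float = 0.5) -> list:
    """Individuals whose combined non-parental posterior exceeds ``threshold``
    (used to exclude putative hybrids before delimitation)."""
    non_parental = posterior.probs[:, 2:].sum(axis=1)
    return [i for i, v in zip(posterior.individual_ids, non_parental)
            if v > threshold]
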