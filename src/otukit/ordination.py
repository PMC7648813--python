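"""Principal coordinates analysis (classical MDS) of inter-individual genetic distance.

Distances are Euclidean on allele dosages rescaled to [0, 1] (genotype / 2),
computed pairwise-complete with a sqrt(L / L_shared) correction for missing
data.  PCoA double-centres -0.5 * D^2 and eigendecomposes; negative
eigenvalues (possible for non-Euclidean corrected distances) are reported but
excluded from the percent-variance denominator.  Axis signs are fixed
deterministically: the largest-magnitude loading on each axis is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .snp_data import MISSING, GenotypeMatrix, InputError


@dataclass
class OrdinationResult:
    coordinates: np.ndarray        # individuals x k
    eigenvalues: np.ndarray        # all eigenvalues, non-increasing
    percent_variance: np.ndarray   # per retained axis, % of positive mass
    individual_ids: list
    populations: list

    def to_dataframe(self) -> pd.DataFrame:
        k = self.coordinates.shape[1]
        df = pd.DataFrame(self.coordinates,
                          columns=[f"PCo{i + 1}" for i in range(k)])
        df.insert(0, "id", self.individual_ids)
        df.insert(1, "population", self.populations)
        return df


def genetic_distance(gm: GenotypeMatrix, method: str = "euclidean_genotype") -> np.ndarray:
    """Pairwise individual distance matrix on the allele-dosage scale.

    For individuals a, b with L total loci and L_shared loci called in both:

        d(a, b) = sqrt(L / L_shared) * sqrt( sum_shared ((g_a - g_b) / 2)^2 )

    Raises an error naming the pair if some pair shares zero called loci.
    """
    if method != "euclidean_genotype":
        raise InputError(f"unknown distance method '{method}'")
    if gm.n_individuals < 2:
        raise InputError("need at least 2 individuals for a distance matrix")
    g = gm.genotypes.astype(float) / 2.0
    called = gm.called().astype(float)
    g0 = np.where(gm.called(), g, 0.0)
    # sum over shared loci of (ga - gb)^2, expanded into matrix products so
    # missing entries drop out exactly
    sq = g0 ** 2
    shared = called @ called.T
    cross = g0 @ g0.T
    a2 = sq @ called.T
    b2 = called @ sq.T
    d2 = a2 + b2 - 2.0 * cross
    np.fill_diagonal(d2, 0.0)
    if (shared <= 0).any():
        i, j = np.argwhere(shared <= 0)[0]
        raise InputError(
            f"individuals '{gm.individual_ids[i]}' and '{gm.individual_ids[j]}' "
            "share zero called loci")
    d2 = np.clip(d2, 0.0, None) * (gm.n_loci / shared)
    d = np.sqrt(d2)
    return (d + d.T) / 2.0


def pcoa(distances: np.ndarray, k: int = 2,
         individual_ids=None, populations=None) -> OrdinationResult:
    """Classical scaling of a distance matrix.

    Returns the first ``k`` axes with positive eigenvalues; percent variance
    is normalized over the positive eigenvalue mass only.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise InputError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise InputError("distance matrix must be symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    positive = evals > max(1e-10, 1e-12 * abs(evals[0]) if n else 0)
    pos_mass = evals[positive].sum()
    k_eff = min(k, int(positive.sum()))
    coords = evecs[:, :k_eff] * np.sqrt(evals[:k_eff])
    # deterministic sign: largest-|loading| entry positive per axis
    for a in range(k_eff):
        col = coords[:, a]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, a] = -col
    percent = 100.0 * evals[:k_eff] / pos_mass if pos_mass > 0 else np.zeros(k_eff)
    ids = list(individual_ids) if individual_ids is not None else list(range(n))
    pops = list(populations) if populations is not None else ["unassigned"] * n
    return OrdinationResult(coords, evals, percent, ids, pops)


def pcoa_genotypes(gm: GenotypeMatrix, k: int = 2) -> OrdinationResult:
    """Convenience: distance + PCoA on a genotype matrix."""
    return pcoa(genetic_distance(gm), k,
                individual_ids=gm.individual_ids, populations=gm.populations)


def scree(result: OrdinationResult) -> pd.DataFrame:
    """Scree table over the positive-eigenvalue axes.

    Columns: axis, eigenvalue, percent, cumulative (cumulative ends at 100).
    """
    evals = result.eigenvalues
    pos = evals[evals > 0]
    total = pos.sum()
    percent = 100.0 * pos / total if total > 0 else np.zeros_like(pos)
    return pd.DataFrame({
        "axis": np.arange(1, len(pos) + 1),
        "eigenvalue": pos,
        "percent": percent,
        "cumulative": np.cumsum(percent),
    })


def plot_ordination(result: OrdinationResult, path) -> None:
    """Scatter of the first two axes coloured by population label."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    pops = np.asarray(result.populations)
    for pop in sorted(set(result.populations)):
        mask = pops == pop
        ax.scatter(result.coordinates[mask, 0], result.coordinates[mask, 1],
                   label=pop, s=25)
    ax.set_xlabel(f"PCo1 ({result.percent_variance[0]:.1f}%)")
    if result.coordinates.shape[1] > 1:
        ax.set_ylabel(f"PCo2 ({result.percent_variance[1]:.1f}%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
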