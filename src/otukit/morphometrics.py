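"""Morphometric analysis: regional summaries, sex screening, Tukey-Kramer,
CVA and PCA.

The schema is one row per adult individual with eight measured traits:
mass (kg), head length (mm), head width (mm), body length (cm), tail length
(cm), knee-to-heel (mm), ear length (mm) and ear width (mm), plus id, site,
region, sex.  Sites map onto three regions (Taravale/Blackbraes -> Northern,
Redcliffe Vale -> Central, Bendoc/Wombat -> Southern).

Sex effects are screened per trait with linear models on unbalanced data
(region + sex + region:sex) and backward elimination, interaction first, at
alpha = 0.05.  Region comparisons use the Tukey-Kramer studentized-range test
with pooled within-group variance, valid for unequal group sizes; the sign of
a difference is first-listed minus second-listed group in the canonical order
Northern, Central, Southern.  Group structure is summarized by canonical
variate analysis (between-group scatter in the metric of the pooled
within-group covariance) and correlation-matrix PCA (traits mix kg/cm/mm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.stats import studentized_range

from .snp_data import InputError

TRAITS: tuple = ("mass", "head_length", "head_width", "body_length",
                 "tail_length", "knee_to_heel", "ear_length", "ear_width")

REGIONS: tuple = ("Northern", "Central", "Southern")

SITE_REGION = {
    "Taravale": "Northern",
    "Blackbraes": "Northern",
    "RedcliffeVale": "Central",
    "Redcliffe Vale": "Central",
    "Bendoc": "Southern",
    "Wombat": "Southern",
}


def validate_morph(morph: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("id", "region") + TRAITS if c not in morph.columns]
    if missing:
        raise InputError(f"morphometrics table lacks columns {missing}")
    bad = morph[list(TRAITS)].le(0).any(axis=1)
    if bad.any():
        raise InputError(f"non-positive trait values for ids "
                         f"{morph.loc[bad, 'id'].tolist()}")
    if "adult" in morph.columns:
        morph = morph[morph["adult"].astype(bool)]
    return morph.reset_index(drop=True)


def region_summary(morph: pd.DataFrame) -> pd.DataFrame:
    """Per-region N, mean and SD for every trait (sample SD, ddof = 1)."""
    morph = validate_morph(morph)
    regions = [r for r in REGIONS if r in set(morph["region"])]
    if not regions:
        raise InputError("no recognised regions in morphometrics table")
    rows = []
    for region in regions:
        sub = morph[morph["region"] == region]
        if len(sub) < 2:
            raise InputError(f"region '{region}' has fewer than 2 individuals")
        row = {"region": region, "N": len(sub)}
        for t in TRAITS:
            row[f"{t}_mean"] = float(sub[t].mean())
            row[f"{t}_sd"] = float(sub[t].std(ddof=1))
        rows.append(row)
    return pd.DataFrame(rows)


def sex_effect_screen(morph: pd.DataFrame, alpha: float = 0.05,
                      traits=None) -> dict:
    """Backward elimination of trait ~ region + sex + region:sex per trait.

    The interaction is considered first; the least significant term with
    p > alpha is dropped iteratively (type-II ANOVA on unbalanced data).
    Returns per trait the retained terms and their final F/p statistics.
    Skipped with a warning if one sex is absent.  Note the compound nature of
    the screen: "any sex term retained" happens at roughly twice the nominal
    alpha (the interaction and the main effect each get a look); the main
    effect alone, with the interaction eliminated, is calibrated near alpha.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    morph = validate_morph(morph)
    if "sex" not in morph.columns or morph["sex"].nunique() < 2:
        warnings.warn("sex screen skipped: fewer than two sexes present",
                      stacklevel=2)
        return {}
    out = {}
    for trait in (traits if traits is not None else TRAITS):
        terms = ["C(region)", "C(sex)", "C(region):C(sex)"]
        df = morph[[trait, "region", "sex"]].dropna()
        if df[trait].std(ddof=1) < 1e-12 * max(1.0, abs(df[trait].mean())):
            warnings.warn(f"sex screen skipped for trait '{trait}': "
                          "degenerate (constant) values", stacklevel=2)
            continue
        try:
            while True:
                formula = f"{trait} ~ " + " + ".join(terms)
                fit = smf.ols(formula, data=df).fit()
                anova = sm.stats.anova_lm(fit, typ=2)
                anova = anova.drop(index="Residual", errors="ignore")
                # interaction is only droppable first; main effects stay while
                # the interaction containing them is present
                droppable = [t for t in terms if ":" in t] or list(terms)
                pvals = {t: anova.loc[t, "PR(>F)"] for t in droppable
                         if t in anova.index}
                worst = max(pvals, key=pvals.get) if pvals else None
                if worst is None or pvals[worst] <= alpha or len(terms) == 0:
                    stats = {t: (float(anova.loc[t, "F"]),
                                 float(anova.loc[t, "PR(>F)"]))
                             for t in terms if t in anova.index}
                    out[trait] = {"terms": list(terms), "stats": stats}
                    break
                terms.remove(worst)
                if not terms:
                    out[trait] = {"terms": [], "stats": {}}
                    break
        except (ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"sex screen skipped for trait '{trait}': {exc}",
                          stacklevel=2)
    return out


@dataclass(frozen=True)
class PairwiseComparison:
    trait: str
    group_a: str
    group_b: str
    diff: float     # mean(a) - mean(b), canonical region order
    se: float
    t_value: float
    p_adj: float


def tukey_kramer(morph: pd.DataFrame, grouping: str = "region") -> list:
    """Tukey-Kramer pairwise comparisons per trait.

    Pooled within-group variance across all groups; SE for the (a, b) pair is
    sqrt(MSE * (1/n_a + 1/n_b)); the adjusted p-value comes from the
    studentized range distribution with q = |diff| * sqrt(2) / SE.  Groups of
    size 1 are excluded with a warning.
    """
    morph = validate_morph(morph)
    results = []
    counts = morph[grouping].value_counts()
    singletons = counts[counts < 2].index.tolist()
    if singletons:
        warnings.warn(f"groups of size 1 excluded: {singletons}", stacklevel=2)
        morph = morph[~morph[grouping].isin(singletons)]
    if grouping == "region":
        groups = [g for g in REGIONS if g in set(morph[grouping])]
    else:
        groups = sorted(set(morph[grouping]))
    if len(groups) < 2:
        raise InputError("need at least 2 groups for pairwise comparisons")
    k = len(groups)
    for trait in TRAITS:
        data = {g: morph.loc[morph[grouping] == g, trait].to_numpy() for g in groups}
        ns = {g: len(v) for g, v in data.items()}
        df_resid = sum(ns.values()) - k
        mse = sum((ns[g] - 1) * np.var(data[g], ddof=1) for g in groups) / df_resid
        for a, b in combinations(groups, 2):
            diff = float(np.mean(data[a]) - np.mean(data[b]))
            se = float(np.sqrt(mse * (1.0 / ns[a] + 1.0 / ns[b])))
            t = diff / se if se > 0 else np.inf * np.sign(diff)
            if se > 0:
                p = float(studentized_range.sf(abs(t) * np.sqrt(2.0), k, df_resid))
            else:
                p = 0.0 if diff != 0 else 1.0
            results.append(PairwiseComparison(trait, a, b, diff, se, float(t),
                                              min(1.0, p)))
    return results


def comparisons_dataframe(comparisons: list) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in comparisons])


@dataclass
class CvaResult:
    scores: np.ndarray        # individuals x n_axes, unit within-group variance
    eigenvalues: np.ndarray
    percent: np.ndarray
    loadings: np.ndarray      # traits x n_axes
    groups: list
    group_labels: list


def cva(morph: pd.DataFrame, grouping: str = "region") -> CvaResult:
    """Canonical variate analysis of the measured traits.

    Eigendecomposition of between-group scatter in the metric of the pooled
    within-group covariance; axes are scaled so within-group variance of the
    scores is 1 and signs fixed so the largest-magnitude loading is positive.
    """
    morph = validate_morph(morph)
    if grouping == "region":
        groups = [g for g in REGIONS if g in set(morph[grouping])]
    else:
        groups = sorted(set(morph[grouping]))
    x = morph[list(TRAITS)].to_numpy(dtype=float)
    labels = morph[grouping].to_numpy()
    n, p = x.shape
    k = len(groups)
    if k < 2:
        raise InputError("need at least 2 groups for CVA")
    if n <= p + k:
        raise InputError("need more individuals than traits + groups for CVA")
    grand = x.mean(axis=0)
    sw = np.zeros((p, p))
    sb = np.zeros((p, p))
    for g in groups:
        xi = x[labels == g]
        ci = xi - xi.mean(axis=0)
        sw += ci.T @ ci
        d = (xi.mean(axis=0) - grand)[:, None]
        sb += len(xi) * (d @ d.T)
    sw /= (n - k)
    try:
        evals, evecs = sla.eigh(sb, sw)
    except sla.LinAlgError as exc:
        raise InputError("singular within-group scatter; reduce the trait set "
                         "or add individuals") from exc
    order = np.argsort(evals)[::-1]
    n_axes = min(k - 1, p)
    evals = np.clip(evals[order][:n_axes], 0.0, None)
    vecs = evecs[:, order][:, :n_axes]  # v' Sw v = 1 by construction
    for a in range(n_axes):
        col = vecs[:, a]
        if col[np.argmax(np.abs(col))] < 0:
            vecs[:, a] = -col
    total = evals.sum()
    percent = 100.0 * evals / total if total > 0 else np.zeros(n_axes)
    scores = (x - grand) @ vecs
    return CvaResult(scores, evals, percent, vecs, groups, labels.tolist())


@dataclass
class MorphPcaResult:
    scores: np.ndarray
    percent: np.ndarray
    loadings: np.ndarray
    n_dropped: int


def pca_morph(morph: pd.DataFrame) -> MorphPcaResult:
    """Correlation-matrix PCA of the traits (rows with missing traits dropped)."""
    morph = validate_morph(morph)
    complete = morph.dropna(subset=list(TRAITS))
    n_dropped = len(morph) - len(complete)
    x = complete[list(TRAITS)].to_numpy(dtype=float)
    if x.shape[0] < 3:
        raise InputError("need at least 3 complete rows for PCA")
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).all():
        raise InputError("all traits have zero variance")
    if (sd == 0).any():
        raise InputError("a trait has zero variance; drop it before PCA")
    z = (x - x.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    var = s ** 2
    percent = 100.0 * var / var.sum()
    scores = u * s
    loadings = vt.T
    for a in range(loadings.shape[1]):
        col = loadings[:, a]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, a] = -col
            scores[:, a] = -scores[:, a]
    return MorphPcaResult(scores, percent, loadings, n_dropped)
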