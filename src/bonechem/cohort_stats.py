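"""Descriptive and inferential statistics over the cohort feature table.

Implements the study's statistical protocol: per-feature normality and
homoscedasticity gating (Shapiro-Wilk, Levene) choosing between Welch's
ANOVA and the Kruskal-Wallis test, pairwise Wilcoxon rank-sum tests with
multiplicity adjustment, the pooled Pearson correlation matrix,
greedy correlation-threshold feature pruning, and PCA on the correlation
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.oneway import anova_oneway

__all__ = [
    "GroupComparison",
    "PCAResult",
    "DEFAULT_DROP",
    "select_global_test",
    "group_comparison",
    "pairwise_wilcoxon",
    "correlation_matrix",
    "prune_correlated",
    "pca",
    "summarise_units",
]

#: variables excluded before model fitting in the reference protocol
#: (highly correlated, low component-space contribution, or exclusive to
#: some assemblages)
DEFAULT_DROP = (
    "AmideI_PO4", "IRSF", "C_P", "Calcite_PO4", "OH_PO4", "C_C",
    "FWHM_v3PO4", "a_axis", "c_axis",
)

ALPHA = 0.05


def _groups(table: pd.DataFrame, feature, group_col="unit"):
    out = [
        (label, grp[feature].to_numpy(dtype=float))
        for label, grp in table.groupby(group_col, sort=True, observed=True)
    ]
    if len(out) < 2:
        raise ValueError("need at least 2 groups")
    for label, x in out:
        if x.size < 3:
            raise ValueError(f"group {label!r} has fewer than 3 samples")
    return out


@dataclass
class GroupComparison:
    feature: str
    global_test: str
    global_stat: float
    global_p: float
    pairwise: pd.DataFrame  # symmetric matrix of adjusted p-values
    adjustment: str = "holm"
    gating: dict = field(default_factory=dict)


@dataclass
class PCAResult:
    loadings: pd.DataFrame  # variables x components, orthonormal columns
    variance_share: np.ndarray
    scores: np.ndarray


def select_global_test(table, feature, group_col="unit", alpha=ALPHA):
    """Choose the global location test for one feature.

    Welch's ANOVA when every group passes Shapiro-Wilk normality at
    ``alpha``; the Kruskal-Wallis rank test otherwise. Levene's
    homoscedasticity check is recorded alongside (Welch's ANOVA does not
    assume equal variances). Returns (test_name, gating_record).
    """
    groups = _groups(table, feature, group_col)
    arrays = [x for _, x in groups]
    if any(np.ptp(x) == 0 for x in arrays):
        raise ValueError(f"feature {feature!r} is constant within a group")
    shapiro_p = {label: float(stats.shapiro(x).pvalue) for label, x in groups}
    levene_p = float(stats.levene(*arrays, center="median").pvalue)
    all_normal = all(p > alpha for p in shapiro_p.values())
    name = "welch_anova" if all_normal else "kruskal_wallis"
    return name, {"shapiro_p": shapiro_p, "levene_p": levene_p, "rule": name}


def pairwise_wilcoxon(table, feature, adjust="holm", group_col="unit") -> GroupComparison:
    """All-pairs two-sided Wilcoxon rank-sum tests, multiplicity adjusted.

    Uses the normal approximation with tie correction (appropriate at the
    cohort's per-unit sample sizes). Also runs the gated global test and
    stores it on the returned comparison.
    """
    groups = _groups(table, feature, group_col)
    labels = [label for label, _ in groups]
    name, gating = select_global_test(table, feature, group_col)
    arrays = [x for _, x in groups]
    if name == "welch_anova":
        res = anova_oneway(arrays, use_var="unequal", welch_correction=True)
        gstat, gp = float(res.statistic), float(res.pvalue)
    else:
        gstat, gp = (float(v) for v in stats.kruskal(*arrays))

    pairs, raw = [], []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            p = stats.mannwhitneyu(
                arrays[i], arrays[j], alternative="two-sided", method="asymptotic"
            ).pvalue
            pairs.append((i, j))
            raw.append(float(p))
    adjusted = multipletests(raw, method=adjust)[1] if raw else raw
    mat = pd.DataFrame(np.eye(len(labels)) * np.nan, index=labels, columns=labels)
    for (i, j), p in zip(pairs, adjusted):
        mat.iloc[i, j] = mat.iloc[j, i] = min(float(p), 1.0)
    return GroupComparison(feature, name, gstat, gp, mat, adjust, gating)


def correlation_matrix(table, variables=None) -> pd.DataFrame:
    """Pooled (all-sample) Pearson correlation matrix."""
    variables = variables or [
        c for c in table.columns if c not in ("sample_id", "unit")
    ]
    if len(table) < 3:
        raise ValueError("need at least 3 samples")
    return table[variables].corr(method="pearson")


def prune_correlated(table, threshold=0.75, keep=(), drop=DEFAULT_DROP):
    """Greedy correlation-threshold pruning of the feature table.

    The explicit ``drop`` list is applied first (defaults to the study's
    exclusions). Then, while any remaining pair has |r| >= threshold, the
    member with the larger mean absolute correlation is removed.
    Variables in ``keep`` are never dropped. Returns (reduced table,
    audit log of removals).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    conflict = set(keep) & set(drop)
    if conflict:
        raise ValueError(f"variables in both keep and drop: {sorted(conflict)}")
    meta = [c for c in ("sample_id", "unit") if c in table.columns]
    variables = [c for c in table.columns if c not in meta]
    audit = []
    for v in drop:
        if v in variables:
            variables.remove(v)
            audit.append({"removed": v, "reason": "explicit drop list"})
    while True:
        corr = table[variables].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        pairs = corr.stack()
        offending = pairs[pairs >= threshold]
        offending = offending[
            ~offending.index.map(lambda ij: ij[0] in keep and ij[1] in keep)
        ]
        if offending.empty:
            break
        va, vb = max(offending.index, key=lambda ij: offending[ij])
        mean_abs = corr.mean()
        cand = [v for v in (va, vb) if v not in keep]
        if not cand:
            break
        victim = max(cand, key=lambda v: mean_abs[v])
        variables.remove(victim)
        audit.append(
            {
                "removed": victim,
                "reason": f"|r({va},{vb})| = {pairs[(va, vb)]:.3f} >= {threshold}",
            }
        )
    return table[meta + variables], audit


def pca(table, variables=None) -> PCAResult:
    """PCA on centred, unit-variance data (correlation-matrix eigenvectors).

    Sign convention: each component's largest-magnitude loading is
    positive. Variance shares sum to 1.
    """
    variables = variables or [
        c for c in table.columns if c not in ("sample_id", "unit")
    ]
    if len(variables) < 2:
        raise ValueError("need at least 2 variables")
    X = table[variables].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [v for v, s in zip(variables, sd) if s == 0]
        raise ValueError(f"zero-variance variables: {bad}")
    Z = (X - X.mean(axis=0)) / sd
    corr = np.corrcoef(Z, rowvar=False)
    vals, vecs = np.linalg.eigh(corr)
    order = np.argsort(vals)[::-1]
    vals, vecs = np.clip(vals[order], 0.0, None), vecs[:, order]
    for j in range(vecs.shape[1]):
        if vecs[np.argmax(np.abs(vecs[:, j])), j] < 0:
            vecs[:, j] = -vecs[:, j]
    loadings = pd.DataFrame(
        vecs, index=variables, columns=[f"PC{i + 1}" for i in range(len(vals))]
    )
    return PCAResult(loadings, vals / vals.sum(), Z @ vecs)


def summarise_units(table, group_col="unit"):
    """Mean +/- SD per unit for every feature column."""
    feats = [c for c in table.columns if c not in ("sample_id", group_col)]
    g = table.groupby(group_col, sort=True, observed=True)[feats]
    return g.mean(), g.std(ddof=1)
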