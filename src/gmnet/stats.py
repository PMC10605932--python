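"""Group inference for network metrics: ANOVA/ANCOVA with LSD post hocs,
chi-square tests, Pearson/partial correlations and Benjamini-Hochberg FDR.

Conventions mirror a standard three-group neuroimaging analysis: a linear
model with group indicators plus nuisance covariates (age, sex, education,
total intracranial volume), an omnibus F-test on the group indicators, and
least-significant-difference (LSD) pairwise contrasts — unadjusted pairwise
t-tests on the pooled residual error term. Brain-cognition associations are
reported both as plain Pearson correlations and as covariate-partial
correlations, with BH-FDR control applied within each group's family of
(metric x score) pairs. All tests are two-sided; significance is declared at
p < 0.05.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupStatsResult",
    "CorrelationResult",
    "one_way_anova_lsd",
    "ancova_group_test",
    "chi_square_independence",
    "correlation",
    "fdr_adjust",
    "run_metric_comparisons",
    "correlation_table",
    "DEFAULT_COVARIATES",
]

DEFAULT_COVARIATES = ("age", "sex", "education", "tiv")

ALPHA = 0.05


@dataclass
class GroupStatsResult:
    """Omnibus F/p plus LSD pairwise p-values for one outcome."""

    outcome: str
    F: float
    p: float
    df: tuple  # (df_between, df_within)
    pairwise: dict  # (groupA, groupB) -> p, unadjusted
    group_means: dict  # adjusted means per group
    covariates: tuple = ()
    flags: tuple = ()


@dataclass
class CorrelationResult:
    metric: str
    score: str
    group: str
    r: float
    p: float
    kind: str  # "pearson" | "partial"
    n: int
    q: float | None = None  # FDR-adjusted p, filled by the family procedure


def _split_groups(values, groups):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and group labels must align")
    levels = sorted(pd.unique(groups).tolist())
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    parts = {g: values[groups == g] for g in levels}
    for g, v in parts.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    return levels, parts


def one_way_anova_lsd(values, groups, outcome: str = "") -> GroupStatsResult:
    """Classical one-way ANOVA with LSD pairwise comparisons.

    The LSD tests are pairwise t-tests whose standard error uses the pooled
    within-group mean square from the omnibus model, with its residual
    degrees of freedom; p-values are unadjusted (the definition of LSD).
    """
    levels, parts = _split_groups(values, groups)
    n_total = sum(v.size for v in parts.values())
    grand = np.concatenate(list(parts.values())).mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in parts.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in parts.values())
    df_b, df_w = len(levels) - 1, n_total - len(levels)
    flags = []
    if ss_within == 0.0:
        if ss_between == 0.0:
            flags.append("degenerate-constant")
            F, p = float("nan"), float("nan")
        else:
            flags.append("zero-within-variance")
            F, p = float("inf"), 0.0
        ms_w = 0.0
    else:
        ms_w = ss_within / df_w
        F = (ss_between / df_b) / ms_w
        p = float(sps.f.sf(F, df_b, df_w))
    pairwise = {}
    for a, b in itertools.combinations(levels, 2):
        va, vb = parts[a], parts[b]
        if ms_w == 0.0:
            pairwise[(a, b)] = (float("nan") if va.mean() == vb.mean() else 0.0)
            continue
        se = np.sqrt(ms_w * (1 / va.size + 1 / vb.size))
        t = (va.mean() - vb.mean()) / se
        pairwise[(a, b)] = float(2 * sps.t.sf(abs(t), df_w))
    return GroupStatsResult(
        outcome=outcome, F=float(F), p=p, df=(df_b, df_w), pairwise=pairwise,
        group_means={g: float(v.mean()) for g, v in parts.items()},
        flags=tuple(flags))


def ancova_group_test(values, groups, covariates, outcome: str = "") -> GroupStatsResult:
    """Covariate-adjusted three-group comparison (ANCOVA) with LSD post hocs.

    Fits ``outcome ~ group indicators + covariates`` by OLS, tests the group
    indicators jointly with a partial F-test against the covariates-only
    model, and reports unadjusted pairwise contrasts of covariate-adjusted
    group means on the residual error term. Covariates with zero variance are
    dropped (they are collinear with the intercept), which also makes the
    test collapse exactly onto the one-way ANOVA when no informative
    covariates remain.
    """
    levels, parts = _split_groups(values, groups)
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    cov = pd.DataFrame(covariates).reset_index(drop=True)
    if len(cov) != values.size:
        raise ValueError("covariates must have one row per observation")
    flags = []
    keep = []
    for c in cov.columns:
        if np.ptp(cov[c].to_numpy(dtype=float)) == 0:
            flags.append(f"dropped-constant-covariate:{c}")
        else:
            keep.append(c)
    cov = cov[keep]
    dummies = np.column_stack([(groups == g).astype(float) for g in levels[1:]])
    X_cov = np.column_stack([np.ones(values.size), cov.to_numpy(dtype=float)]) \
        if keep else np.ones((values.size, 1))
    X_full = np.column_stack([X_cov, dummies])
    if X_full.shape[0] <= X_full.shape[1]:
        raise ValueError("more parameters than observations")
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("rank-deficient design matrix (collinear covariates?)")
    full = sm.OLS(values, X_full).fit()
    reduced = sm.OLS(values, X_cov).fit()
    df_b = len(levels) - 1
    df_w = int(full.df_resid)
    if full.ssr == 0.0:
        flags.append("zero-within-variance")
        F, p = float("inf"), 0.0
    else:
        F = ((reduced.ssr - full.ssr) / df_b) / (full.ssr / df_w)
        p = float(sps.f.sf(F, df_b, df_w))
    # adjusted means: prediction at covariate means, per group
    n_cov = X_cov.shape[1]
    base = np.zeros(X_full.shape[1])
    base[0] = 1.0
    if n_cov > 1:
        base[1:n_cov] = cov.to_numpy(dtype=float).mean(axis=0)
    group_rows = {}
    for gi, g in enumerate(levels):
        row = base.copy()
        if gi > 0:
            row[n_cov + gi - 1] = 1.0
        group_rows[g] = row
    adj_means = {g: float(row @ full.params) for g, row in group_rows.items()}
    pairwise = {}
    for a, b in itertools.combinations(levels, 2):
        contrast = group_rows[a] - group_rows[b]
        tt = full.t_test(contrast)
        pairwise[(a, b)] = float(tt.pvalue)
    return GroupStatsResult(
        outcome=outcome, F=float(F), p=p, df=(df_b, df_w), pairwise=pairwise,
        group_means=adj_means, covariates=tuple(keep), flags=tuple(flags))


def chi_square_independence(table) -> dict:
    """Pearson chi-square test of independence (no continuity correction)."""
    table = np.asarray(table)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(table < 0) or np.any(table != np.round(table)):
        raise ValueError("contingency table must hold non-negative counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table has an empty row or column")
    res = sps.chi2_contingency(table, correction=False)
    return {"chi2": float(res.statistic), "df": int(res.dof),
            "p": float(res.pvalue)}


def _residualize(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def correlation(x, y, covariates=None, metric: str = "", score: str = "",
                group: str = "") -> CorrelationResult:
    """Pearson correlation, or partial correlation given covariates.

    The partial correlation residualizes both variables on the covariates
    (with intercept) and correlates the residuals; its p-value uses
    ``n - 2 - k`` degrees of freedom for ``k`` covariates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if covariates is None:
        if x.size < 3:
            raise ValueError("need n >= 3 for a correlation")
        if x.std() == 0 or y.std() == 0:
            raise ValueError("zero variance in x or y")
        r, p = sps.pearsonr(x, y)
        return CorrelationResult(metric, score, group, float(r), float(p),
                                 "pearson", x.size)
    Z = np.column_stack([np.ones(x.size),
                         np.asarray(pd.DataFrame(covariates), dtype=float)])
    k = Z.shape[1] - 1
    dof = x.size - 2 - k
    if dof < 1:
        raise ValueError("too few observations for a partial correlation")
    rx, ry = _residualize(x, Z), _residualize(y, Z)
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("zero variance after residualizing on covariates")
    r = float(np.corrcoef(rx, ry)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(dof / (1 - r ** 2))
        p = float(2 * sps.t.sf(abs(t), dof))
    return CorrelationResult(metric, score, group, r, p, "partial", x.size)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_metric_comparisons(global_auc: pd.DataFrame, nodal_auc: pd.DataFrame,
                           groups, covariates, region_table=None,
                           alpha: float = ALPHA) -> pd.DataFrame:
    """ANCOVA + LSD for every global metric and every region's BC AUC.

    Produces a long table analogous to the global-property and nodal-change
    tables of a three-group network study: one row per outcome with adjusted
    group means, omnibus F/p, the three pairwise LSD p-values, and (for nodal
    outcomes) the region's functional-module label.
    """
    groups = np.asarray(groups)
    rows = []
    module_of = {}
    if nodal_auc is not None:
        if region_table is None:
            from .regions import aal90_table

            region_table = aal90_table()
        module_of = dict(zip(region_table["abbreviation"],
                             region_table["functional_module"]))
    blocks = [("global", global_auc)]
    if nodal_auc is not None:
        blocks.append(("nodal", nodal_auc))
    for kind, frame in blocks:
        for col in frame.columns:
            res = ancova_group_test(frame[col].to_numpy(dtype=float), groups,
                                    covariates, outcome=str(col))
            row = {"outcome": str(col), "kind": kind,
                   "module": module_of.get(col, ""),
                   "F": res.F, "p": res.p,
                   "significant": bool(res.p < alpha)}
            for g, m in res.group_means.items():
                row[f"adj_mean[{g}]"] = m
                row[f"sd[{g}]"] = float(frame[col].to_numpy(dtype=float)
                                        [groups == g].std(ddof=1))
            for (a, b), pv in res.pairwise.items():
                row[f"p[{a} vs {b}]"] = pv
            rows.append(row)
    return pd.DataFrame(rows)


def correlation_table(metrics: pd.DataFrame, scores: pd.DataFrame, groups,
                      covariates=None, alpha: float = ALPHA) -> pd.DataFrame:
    """Brain-cognition correlations per group, FDR-controlled per family.

    For every group, computes plain Pearson and covariate-partial
    correlations over the full (metric x score) grid; BH-FDR is applied
    within each (group, kind) family. Returns a long DataFrame.
    """
    groups = np.asarray(groups)
    covariates = None if covariates is None else pd.DataFrame(covariates)
    out = []
    for g in sorted(pd.unique(groups).tolist()):
        mask = groups == g
        for kind in ("pearson", "partial"):
            fam = []
            for metric in metrics.columns:
                for score in scores.columns:
                    cov = None
                    if kind == "partial":
                        cov = covariates.loc[mask] if covariates is not None else None
                        if cov is None:
                            continue
                        cov = cov.loc[:, cov.nunique() > 1]
                    fam.append(correlation(
                        metrics.loc[mask, metric].to_numpy(dtype=float),
                        scores.loc[mask, score].to_numpy(dtype=float),
                        covariates=cov, metric=str(metric), score=str(score),
                        group=str(g)))
            if not fam:
                continue
            qs = fdr_adjust([c.p for c in fam])
            for c, q in zip(fam, qs):
                c.q = float(q)
            out.extend(fam)
    return pd.DataFrame([{
        "group": c.group, "metric": c.metric, "score": c.score, "kind": c.kind,
        "r": c.r, "p": c.p, "q": c.q, "n": c.n,
        "significant_fdr": bool(c.q is not None and c.q < alpha),
    } for c in out])
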