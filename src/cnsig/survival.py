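"""Outcome association: Kaplan-Meier/log-rank, Cox regression, and the
categorical / rank / correlation tests used to relate subgroups, exposures
and clinical covariates.

The cohort table is a plain DataFrame ("CohortFrame") with one row per
sample: a follow-up time column (months), boolean event flags per endpoint
(e.g. overall death, cancer-specific death, metastasis), and categorical /
numeric covariates. Cox models use Efron tie handling; all p-values are
two-sided and reported uncorrected (a Benjamini-Hochberg helper is
provided but off by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = [
    "km_logrank",
    "cox_fit",
    "categorical_assoc",
    "rank_assoc",
    "exposure_activity_correlation",
    "benjamini_hochberg",
    "KMResult",
    "CoxResult",
]


@dataclass
class KMResult:
    curves: dict[str, pd.DataFrame]  # group -> (timeline, survival, at risk)
    statistic: float
    p_value: float
    medians: dict[str, float]

    def survival_at(self, t: float) -> dict[str, float]:
        """KM survival estimate of each group at time t."""
        out = {}
        for g, curve in self.curves.items():
            s = curve[curve["time"] <= t]["survival"]
            out[g] = float(s.iloc[-1]) if len(s) else 1.0
        return out


def km_logrank(frame: pd.DataFrame, group_column: str, time_column: str,
               event_column: str) -> KMResult:
    """Per-group Kaplan-Meier curves and the k-group log-rank test."""
    sub = frame.dropna(subset=[group_column, time_column, event_column])
    groups = sub[group_column].unique()
    if len(groups) < 2:
        raise ValueError("log-rank requires >= 2 non-empty groups")
    curves = {}
    medians = {}
    for g in groups:
        gsub = sub[sub[group_column] == g]
        if gsub[event_column].sum() == 0:
            warnings.warn(f"group {g!r}: zero events; KM curve is flat", stacklevel=2)
        kmf = KaplanMeierFitter()
        kmf.fit(gsub[time_column], event_observed=gsub[event_column])
        curves[str(g)] = pd.DataFrame({
            "time": kmf.survival_function_.index.to_numpy(),
            "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
        })
        medians[str(g)] = float(kmf.median_survival_time_)
    res = multivariate_logrank_test(sub[time_column], sub[group_column], sub[event_column])
    return KMResult(curves=curves, statistic=float(res.test_statistic),
                    p_value=float(res.p_value), medians=medians)


@dataclass
class CoxResult:
    table: pd.DataFrame  # per covariate: hr, ci_low, ci_high, p, flag
    mode: str
    n: int
    n_events: int

    def summary(self) -> str:
        lines = [f"Cox proportional hazards ({self.mode}); "
                 f"n={self.n}, events={self.n_events}"]
        for cov, row in self.table.iterrows():
            flag = f"  [{row['flag']}]" if row.get("flag") else ""
            lines.append(
                f"  {cov:<28} HR={row['hr']:.3f} "
                f"(95% CI {row['ci_low']:.3f}-{row['ci_high']:.3f}) p={row['p']:.4g}{flag}"
            )
        return "\n".join(lines)


def _fit_one_cox(df: pd.DataFrame, time_column: str, event_column: str,
                 covariates: list[str]) -> pd.DataFrame:
    cph = CoxPHFitter()
    rows = []
    flag = ""
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            cph.fit(df[[time_column, event_column] + covariates],
                    duration_col=time_column, event_col=event_column)
        if any("convergence" in str(w.message).lower()
               or "collinear" in str(w.message).lower() for w in caught):
            flag = "unstable"
    except ConvergenceError as exc:
        return pd.DataFrame(
            {"hr": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
             "flag": f"failed: {type(exc).__name__}"},
            index=covariates,
        )
    s = cph.summary
    for cov in covariates:
        rows.append({
            "hr": float(s.loc[cov, "exp(coef)"]),
            "ci_low": float(s.loc[cov, "exp(coef) lower 95%"]),
            "ci_high": float(s.loc[cov, "exp(coef) upper 95%"]),
            "p": float(s.loc[cov, "p"]),
            "flag": flag,
        })
    return pd.DataFrame(rows, index=covariates)


def cox_fit(frame: pd.DataFrame, covariates: list[str], time_column: str,
            event_column: str, mode: str = "multivariate") -> CoxResult:
    """Cox partial-likelihood fit with Efron ties and Wald intervals.

    ``mode="univariate"`` fits each covariate in its own model;
    ``"multivariate"`` fits them jointly and requires at least as many
    events as covariates. Numerically suspect fits (separation, collinear
    covariates) are flagged "unstable" rather than suppressed.
    """
    sub = frame.dropna(subset=[time_column, event_column] + covariates).copy()
    n_events = int(sub[event_column].sum())
    if mode == "multivariate":
        if n_events < len(covariates):
            raise ValueError(
                f"{n_events} events < {len(covariates)} covariates; "
                "multivariate fit is not identifiable"
            )
        table = _fit_one_cox(sub, time_column, event_column, covariates)
    elif mode == "univariate":
        parts = [_fit_one_cox(sub, time_column, event_column, [c]) for c in covariates]
        table = pd.concat(parts)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return CoxResult(table=table, mode=mode, n=len(sub), n_events=n_events)


def categorical_assoc(frame: pd.DataFrame, label_column: str, covariate: str):
    """Pearson chi-square (no continuity correction) on the contingency table.

    Returns (statistic, p, expected counts DataFrame). Cells with expected
    count below 1 trigger a warning recommending an exact test.
    """
    table = pd.crosstab(frame[label_column], frame[covariate])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has an empty margin")
    stat, p, _, expected = stats.chi2_contingency(table, correction=False)
    expected = pd.DataFrame(expected, index=table.index, columns=table.columns)
    if (expected.values < 1).any():
        warnings.warn(
            "expected count < 1 in the contingency table; "
            "consider an exact test", stacklevel=2,
        )
    return float(stat), float(p), expected


def rank_assoc(frame: pd.DataFrame, group_column: str, value_column: str):
    """Rank-based group comparison.

    Two groups: Wilcoxon rank-sum — the statistic is the rank sum W of the
    first group (average ranks), p from the tie-corrected normal
    approximation. More than two: Kruskal-Wallis H with chi-square p.
    Identical values across all samples give p = 1.
    """
    sub = frame.dropna(subset=[group_column, value_column])
    groups = [g.to_numpy(dtype=float)
              for _, g in sub.groupby(group_column, sort=True)[value_column]]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    values = np.concatenate(groups)
    if np.all(values == values[0]):
        return (float(len(groups[0]) * (len(values) + 1) / 2) if len(groups) == 2 else 0.0, 1.0)
    if len(groups) == 2:
        ranks = stats.rankdata(values)
        n1 = len(groups[0])
        w = float(ranks[:n1].sum())
        res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided",
                                 method="asymptotic")
        return w, float(res.pvalue)
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def exposure_activity_correlation(exposures: pd.DataFrame,
                                  activities: pd.DataFrame) -> pd.DataFrame:
    """Signature-by-activity Spearman matrix on shared samples."""
    shared = exposures.index.intersection(activities.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared samples; need >= 3")
    E = exposures.loc[shared]
    A = activities.loc[shared]
    out = np.zeros((E.shape[1], A.shape[1]))
    for i, sig in enumerate(E.columns):
        for j, act in enumerate(A.columns):
            out[i, j] = stats.spearmanr(E[sig], A[act]).statistic
    return pd.DataFrame(out, index=E.columns, columns=A.columns)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH-adjusted p-values (optional; associations are reported raw by default)."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    prev = 1.0
    for rank_i, idx in list(enumerate(order))[::-1]:
        prev = min(prev, p[idx] * n / (rank_i + 1))
        adj[idx] = prev
    return adj
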