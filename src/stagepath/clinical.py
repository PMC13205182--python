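"""Survival and categorical statistics used throughout the pipeline.

Kaplan-Meier curves with the log-rank test, Cox proportional hazards
(Efron tie handling, the common software default), the continuity-
corrected chi-square test for 2x2 tables with Fisher's exact test as the
small-cell alternative, and Benjamini-Hochberg adjustment.  Survival
fitting is delegated to lifelines; the 2x2 corrected chi-square is the
closed Yates formula.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KMResult",
    "km_logrank",
    "cox_ph",
    "chisq_yates",
    "fisher_exact",
    "chisq_or_fisher",
    "bh_adjust",
]


@dataclass
class KMResult:
    curves: dict  # group -> DataFrame(time, survival)
    medians: dict  # group -> median survival (NaN if curve stays above 0.5)
    statistic: float
    p: float
    n_per_group: dict
    events_per_group: dict


def km_logrank(
    records: pd.DataFrame,
    group_col: str,
    time_col: str = "time",
    event_col: str = "event",
) -> KMResult:
    """Product-limit curves per group plus the log-rank comparison.

    Needs at least two groups; a group with no events triggers a warning
    but the test is still computed when events exist elsewhere.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    groups = records[group_col].unique()
    if len(groups) < 2:
        raise ValueError("log-rank comparison needs at least two groups")
    curves, medians, n_per, ev_per = {}, {}, {}, {}
    for g in groups:
        sub = records[records[group_col] == g]
        if sub[event_col].sum() == 0:
            warnings.warn(f"group {g!r} has no events")
        kmf = KaplanMeierFitter()
        kmf.fit(sub[time_col], sub[event_col], label=str(g))
        sf = kmf.survival_function_
        curves[g] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
        medians[g] = float(kmf.median_survival_time_)
        n_per[g] = int(len(sub))
        ev_per[g] = int(sub[event_col].sum())
    if records[event_col].sum() == 0:
        raise ValueError("no events in any group")
    res = multivariate_logrank_test(
        records[time_col], records[group_col], records[event_col]
    )
    return KMResult(
        curves=curves,
        medians=medians,
        statistic=float(res.test_statistic),
        p=float(res.p_value),
        n_per_group=n_per,
        events_per_group=ev_per,
    )


def cox_ph(
    records: pd.DataFrame,
    covariates: list[str],
    time_col: str = "time",
    event_col: str = "event",
) -> pd.DataFrame:
    """Cox proportional-hazards fit; one row per covariate.

    Partial-likelihood maximisation with Efron tie handling; hazard ratio
    and 95% CI from the observed information.  Rank-deficient covariate
    matrices and non-convergence raise with a diagnostic.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    n_events = int(records[event_col].sum())
    if n_events < len(covariates) + 1:
        raise ValueError(
            f"{n_events} events cannot support {len(covariates)} covariates"
        )
    X = records[covariates].to_numpy(dtype=float)
    sds = X.std(axis=0)
    constant = [c for c, s in zip(covariates, sds) if s == 0]
    if constant:
        raise ValueError(f"constant covariate(s): {constant}")
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < len(covariates):
        raise ValueError("covariate matrix is rank deficient (collinear columns)")
    cph = CoxPHFitter()
    try:
        cph.fit(
            records[[time_col, event_col, *covariates]],
            duration_col=time_col,
            event_col=event_col,
        )
    except ConvergenceError as exc:  # pragma: no cover - diagnostic path
        raise ValueError(f"Cox model failed to converge: {exc}") from exc
    summary = cph.summary
    return pd.DataFrame(
        {
            "coef": summary["coef"],
            "hr": summary["exp(coef)"],
            "hr_ci_lower": summary["exp(coef) lower 95%"],
            "hr_ci_upper": summary["exp(coef) upper 95%"],
            "p": summary["p"],
        }
    )


def chisq_yates(table) -> tuple[float, float]:
    """Continuity-corrected chi-square for a 2x2 table.

    statistic = max(|ad - bc| - n/2, 0)^2 * n / (r1 r2 c1 c2), with the
    two-sided p from the 1-df chi-square reference distribution.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("cell counts must be nonnegative")
    a, b = t[0]
    c, d = t[1]
    n = t.sum()
    margins = [a + b, c + d, a + c, b + d]
    if any(m == 0 for m in margins):
        raise ValueError("zero row or column margin")
    num = max(abs(a * d - b * c) - n / 2, 0.0) ** 2 * n
    statistic = num / np.prod(margins)
    return float(statistic), float(stats.chi2.sf(statistic, df=1))


def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table (odds ratio, p)."""
    odds, p = stats.fisher_exact(np.asarray(table), alternative="two-sided")
    return float(odds), float(p)


def chisq_or_fisher(table) -> dict:
    """Corrected chi-square, falling back to Fisher when any expected cell < 5."""
    t = np.asarray(table, dtype=float)
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    if (expected < 5).any():
        odds, p = fisher_exact(t)
        return {"test": "fisher", "statistic": odds, "p": p}
    statistic, p = chisq_yates(t)
    return {"test": "chisq_yates", "statistic": statistic, "p": p}


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]
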