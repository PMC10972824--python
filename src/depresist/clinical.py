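"""Survival and paired-sample contrasts for altered vs unaltered groups.

The survival table carries one row per subject: follow-up time, event flag
(1 = event, 0 = censored) and a binary group flag (altered / unaltered).
The log-rank test and a single-covariate Cox proportional-hazards model
(Efron tie handling by default, Breslow by flag) quantify the contrast as a
p-value and a hazard ratio with its 95% Wald interval.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

logger = logging.getLogger("depresist")


def _check_table(table: pd.DataFrame) -> None:
    for col in ("time", "event", "group"):
        if col not in table.columns:
            raise ValueError(f"survival table missing column {col!r}")
    if not np.isfinite(table["time"]).all():
        raise ValueError("survival times must be finite")
    if table["event"].sum() < 1:
        raise ValueError("at least one event is required")
    if table.groupby("group").size().min() < 1 or table["group"].nunique() != 2:
        raise ValueError("exactly two non-empty groups required")


def log_rank_test(table: pd.DataFrame) -> tuple[float, float]:
    """Mantel-Haenszel log-rank statistic and chi-square(1) p-value."""
    _check_table(table)
    groups = sorted(table["group"].unique())
    a = table[table["group"] == groups[0]]
    b = table[table["group"] == groups[1]]
    res = _ll_logrank(a["time"], b["time"], event_observed_A=a["event"],
                      event_observed_B=b["event"])
    return float(res.test_statistic), float(res.p_value)


def _cox_loglik(beta: float, times: np.ndarray, events: np.ndarray, x: np.ndarray,
                tie_method: str) -> tuple[float, float, float]:
    """Log partial likelihood, gradient and Hessian for one covariate.

    Ties are handled by Efron's correction (each tied event sees the risk-set
    sum minus a growing fraction of the tied-set sum) or Breslow's (full risk
    set for every tied event).
    """
    ll = grad = info = 0.0
    eb = np.exp(beta * x)
    order = np.argsort(-times, kind="stable")  # descending: accumulate risk sets
    t_sorted = times[order]
    s0 = s1 = s2 = 0.0  # risk-set sums of eb, x*eb, x^2*eb
    i = 0
    n = len(times)
    while i < n:
        t = t_sorted[i]
        j = i
        while j < n and t_sorted[j] == t:
            j += 1
        block = order[i:j]
        s0 += eb[block].sum()
        s1 += (x[block] * eb[block]).sum()
        s2 += (x[block] ** 2 * eb[block]).sum()
        dead = block[events[block] == 1]
        d = len(dead)
        if d > 0:
            t0 = eb[dead].sum()
            t1 = (x[dead] * eb[dead]).sum()
            t2 = (x[dead] ** 2 * eb[dead]).sum()
            ll += beta * x[dead].sum()
            grad += x[dead].sum()
            for l in range(d):
                f = l / d if tie_method == "efron" else 0.0
                z0 = s0 - f * t0
                z1 = s1 - f * t1
                z2 = s2 - f * t2
                ll -= np.log(z0)
                grad -= z1 / z0
                info += z2 / z0 - (z1 / z0) ** 2
        i = j
    return ll, grad, info


def cox_hr(
    table: pd.DataFrame, tie_method: str = "efron", ci: float = 0.95,
    max_iter: int = 50, tol: float = 1e-9,
) -> dict:
    """Single-covariate Cox PH fit by Newton-Raphson: HR = exp(beta), Wald CI, p.

    ``tie_method`` is "efron" (default) or "breslow"; the two coincide
    exactly when no event times are tied.  Non-convergence raises with the
    iteration trace; monotone likelihood (complete separation) is flagged
    in the result rather than raised.
    """
    _check_table(table)
    if tie_method not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method {tie_method!r}")
    times = table["time"].to_numpy(dtype=float)
    events = table["event"].to_numpy(dtype=int)
    x = table["group"].to_numpy(dtype=float)
    for g in np.unique(x):
        if events[x == g].sum() < 1:
            logger.warning("cox_hr: no events in group %g; CI will be wide", g)

    beta = 0.0
    trace = []
    converged = False
    for it in range(max_iter):
        ll, grad, neg_hess = _cox_loglik(beta, times, events, x, tie_method)
        trace.append((it, beta, ll, grad))
        if neg_hess <= 0:
            break
        step = grad / neg_hess
        # dampen wild steps to keep the ascent stable
        step = np.clip(step, -2.0, 2.0)
        beta += step
        if abs(step) < tol:
            converged = True
            break
    separated = abs(beta) > 15
    if not converged and not separated:
        raise RuntimeError(f"Cox Newton-Raphson failed to converge; trace={trace}")
    _, _, neg_hess = _cox_loglik(beta, times, events, x, tie_method)
    se = float(1.0 / np.sqrt(neg_hess)) if neg_hess > 0 else np.inf
    z = stats.norm.ppf(1 - (1 - ci) / 2)
    wald = beta / se if se > 0 and np.isfinite(se) else 0.0
    result = {
        "HR": float(np.exp(beta)),
        "ci_low": float(np.exp(beta - z * se)),
        "ci_high": float(np.exp(beta + z * se)),
        "p": float(2 * stats.norm.sf(abs(wald))),
        "beta": float(beta),
        "se": se,
        "separated": bool(separated),
        "n_iter": len(trace),
    }
    if separated:
        logger.warning("cox_hr: monotone likelihood (complete separation); estimate flagged")
    return result


def paired_t_test(values_a, values_b) -> tuple[float, float]:
    """One-sample t on paired differences, two-sided p.

    Zero-variance differences (a perfectly constant shift) have no valid t
    and raise rather than returning an infinite statistic.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("need >= 2 pairs")
    diff = a - b
    if np.allclose(diff, diff[0]) and diff[0] != 0:
        raise ValueError("zero-variance nonzero differences: t undefined")
    res = stats.ttest_rel(a, b)
    t = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(t):  # identical pairs
        return 0.0, 1.0
    return t, p


def recurrence_rate_contrast(outcome, group) -> tuple[dict, float]:
    """Per-group event rates and Fisher's exact p on the 2x2 table.

    ``outcome`` and ``group`` are aligned binary vectors (e.g. recurrence
    yes/no vs expression high/low by a median split chosen upstream).
    """
    y = np.asarray(outcome, dtype=int)
    g = np.asarray(group, dtype=int)
    if y.shape != g.shape:
        raise ValueError("outcome and group must align")
    if len(np.unique(g)) != 2:
        raise ValueError("exactly two groups required")
    table = np.array([
        [np.sum((g == 0) & (y == 1)), np.sum((g == 0) & (y == 0))],
        [np.sum((g == 1) & (y == 1)), np.sum((g == 1) & (y == 0))],
    ])
    rates = {
        "group0": table[0, 0] / table[0].sum() if table[0].sum() else np.nan,
        "group1": table[1, 0] / table[1].sum() if table[1].sum() else np.nan,
    }
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return rates, float(p)


def median_split(values: pd.Series) -> pd.Series:
    """Binary high/low grouping at the median (high = 1, strictly above)."""
    med = values.median()
    return (values > med).astype(int).rename("group")


def km_curve(table: pd.DataFrame, group: int) -> pd.DataFrame:
    """Kaplan-Meier survival curve coordinates for one group (for TSV export)."""
    from lifelines import KaplanMeierFitter

    sub = table[table["group"] == group]
    km = KaplanMeierFitter()
    km.fit(sub["time"], event_observed=sub["event"])
    out = km.survival_function_.reset_index()
    out.columns = ["time", "survival"]
    return out
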