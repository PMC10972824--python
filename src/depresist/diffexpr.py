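"""Differential expression between resistant and sensitive groups.

One inference engine serves both RNA (log2(TPM+1)) and protein (log
intensity) inputs: a two-sample empirical-Bayes moderated t.  Per-gene pooled
variances s^2 are shrunk toward a prior (s0^2, d0) estimated by method of
moments on log s^2 under the scaled-F model — the posterior variance is

    s~^2 = (d0 * s0^2 + d * s^2) / (d0 + d)

and the moderated statistic t~ = logFC / (s~ * sqrt(1/nA + 1/nB)) is referred
to a t distribution on d0 + d degrees of freedom.  d0 -> 0 recovers the
ordinary pooled t; d0 -> inf pins every variance at s0^2.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("depresist")


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior (s0^2, d0) from sample variances.

    Under the hierarchical model s^2 ~ s0^2 * F(df, d0); moments of log s^2
    give d0 via a trigamma inversion and s0^2 from the mean.  Zero or
    non-finite variances are excluded from the fit.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        raise ValueError("need >= 2 positive finite variances to fit the prior")
    z = np.log(s2[ok])
    e = z - special.polygamma(0, df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1)
    resid = e_var - special.polygamma(1, df / 2.0)
    if resid <= 0:
        return float(np.exp(e_mean)), np.inf
    half_d0 = trigamma_inverse(resid)
    d0 = 2.0 * half_d0
    s0_2 = np.exp(e_mean + special.polygamma(0, half_d0) - np.log(half_d0))
    return float(s0_2), float(d0)


def moderated_t_test(
    expression: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> pd.DataFrame:
    """Moderated two-sample t per gene; logFC and t are group_a minus group_b.

    ``expression`` is genes x samples on a log scale.  ``prior_df`` /
    ``prior_var`` override the estimated (d0, s0^2) — 0 gives the ordinary
    pooled t, ``inf`` fixes every variance at s0^2.  Genes with zero variance
    in both groups get p = 1 and a flag; they never enter the prior fit.
    """
    a = expression[list(group_a)].to_numpy(dtype=float)
    b = expression[list(group_b)].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError(f"need >= 2 samples per group, got {na} and {nb}")
    d = na + nb - 2
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    logfc = mean_a - mean_b
    ss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + ((b - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / d
    zero_var = s2 <= 0

    if prior_df is None or prior_var is None:
        if np.all(zero_var):
            raise ValueError("all genes have zero variance; cannot fit prior")
        s0_2_est, d0_est = fit_f_dist(s2[~zero_var], d)
        d0 = d0_est if prior_df is None else prior_df
        s0_2 = s0_2_est if prior_var is None else prior_var
    else:
        d0, s0_2 = prior_df, prior_var

    se_factor = np.sqrt(1.0 / na + 1.0 / nb)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + d * s2) / (d0 + d)
        df_total = d0 + d
    with np.errstate(divide="ignore", invalid="ignore"):
        t = logfc / (np.sqrt(s2_post) * se_factor)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    # genes with no within-group variance carry no evidence of their own
    degenerate = zero_var
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    if degenerate.any():
        logger.warning("%d genes with zero variance in both groups: p set to 1", degenerate.sum())

    result = pd.DataFrame(
        {
            "logFC": logfc,
            "t": t,
            "p": p,
            "FDR": bh_adjust(p),
            "s2": s2,
            "s2_post": s2_post,
            "zero_variance": degenerate,
        },
        index=expression.index,
    )
    result.attrs["prior_df"] = float(d0)
    result.attrs["prior_var"] = float(s0_2)
    result.attrs["residual_df"] = float(d)
    result.attrs["engine"] = "moderated-t on log expression"
    return result


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_deg(
    result: pd.DataFrame, fdr: float = 0.01, fc: float = 2.0
) -> tuple[list[str], list[str]]:
    """Up/down gene lists at FDR < fdr and |logFC| > log2(fc)."""
    lfc_cut = np.log2(fc)
    sig = result["FDR"] < fdr
    up = list(result.index[sig & (result["logFC"] > lfc_cut)])
    down = list(result.index[sig & (result["logFC"] < -lfc_cut)])
    logger.info("select_deg: %d up, %d down at FDR<%g, |FC|>%g", len(up), len(down), fdr, fc)
    return up, down


def direction_labels(result: pd.DataFrame, fdr: float = 0.01, fc: float = 2.0) -> pd.Series:
    up, down = select_deg(result, fdr, fc)
    lab = pd.Series("ns", index=result.index, name="direction")
    lab.loc[up] = "up"
    lab.loc[down] = "down"
    return lab
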