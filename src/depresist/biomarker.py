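"""Signature scoring against drug response and ROC-based predictor comparison.

Signature activities (ssGSEA scores) and the ordinal mutation score are
candidate predictors of membership in the sensitive extreme; the AUROC —
the probability a random positive outranks a random negative, ties counted
one half — is the common currency for comparing them.  Labels always come
from the response data (lowest-AUC decile = positive) and are never fed to
the predictors themselves.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics

logger = logging.getLogger("depresist")


def correlate_signature_auc(
    scores: pd.Series, auc: pd.Series, method: str = "pearson"
) -> tuple[float, float]:
    """Correlation (and two-sided p) between signature scores and AUC.

    Pairs are aligned on shared identifiers; a negative correlation means
    higher signature activity tracks greater drug sensitivity (lower AUC).
    """
    shared = scores.index.intersection(auc.index)
    x = scores.loc[shared].to_numpy(dtype=float)
    y = auc.loc[shared].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.var(x) == 0:
        raise ValueError(f"constant scores for predictor {scores.name!r}")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def _check_labels(labels: np.ndarray) -> None:
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("labels must contain exactly two classes")


def auroc(scores, labels) -> float:
    """AUROC via the Mann-Whitney identity; ties between classes count 1/2."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    _check_labels(y)
    return float(metrics.roc_auc_score(y, s))


def roc_curve(scores, labels) -> pd.DataFrame:
    """Stepwise ROC points (FPR, TPR, threshold) from +inf down to -inf."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    _check_labels(y)
    fpr, tpr, thr = metrics.roc_curve(y, s, drop_intermediate=False)
    return pd.DataFrame({"FPR": fpr, "TPR": tpr, "threshold": thr})


def compare_predictors(
    predictors: pd.DataFrame,
    labels: pd.Series,
    n_boot: int = 1000,
    ci: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-predictor AUROC with percentile bootstrap CI, ranked descending.

    Lines missing any predictor are dropped listwise (count logged).
    """
    if predictors.shape[1] < 1:
        raise ValueError("need at least one predictor column")
    shared = predictors.index.intersection(labels.index)
    tab = predictors.loc[shared]
    y = labels.loc[shared].to_numpy(dtype=int)
    complete = tab.notna().all(axis=1).to_numpy()
    dropped = int((~complete).sum())
    if dropped:
        logger.info("compare_predictors: %d lines dropped for missing predictors", dropped)
    tab = tab.loc[complete]
    y = y[complete]
    _check_labels(y)
    rng = np.random.default_rng(seed)
    n = len(y)
    boot_idx = rng.integers(n, size=(n_boot, n))
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    rows = []
    for col in tab.columns:
        s = tab[col].to_numpy(dtype=float)
        point = auroc(s, y)
        boots = []
        for b in range(n_boot):
            idx = boot_idx[b]
            yb = y[idx]
            if yb.min() == yb.max():
                continue
            boots.append(auroc(s[idx], yb))
        lo, hi = (np.quantile(boots, [lo_q, hi_q]) if boots else (np.nan, np.nan))
        rows.append((col, point, lo, hi, n))
    out = pd.DataFrame(rows, columns=["predictor", "AUROC", "ci_low", "ci_high", "n"])
    return out.sort_values("AUROC", ascending=False, kind="stable").set_index("predictor")


def sensitivity_labels(groups, cell_lines: list[str]) -> pd.Series:
    """Binary label vector over scored lines: 1 = member of the sensitive extreme."""
    sens = set(groups.sensitive)
    scored = [ln for ln in cell_lines
              if ln in sens or ln in set(groups.resistant) or ln in set(groups.middle)]
    return pd.Series({ln: int(ln in sens) for ln in scored}, name="label")
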