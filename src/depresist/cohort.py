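"""Stratify cell lines into sensitive/resistant extremes by drug-response AUC.

The orientation contract throughout: a lower AUC means greater drug
sensitivity.  The sensitive (S) and resistant (R) groups are the lowest- and
highest-AUC deciles by default, mirroring a 10% AUC threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("depresist")


@dataclass
class SensitivityGroups:
    sensitive: list[str]
    resistant: list[str]
    middle: list[str]
    fraction: float

    def labels(self) -> pd.Series:
        out = {}
        for name, group in (("S", self.sensitive), ("R", self.resistant), ("mid", self.middle)):
            for line in group:
                out[line] = name
        return pd.Series(out, name="group")


def assign_sensitivity_groups(auc: pd.Series, fraction: float = 0.10) -> SensitivityGroups:
    """Split lines into S (lowest-AUC), R (highest-AUC) extremes and the middle.

    Group size is ``floor(fraction * n)`` over lines with non-missing AUC.
    Ties at a boundary break by a stable sort on (AUC, line identifier) so
    the split is deterministic across platforms.
    """
    if not 0 < fraction <= 0.5:
        raise ValueError(f"fraction must be in (0, 0.5], got {fraction}")
    auc = auc.dropna()
    n_missing = auc.isna().sum()
    if n_missing:
        logger.info("assign_sensitivity_groups: %d lines without AUC excluded", n_missing)
    n = len(auc)
    if n < 10:
        raise ValueError(f"need >= 10 lines with AUC, got {n}")
    k = int(np.floor(fraction * n))
    if k < 2:
        raise ValueError(f"fewer than 2 lines per group at fraction={fraction}, n={n}")
    if auc.nunique() == 1:
        raise ValueError("all AUC values identical: no extremes definable")
    ordered = auc.sort_index(kind="stable").sort_values(kind="stable")
    lines = list(ordered.index)
    return SensitivityGroups(
        sensitive=lines[:k],
        resistant=lines[-k:],
        middle=lines[k:-k],
        fraction=fraction,
    )


def consensus_groups(
    responses: pd.DataFrame, drugs: list[str] | None = None, fraction: float = 0.10
) -> SensitivityGroups:
    """Multi-drug grouping: a line must fall in the same extreme for every drug.

    The default single-drug path is ``assign_sensitivity_groups``; this
    consensus rule is the stricter pooling option for panels of inhibitors
    with comparable cellular responses.
    """
    drugs = drugs or list(responses.columns)
    per_drug = [assign_sensitivity_groups(responses[d], fraction) for d in drugs]
    sens = set(per_drug[0].sensitive)
    res = set(per_drug[0].resistant)
    for g in per_drug[1:]:
        sens &= set(g.sensitive)
        res &= set(g.resistant)
    scored = [ln for ln in responses.index if responses.loc[ln, drugs].notna().all()]
    middle = [ln for ln in scored if ln not in sens and ln not in res]
    return SensitivityGroups(sorted(sens), sorted(res), middle, fraction)


def ks_test(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test: D = sup |ECDF_a - ECDF_b|, asymptotic p."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("K-S test requires non-empty samples")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def drug_response_correlation(
    responses: pd.DataFrame, drugs: list[str] | None = None
) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation of per-line AUC across drugs."""
    drugs = drugs or list(responses.columns)
    sub = responses[drugs]
    for i, d1 in enumerate(drugs):
        for d2 in drugs[i + 1:]:
            if (sub[[d1, d2]].dropna().shape[0]) < 3:
                raise ValueError(f"fewer than 3 complete pairs for drugs {d1!r}, {d2!r}")
    corr = sub.corr(method="pearson", min_periods=3)
    np.fill_diagonal(corr.values, 1.0)
    return corr
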