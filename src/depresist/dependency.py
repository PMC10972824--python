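"""Differential gene dependency between sensitive and resistant lines.

Knockout effect scores are oriented so that a more negative value means the
gene is more essential for that line.  The per-gene two-sample t-statistic
is computed as (mean over S - mean over R) / SE, so a low negative t flags a
gene essential in the sensitive group and a high positive t flags one
essential in the resistant group — the resistant-selective end is where
druggable sensitisation targets are nominated.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

logger = logging.getLogger("depresist")


def viability_filter(
    effects: pd.DataFrame, sensitive: list[str], resistant: list[str], tau: float = -0.5
) -> list[str]:
    """Genes whose knockout costs viability in at least one extreme group.

    Keeps genes with mean effect < tau in the sensitive or resistant group
    (missing effects ignored in the means).
    """
    if not sensitive or not resistant:
        raise ValueError("both groups must be non-empty")
    mean_s = effects[sensitive].mean(axis=1)
    mean_r = effects[resistant].mean(axis=1)
    keep = effects.index[(mean_s < tau) | (mean_r < tau)]
    logger.info("viability_filter: %d/%d genes retained at tau=%g", len(keep), len(effects), tau)
    return list(keep)


def differential_dependency(
    effects: pd.DataFrame,
    sensitive: list[str],
    resistant: list[str],
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-gene two-sample t (Student's pooled by default; Welch by flag).

    t = (mean_S - mean_R)/SE: negative <=> S-selective essentiality,
    positive <=> R-selective.  Genes with fewer than two observations in a
    group are flagged and excluded from the FDR computation.
    """
    s = effects[list(sensitive)].to_numpy(dtype=float)
    r = effects[list(resistant)].to_numpy(dtype=float)
    ns = np.isfinite(s).sum(axis=1)
    nr = np.isfinite(r).sum(axis=1)
    ok = (ns >= 2) & (nr >= 2)
    if not ok.all():
        logger.warning("differential_dependency: %d genes with <2 observations flagged",
                       int((~ok).sum()))
    t_stat, p = stats.ttest_ind(s, r, axis=1, equal_var=equal_var, nan_policy="omit")
    t_stat = np.asarray(t_stat, dtype=float)
    p = np.asarray(p, dtype=float)
    out = pd.DataFrame(
        {
            "mean_S": np.nanmean(s, axis=1),
            "mean_R": np.nanmean(r, axis=1),
            "t": np.where(ok, t_stat, np.nan),
            "p": np.where(ok, p, np.nan),
            "n_S": ns,
            "n_R": nr,
            "flagged": ~ok,
        },
        index=effects.index,
    )
    fdr = np.full(len(out), np.nan)
    fdr[ok] = bh_adjust(out.loc[ok, "p"].to_numpy())
    out["FDR"] = fdr
    out["selectivity"] = np.select(
        [out["t"] < 0, out["t"] > 0], ["S-selective", "R-selective"], default="none"
    )
    return out


def nominate_targets(
    dep_result: pd.DataFrame,
    druggable_genes: list[str],
    top_k: int = 20,
) -> pd.DataFrame:
    """Druggable candidates among the top-k resistant-selective genes.

    Genes are ranked by descending t (the R-selective extreme); the top_k
    are intersected with the druggable list.  An empty intersection returns
    an empty report with a warning rather than an error.
    """
    if not druggable_genes:
        raise ValueError("druggable gene list is empty")
    ranked = dep_result.dropna(subset=["t"]).sort_values("t", ascending=False, kind="stable")
    if top_k > len(ranked):
        logger.info("nominate_targets: top_k=%d exceeds %d scored genes; using all",
                    top_k, len(ranked))
        top_k = len(ranked)
    top = ranked.head(top_k)
    druggable = set(druggable_genes)
    hits = top[top.index.isin(druggable)].copy()
    hits["rank"] = [int(ranked.index.get_loc(g)) + 1 for g in hits.index]
    if hits.empty:
        logger.warning("nominate_targets: no druggable gene in the top %d", top_k)
    cols = ["rank", "t", "p", "FDR", "mean_S", "mean_R"]
    return hits[cols]
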