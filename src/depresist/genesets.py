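"""Gene-set statistics: over-representation, permutation GSEA, ssGSEA.

Three enrichment flavours share one vocabulary (a ``{name: gene list}``
collection, typically read from GMT):

* ``hypergeometric_enrichment`` / ``ora`` — upper-tail hypergeometric test of
  a discrete query list against a universe;
* ``gsea`` — preranked enrichment: a weighted Kolmogorov-Smirnov running sum
  over a ranked statistic, significance by gene-label permutation, NES by
  same-sign normalisation, FDR by Benjamini-Hochberg across sets;
* ``ssgsea`` — a per-sample score from the difference between the
  rank-weighted ECDF of set members and the uniform ECDF of non-members.

The signed pathway score sign(NES) * -log10(FDR) condenses a GSEA row into
one signed significance value.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

logger = logging.getLogger("depresist")


def hypergeometric_enrichment(
    query: Sequence[str], gene_set: Sequence[str], universe: Sequence[str]
) -> tuple[float, int]:
    """Upper-tail hypergeometric p for the query/set overlap; returns (p, k).

    The set is intersected with the universe before testing; the query must
    be a subset of the universe.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q = set(query)
    if not q <= uni:
        raise ValueError("query is not a subset of the universe")
    members = set(gene_set) & uni
    k = len(q & members)
    n_uni, n_set, n_query = len(uni), len(members), len(q)
    p = float(stats.hypergeom.sf(k - 1, n_uni, n_set, n_query))
    return min(p, 1.0), k


def ora(
    query: Sequence[str],
    collection: Mapping[str, Sequence[str]],
    universe: Sequence[str],
) -> pd.DataFrame:
    """Over-representation analysis of a query list across a collection."""
    rows = []
    for name, members in collection.items():
        p, k = hypergeometric_enrichment(query, members, universe)
        rows.append((name, k, len(set(members) & set(universe)), len(set(query)), len(set(universe)), p))
    out = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "p"]).set_index("set")
    out["FDR"] = bh_adjust(out["p"].to_numpy())
    return out


def running_sum_es(
    ranked_stats: np.ndarray, member_flags: np.ndarray, weight_p: float = 1.0
) -> tuple[float, list[int]]:
    """Enrichment score of one set against a descending-ranked statistic.

    Hits step up by ``|s_i|^p / sum_set |s|^p``; misses step down by
    ``1/(N-K)``.  ES is the running sum's largest-magnitude deviation; the
    leading edge is the member indices at or before a positive extremum (or
    at/after a negative one).
    """
    s = np.asarray(ranked_stats, dtype=float)
    flags = np.asarray(member_flags, dtype=bool)
    n = s.size
    k = int(flags.sum())
    if k == 0:
        raise ValueError("set must be non-empty")
    w = np.abs(s) ** weight_p
    hit_total = w[flags].sum()
    if weight_p > 0 and hit_total == 0:
        raise ValueError("all member statistics are zero: hit weights undefined")
    steps = np.where(flags, (w / hit_total if weight_p > 0 else 1.0 / k),
                     (-1.0 / (n - k)) if k < n else 0.0)
    running = np.cumsum(steps)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    if abs(running[i_max]) >= abs(running[i_min]):
        es = float(running[i_max])
        leading = [i for i in np.flatnonzero(flags) if i <= i_max]
    else:
        es = float(running[i_min])
        leading = [i for i in np.flatnonzero(flags) if i > i_min]
    return es, leading


def _permutation_es(
    w_sorted: np.ndarray, k: int, nperm: int, rng: np.random.Generator, chunk: int = 2000
) -> np.ndarray:
    """Null ES values from gene-label permutation (random k-subsets of positions)."""
    n = w_sorted.size
    out = np.empty(nperm)
    done = 0
    miss_step = -1.0 / (n - k) if k < n else 0.0
    while done < nperm:
        m = min(chunk, nperm - done)
        # m random k-subsets via partial argsort of uniform keys
        keys = rng.random((m, n))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        mask = np.zeros((m, n), dtype=bool)
        np.put_along_axis(mask, idx, True, axis=1)
        w = np.broadcast_to(w_sorted, (m, n))
        hit_tot = np.where(mask, w, 0.0).sum(axis=1)
        hit_tot[hit_tot == 0] = np.inf  # all-zero draws contribute flat sums
        steps = np.where(mask, w / hit_tot[:, None], miss_step)
        running = np.cumsum(steps, axis=1)
        hi = running.max(axis=1)
        lo = running.min(axis=1)
        out[done:done + m] = np.where(np.abs(hi) >= np.abs(lo), hi, lo)
        done += m
    return out


def gsea(
    ranked_stats: pd.Series,
    collection: Mapping[str, Sequence[str]],
    nperm: int = 100_000,
    min_size: int = 10,
    max_size: int = 500,
    weight_p: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Preranked GSEA over a collection.

    ``ranked_stats`` maps gene -> statistic; genes are ranked descending
    (ties broken by stable input order).  Sets are intersected with the
    ranked universe, then size-filtered to [min_size, max_size]; excluded
    sets appear in the report with reason "size".  The null is gene-label
    permutation: p = (1 + #{same-sign |ES_perm| >= |ES|}) / (1 + #same-sign),
    NES = ES / mean(|ES_perm| of matching sign), FDR = BH across tested sets.
    Deterministic given the seed.
    """
    order = np.argsort(-ranked_stats.to_numpy(), kind="stable")
    genes = ranked_stats.index.to_numpy()[order]
    s_sorted = ranked_stats.to_numpy()[order]
    w_sorted = np.abs(s_sorted) ** weight_p
    pos = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    rng = np.random.default_rng(seed)

    rows = []
    null_cache: dict[int, np.ndarray] = {}
    for name, members in collection.items():
        idx = sorted(pos[g] for g in set(members) if g in pos)
        k = len(idx)
        if not (min_size <= k <= max_size):
            rows.append((name, k, np.nan, np.nan, np.nan, None, "size"))
            continue
        flags = np.zeros(n, dtype=bool)
        flags[idx] = True
        es, leading = running_sum_es(s_sorted, flags, weight_p)
        if k not in null_cache:
            null_cache[k] = _permutation_es(w_sorted, k, nperm, rng)
        null = null_cache[k]
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        n_same = same_sign.size
        if n_same == 0:
            p = 1.0 / (nperm + 1)
            nes = np.nan
            flag = "no-same-sign-perms"
        else:
            p = (1.0 + np.sum(np.abs(same_sign) >= abs(es))) / (1.0 + n_same)
            nes = es / np.mean(np.abs(same_sign))
            flag = ""
        rows.append((name, k, es, nes, p, [genes[i] for i in leading], flag))

    out = pd.DataFrame(
        rows, columns=["set", "size", "ES", "NES", "p", "leading_edge", "flag"]
    ).set_index("set")
    tested = out["flag"] != "size"
    fdr = np.full(len(out), np.nan)
    if tested.any():
        fdr[tested.to_numpy()] = bh_adjust(out.loc[tested, "p"].to_numpy())
    out["FDR"] = fdr
    excluded = out.index[~tested].tolist()
    if excluded:
        logger.info("gsea: %d sets excluded by size bounds: %s", len(excluded), excluded)
    return out


def ssgsea_scores(
    profile: pd.Series,
    collection: Mapping[str, Sequence[str]],
    alpha: float = 0.25,
    normalize: bool = False,
) -> pd.Series:
    """Single-sample GSEA scores for one expression profile.

    Genes are ranked by expression (highest expression -> rank N; ties break
    by stable input order).  For each set the score is the summed difference
    between the rank-weighted ECDF of members (weights rank^alpha) and the
    uniform ECDF of non-members.  ``normalize`` divides all scores by their
    (max - min) across the collection.  Sets with no member in the profile
    are absent from the output.
    """
    values = profile.to_numpy(dtype=float)
    n = values.size
    order = np.argsort(-values, kind="stable")
    ranks = np.empty(n)
    ranks[order] = np.arange(n, 0, -1)  # top gene gets rank n
    gene_pos = {g: i for i, g in enumerate(profile.index)}
    scores = {}
    for name, members in collection.items():
        idx = np.array(sorted(gene_pos[g] for g in set(members) if g in gene_pos), dtype=int)
        if idx.size == 0:
            logger.info("ssgsea: set %r has no members in profile, skipped", name)
            continue
        in_set = np.zeros(n, dtype=bool)
        in_set[idx] = True
        in_sorted = in_set[order]
        w = ranks[order] ** alpha
        p_in = np.cumsum(np.where(in_sorted, w, 0.0))
        p_in /= p_in[-1]
        n_out = n - idx.size
        if n_out == 0:
            p_out = np.zeros(n)
        else:
            p_out = np.cumsum(~in_sorted) / n_out
        scores[name] = float(np.sum(p_in - p_out))
    out = pd.Series(scores, name=profile.name)
    if normalize and len(out) > 0:
        rng_width = out.max() - out.min()
        if rng_width > 0:
            out = out / rng_width
    return out


def ssgsea_matrix(
    expression: pd.DataFrame,
    collection: Mapping[str, Sequence[str]],
    alpha: float = 0.25,
    normalize: bool = False,
) -> pd.DataFrame:
    """ssGSEA per sample (column); rows = sets.  Normalisation, when on, uses
    the global (max - min) across the whole score matrix, per run."""
    cols = {c: ssgsea_scores(expression[c], collection, alpha, normalize=False)
            for c in expression.columns}
    out = pd.DataFrame(cols)
    if normalize and out.size:
        width = float(out.max().max() - out.min().min())
        if width > 0:
            out = out / width
    return out


def pathway_score(nes: float, fdr: float, nperm: int | None = None) -> float:
    """Signed significance: sign(NES) * -log10(FDR), FDR floored at 1/(nperm+1)."""
    if not np.isfinite(nes):
        raise ValueError("NES must be finite")
    if not 0 <= fdr <= 1:
        raise ValueError("FDR must lie in [0, 1]")
    floor = 1.0 / (nperm + 1) if nperm else np.finfo(float).tiny
    return float(np.sign(nes) * -np.log10(max(fdr, floor)))
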