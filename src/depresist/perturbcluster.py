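"""Gene clustering over drug-induced transcriptional change profiles.

Genes are z-transformed across all samples and grouped by complete-linkage
agglomerative clustering on Euclidean distances over the full replicate
matrix, cut at a fixed cluster number (K = 5 by default).  A
replicate-averaged mode (``average_replicates``) condenses profiles to
condition means for display and pattern reading.  Each cluster
is then annotated by hypergeometric over-representation against a gene-set
collection, with the clustered genes as the universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from . import genesets
from .diffexpr import bh_adjust

logger = logging.getLogger("depresist")


def z_transform(matrix: pd.DataFrame, drop_constant: bool = True) -> pd.DataFrame:
    """Row-wise z-scores (mean 0, sd 1 with n-1 denominator).

    Constant rows have no scale; they are dropped with a warning by default.
    """
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        if not drop_constant:
            raise ValueError(f"{constant.sum()} constant rows; z-transform undefined")
        logger.warning("z_transform: dropping %d constant rows", int(constant.sum()))
    z = (values - mean) / np.where(sd == 0, np.nan, sd)
    out = pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
    return out.loc[~constant]


def average_replicates(matrix: pd.DataFrame, conditions: Sequence[str]) -> pd.DataFrame:
    """Collapse replicate columns named ``<condition>_<rep>`` to condition means."""
    cols = {}
    for cond in conditions:
        # replicate columns are "<condition>_<rep>"; exact-match the condition
        # stem so e.g. "drug" does not absorb "drug_inhibitor" replicates
        reps = [c for c in matrix.columns
                if c == cond or str(c).rsplit("_", 1)[0] == cond]
        if not reps:
            raise ValueError(f"no columns found for condition {cond!r}")
        cols[cond] = matrix[reps].mean(axis=1)
    return pd.DataFrame(cols)


@dataclass
class ClusterAssignment:
    labels: pd.Series           # gene -> cluster id in 1..K
    linkage: np.ndarray         # scipy linkage matrix, for audit
    k: int

    def members(self, cluster_id: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster_id])


def hierarchical_clusters(matrix: pd.DataFrame, k: int = 5) -> ClusterAssignment:
    """Complete-linkage Euclidean clustering cut to exactly k clusters.

    Deterministic given input: scipy's agglomeration breaks distance ties by
    the smallest row-index pair.  Cluster ids are 1..k in order of first
    appearance along the input rows.
    """
    if len(matrix) < k:
        raise ValueError(f"need >= {k} rows to form {k} clusters, got {len(matrix)}")
    values = matrix.to_numpy(dtype=float)
    link = hierarchy.linkage(values, method="complete", metric="euclidean")
    raw = hierarchy.fcluster(link, t=k, criterion="maxclust")
    # relabel in order of first appearance for a stable presentation
    remap: dict[int, int] = {}
    for lab in raw:
        if lab not in remap:
            remap[lab] = len(remap) + 1
    labels = pd.Series([remap[v] for v in raw], index=matrix.index, name="cluster")
    if labels.nunique() != k:
        raise ValueError(f"cut produced {labels.nunique()} clusters, expected {k}")
    return ClusterAssignment(labels=labels, linkage=link, k=k)


def cluster_enrichment(
    assignment: ClusterAssignment,
    collection: Mapping[str, Sequence[str]],
    top_n: int | None = None,
) -> pd.DataFrame:
    """Per-cluster hypergeometric ORA; universe = all clustered genes.

    FDR is Benjamini-Hochberg within each cluster.  ``top_n`` truncates each
    cluster's report to its smallest-p sets.
    """
    universe = list(assignment.labels.index)
    frames = []
    for cid in range(1, assignment.k + 1):
        members = assignment.members(cid)
        tab = genesets.ora(members, collection, universe).reset_index()
        tab["FDR"] = bh_adjust(tab["p"].to_numpy())
        tab.insert(0, "cluster", cid)
        tab = tab.sort_values("p", kind="stable")
        if top_n is not None:
            tab = tab.head(top_n)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def pca_projection(matrix: pd.DataFrame, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered-SVD projection of samples (columns) with explained variance.

    Sign convention: each component's largest-magnitude loading is forced
    positive, so projections are reproducible across runs and platforms.
    Returns (coordinates samples x components, explained-variance fractions).
    """
    x = matrix.to_numpy(dtype=float).T  # samples x features
    if n_components > min(x.shape):
        raise ValueError(f"n_components={n_components} exceeds min(dims)={min(x.shape)}")
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    for i in range(n_components):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    coords = u[:, :n_components] * s[:n_components]
    total_var = (s ** 2).sum()
    explained = (s[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return pd.DataFrame(coords, index=matrix.columns, columns=cols), explained


def condition_profiles(
    matrix: pd.DataFrame, assignment: ClusterAssignment, conditions: Sequence[str]
) -> pd.DataFrame:
    """Mean z-profile of each cluster across conditions (for pattern reading)."""
    avg = average_replicates(matrix, conditions)
    rows = {cid: avg.loc[assignment.members(cid)].mean(axis=0)
            for cid in range(1, assignment.k + 1)}
    return pd.DataFrame(rows).T.rename_axis("cluster")
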