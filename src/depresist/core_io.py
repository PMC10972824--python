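"""Readers/writers for the on-disk formats and cell-line identifier alignment.

Matrices (expression, drug-response AUC, gene effect) travel as delimited text
with row identifiers in the first column and column identifiers in the header.
Gene sets travel as GMT.  Cell-line identifiers are opaque, case-sensitive
strings; no name-mapping layer is provided.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("depresist")


def _delimiter_for(path: str | Path, delimiter: str | None = None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).endswith(".csv") else "\t"


def read_matrix(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a delimited matrix: first column = row ids, header = column ids.

    Missing cells (empty field or ``NA``) become NaN, never zero.  Duplicate
    row or column identifiers and ragged rows raise ``ValueError``.
    """
    sep = _delimiter_for(path, delimiter)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
        ncol = len(header) - 1
        cols = header[1:]
        rows: list[str] = []
        data: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split(sep)
            if len(fields) - 1 != ncol:
                raise ValueError(
                    f"{path}: ragged row at line {lineno}: expected "
                    f"{ncol} values, got {len(fields) - 1}"
                )
            rows.append(fields[0])
            data.append(
                [np.nan if f in ("", "NA", "NaN", "nan") else float(f) for f in fields[1:]]
            )
    for name, labels in (("row", rows), ("column", cols)):
        seen = pd.Index(labels)
        if seen.has_duplicates:
            dups = sorted(set(seen[seen.duplicated()]))
            raise ValueError(f"{path}: duplicate {name} identifiers: {dups}")
    return pd.DataFrame(data, index=pd.Index(rows), columns=pd.Index(cols), dtype=float)


def write_matrix(df: pd.DataFrame, path: str | Path, delimiter: str | None = None) -> None:
    """Write a matrix in the format ``read_matrix`` reads (NaN -> ``NA``)."""
    sep = _delimiter_for(path, delimiter)
    df.to_csv(path, sep=sep, na_rep="NA", index_label="id")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file into ``{set name: unique member list}``.

    Lines are ``name<TAB>description<TAB>gene1<TAB>...``.  Duplicate genes
    within a set are dropped (first occurrence kept) with a logged warning;
    lines with fewer than three fields raise ``ValueError``.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno} has fewer than 3 fields")
            name, genes = fields[0], fields[2:]
            unique = list(dict.fromkeys(g for g in genes if g))
            if len(unique) < len([g for g in genes if g]):
                logger.warning("GMT set %r: duplicate members deduplicated", name)
            if name in sets:
                raise ValueError(f"{path}: duplicate set name {name!r} at line {lineno}")
            sets[name] = unique
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """Plain-text gene list, one symbol per line; blank lines skipped."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_mutation_table(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Mutation table with columns cell_line, gene, protein_change, oncogenic."""
    sep = _delimiter_for(path, delimiter)
    df = pd.read_csv(path, sep=sep)
    required = {"cell_line", "gene", "protein_change", "oncogenic"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing mutation-table columns {sorted(missing)}")
    if df["oncogenic"].dtype == object:
        df["oncogenic"] = df["oncogenic"].astype(str).str.lower().isin(("true", "1", "yes"))
    return df


@dataclass
class PanelBundle:
    """In-memory cell-line panel: all components share one ordered line list.

    ``expression`` is genes x lines (log2(TPM+1)); ``responses`` is lines x
    drugs AUC; ``mutations`` is a per-variant record table; ``effects`` is
    genes x lines knockout effect scores (optional; more negative = more
    essential).
    """

    expression: pd.DataFrame
    responses: pd.DataFrame
    mutations: pd.DataFrame
    effects: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.expression.columns)

    def validate(self) -> None:
        lines = self.cell_lines
        if list(self.responses.index) != lines:
            raise ValueError("responses index does not match expression columns")
        if self.effects is not None and list(self.effects.columns) != lines:
            raise ValueError("effects columns do not match expression columns")
        extra = set(self.mutations["cell_line"]) - set(lines)
        if extra:
            raise ValueError(f"mutation records for unknown cell lines: {sorted(extra)}")


def intersect_bundle(
    expression: pd.DataFrame,
    responses: pd.DataFrame,
    mutations: pd.DataFrame,
    effects: pd.DataFrame | None = None,
    metadata: dict | None = None,
) -> PanelBundle:
    """Restrict all components to their common cell lines, in sorted order.

    Mirrors the panel-assembly step of intersecting drug response, genome and
    transcriptome coverage.  Raises ``ValueError`` on an empty intersection.
    """
    common = set(expression.columns) & set(responses.index)
    if effects is not None:
        common &= set(effects.columns)
    if not common:
        raise ValueError("empty cell-line intersection across components")
    lines = sorted(common)
    logger.info("intersect_bundle: %d common cell lines", len(lines))
    bundle = PanelBundle(
        expression=expression[lines],
        responses=responses.loc[lines],
        mutations=mutations[mutations["cell_line"].isin(lines)].reset_index(drop=True),
        effects=None if effects is None else effects[lines],
        metadata=metadata or {},
    )
    bundle.validate()
    return bundle


@dataclass
class Config:
    """Pipeline parameters with the defaults the analysis prescribes."""

    seed: int = 0
    fraction: float = 0.10          # sensitivity decile for group assignment
    de_fdr: float = 0.01            # DEG FDR cut-off
    de_fc: float = 2.0              # DEG absolute fold-change cut-off
    gsea_nperm: int = 100_000
    gsea_min_size: int = 10
    gsea_max_size: int = 500
    gsea_weight: float = 1.0
    ssgsea_alpha: float = 0.25
    dependency_tau: float = -0.5    # viability-filter mean-effect threshold
    dependency_top_k: int = 20
    cluster_k: int = 5
    paths: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not 0 < self.fraction <= 0.5:
            raise ValueError(f"fraction must be in (0, 0.5], got {self.fraction}")
        if self.gsea_nperm < 100:
            raise ValueError(f"gsea_nperm must be >= 100, got {self.gsea_nperm}")
        if self.cluster_k < 2:
            raise ValueError(f"cluster_k must be >= 2, got {self.cluster_k}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def file_digest(path: str | Path) -> str:
    """SHA-256 of a file, for provenance logs."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
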