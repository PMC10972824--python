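"""Five-class mutation taxonomy and the ordinal mutation score.

Protein-changing variants are classified by where they fall relative to a
residue interval approximating the receptor's kinase domain (exons 18-21)
crossed with an externally supplied oncogenicity annotation (OncoKB-style):

    class II  — outside the domain, not annotated oncogenic
    class III — outside the domain, annotated oncogenic
    class IV  — inside the domain, not annotated oncogenic
    class V   — inside the domain, annotated oncogenic

Class I is the superset label "any protein-changing mutation" and is implied
by II-V.  A cell line carrying several variants is labelled by the highest
class under the ordinal score, and the score itself (none=0 < II=1 < IV=2 <
III=3 < V=4 by default) turns mutation status into an ordered predictor that
ranks annotated oncogenicity above location.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import pandas as pd

from .cohort import ks_test

logger = logging.getLogger("depresist")

DEFAULT_DOMAIN = (688, 875)
DEFAULT_SCORE_MAP = {"none": 0, "II": 1, "IV": 2, "III": 3, "V": 4}

_RESIDUE_RE = re.compile(r"^[A-Za-z*]+?(\d+)")


@dataclass(frozen=True)
class DomainInterval:
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"domain start {self.start} > end {self.end}")

    def __contains__(self, residue: int) -> bool:
        return self.start <= residue <= self.end


def parse_residue(protein_change: str) -> int | None:
    """Extract the residue position from a protein change like ``L858R``.

    Returns None when no leading residue number is parseable (e.g. splice or
    frame-shift notations outside the simple substitution grammar).
    """
    if not isinstance(protein_change, str):
        return None
    m = _RESIDUE_RE.match(protein_change.strip().removeprefix("p."))
    return int(m.group(1)) if m else None


def classify_mutation(
    protein_change: str, oncogenic: bool, domain: DomainInterval | tuple[int, int] = DEFAULT_DOMAIN
) -> str | None:
    """Classify one variant into II-V; None when the residue is unparseable."""
    if not isinstance(domain, DomainInterval):
        domain = DomainInterval(*domain)
    residue = parse_residue(protein_change)
    if residue is None:
        return None
    inside = residue in domain
    if inside:
        return "V" if oncogenic else "IV"
    return "III" if oncogenic else "II"


def classify_cell_line(
    records: pd.DataFrame,
    domain: DomainInterval | tuple[int, int] = DEFAULT_DOMAIN,
    score_map: dict[str, int] | None = None,
) -> str:
    """One label per line: the maximum class over its variants by ordinal score.

    ``records`` holds that line's rows (columns protein_change, oncogenic);
    an empty frame yields "none".  Unparseable records are skipped with a
    warning, never silently treated as wild-type when parseable ones exist.
    """
    score_map = score_map or DEFAULT_SCORE_MAP
    best = "none"
    for _, row in records.iterrows():
        label = classify_mutation(row["protein_change"], bool(row["oncogenic"]), domain)
        if label is None:
            logger.warning("unparseable protein change %r skipped", row["protein_change"])
            continue
        if score_map[label] > score_map[best]:
            best = label
    return best


def classify_panel(
    mutations: pd.DataFrame,
    cell_lines: list[str],
    gene: str = "EGFR",
    domain: DomainInterval | tuple[int, int] = DEFAULT_DOMAIN,
    score_map: dict[str, int] | None = None,
) -> pd.Series:
    """Per-line class label over a whole panel; lines without records -> "none"."""
    sub = mutations[mutations["gene"] == gene]
    grouped = dict(tuple(sub.groupby("cell_line")))
    empty = sub.iloc[0:0]
    return pd.Series(
        {ln: classify_cell_line(grouped.get(ln, empty), domain, score_map) for ln in cell_lines},
        name="mutation_class",
    )


def mutation_score(class_label: str, score_map: dict[str, int] | None = None) -> int:
    """Ordinal score of a class label; ordering tracks known oncogenic potential."""
    score_map = score_map or DEFAULT_SCORE_MAP
    if class_label not in score_map:
        raise ValueError(f"unknown mutation class {class_label!r}")
    return score_map[class_label]


def class_auc_association(
    auc: pd.Series,
    class_labels: pd.Series,
    reference: str = "none",
    min_n: int = 2,
) -> pd.DataFrame:
    """K-S test of AUC distributions for each mutation class against wild-type.

    Classes with fewer than ``min_n`` lines are reported but skipped (D, p
    NaN) with the reason logged.
    """
    shared = auc.index.intersection(class_labels.index)
    auc = auc.loc[shared]
    class_labels = class_labels.loc[shared]
    ref_auc = auc[class_labels == reference].dropna()
    rows = []
    for label in ["II", "III", "IV", "V"]:
        grp = auc[class_labels == label].dropna()
        if len(grp) < min_n or len(ref_auc) < min_n:
            logger.info("class %s skipped: n=%d (< %d)", label, len(grp), min_n)
            rows.append((label, len(grp), len(ref_auc), float("nan"), float("nan")))
            continue
        d, p = ks_test(grp.to_numpy(), ref_auc.to_numpy())
        rows.append((label, len(grp), len(ref_auc), d, p))
    return pd.DataFrame(rows, columns=["class", "n_class", "n_reference", "D", "p"]).set_index("class")
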