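"""Driver-gene screen: the 20/20 rule.

A gene's oncogene (ONG) score is the fraction of its variants that are
gain-of-function — missense or in-frame indels recurring at the same
amino-acid residue. Its tumor-suppressor (TSG) score is the fraction that are
loss-of-function — nonsense, nonstop or frameshift indels. A score above 20 %
classifies the gene; candidate drivers additionally need a minimum number of
variants across the cohort.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .exceptions import ContractError, DomainError
from .matrix_io import VariantClass, VariantRecord

__all__ = ["DriverScore", "score_gene", "score_all_genes", "select_drivers", "drivers_report"]

_GOF_CLASSES = {VariantClass.MISSENSE, VariantClass.IN_FRAME_INDEL}
_LOF_CLASSES = {VariantClass.NONSENSE, VariantClass.NONSTOP, VariantClass.FRAMESHIFT_INDEL}


@dataclass(frozen=True)
class DriverScore:
    gene: str
    total_variants: int
    gof_count: int
    lof_count: int
    ong_score: float
    tsg_score: float
    classification: str  # oncogene | tumor_suppressor | both | neither


def score_gene(
    records: Sequence[VariantRecord],
    recurrence_min: int = 2,
    class_threshold: float = 0.20,
) -> DriverScore:
    """Score one gene's variant records.

    ``recurrence_min`` is the number of missense/in-frame records that must
    share one residue position for those records to count as gain-of-function.
    Records without a parsed protein position never contribute to recurrence.
    Classification uses strict ``>`` against ``class_threshold`` on each score.
    """
    if not records:
        raise DomainError("cannot score a gene with no variant records")
    if recurrence_min < 2:
        raise ContractError(f"recurrence_min must be >= 2, got {recurrence_min}")
    genes = {r.gene for r in records}
    if len(genes) != 1:
        raise ContractError(f"records span multiple genes: {sorted(genes)}")
    (gene,) = genes

    total = len(records)
    positions = Counter(
        r.protein_position
        for r in records
        if r.variant_class in _GOF_CLASSES and r.protein_position is not None
    )
    recurrent = {pos for pos, cnt in positions.items() if cnt >= recurrence_min}
    gof = sum(
        1
        for r in records
        if r.variant_class in _GOF_CLASSES and r.protein_position in recurrent
    )
    lof = sum(1 for r in records if r.variant_class in _LOF_CLASSES)

    ong = gof / total
    tsg = lof / total
    is_ong = ong > class_threshold
    is_tsg = tsg > class_threshold
    classification = {
        (True, True): "both",
        (True, False): "oncogene",
        (False, True): "tumor_suppressor",
        (False, False): "neither",
    }[(is_ong, is_tsg)]
    return DriverScore(gene, total, gof, lof, ong, tsg, classification)


def score_all_genes(
    records: Iterable[VariantRecord],
    recurrence_min: int = 2,
    class_threshold: float = 0.20,
) -> list[DriverScore]:
    """Group a cohort's records by gene (order of first appearance) and score each."""
    by_gene: dict[str, list[VariantRecord]] = {}
    for r in records:
        by_gene.setdefault(r.gene, []).append(r)
    return [
        score_gene(rs, recurrence_min=recurrence_min, class_threshold=class_threshold)
        for rs in by_gene.values()
    ]


def select_drivers(
    scores: Sequence[DriverScore],
    min_variants: int = 20,
    score_threshold: float = 0.20,
) -> list[str]:
    """Candidate drivers: >= ``min_variants`` records and ONG or TSG score
    strictly above ``score_threshold``. Input order preserved."""
    if min_variants < 1:
        raise ContractError("min_variants must be >= 1")
    if not (0 < score_threshold < 1):
        raise ContractError("score_threshold must lie in (0, 1)")
    return [
        s.gene
        for s in scores
        if s.total_variants >= min_variants
        and (s.ong_score > score_threshold or s.tsg_score > score_threshold)
    ]


def drivers_report(
    scores: Sequence[DriverScore],
    selected: Sequence[str],
) -> pd.DataFrame:
    """Tabular report (one row per gene) suitable for a TSV dump."""
    sel = set(selected)
    return pd.DataFrame(
        {
            "gene": [s.gene for s in scores],
            "total_variants": [s.total_variants for s in scores],
            "gof": [s.gof_count for s in scores],
            "lof": [s.lof_count for s in scores],
            "ong_score": [s.ong_score for s in scores],
            "tsg_score": [s.tsg_score for s in scores],
            "classification": [s.classification for s in scores],
            "selected": [s.gene in sel for s in scores],
        }
    )
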