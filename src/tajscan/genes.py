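"""Map windows onto gene models and classify genes.

A gene enters the analysis when more than half of its span lies in
ANALYSED windows; an analysed gene is significant when it overlaps at
least one significant window, taking its sign from the overlapping
significant window with the largest |D|.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Sequence

from .genome_io import GeneModel
from .windows import Significance, WindowStats, WindowStatus

log = logging.getLogger(__name__)

__all__ = ["GeneClass", "GeneClassification", "gene_coverage_fraction",
           "classify_genes", "gene_class_counts"]


class GeneClass(enum.Enum):
    NOT_ANALYSED = "not_analysed"
    ANALYSED = "analysed"
    SIGNIFICANT_POSITIVE = "significant_positive"
    SIGNIFICANT_NEGATIVE = "significant_negative"


@dataclass
class GeneClassification:
    gene: GeneModel
    coverage_fraction: float
    gene_class: GeneClass
    supporting_windows: list[int] = field(default_factory=list)
    extreme_D: float | None = None
    mixed_signs: bool = False


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def gene_coverage_fraction(gene: GeneModel,
                           analysed_windows: Sequence) -> float:
    """Fraction of the gene span overlapped by (non-overlapping) windows."""
    covered = sum(
        _overlap(gene.start, gene.end, w.start, w.end)
        for w in analysed_windows if w.chrom == gene.chrom
    )
    return covered / gene.length


def classify_genes(genes: Sequence[GeneModel],
                   window_stats: Sequence[WindowStats],
                   min_coverage: float = 0.5) -> list[GeneClassification]:
    """Assign exactly one class to every gene.

    Coverage counts ANALYSED windows only. Significance requires any
    overlap with a significant window; genes overlapping windows of both
    signs take the sign of the maximal |D| (ties resolve positive, and the
    conflict is logged).
    """
    analysed = [s for s in window_stats if s.status is WindowStatus.ANALYSED]
    by_chrom: dict[str, list[WindowStats]] = {}
    for s in analysed:
        by_chrom.setdefault(s.window.chrom, []).append(s)

    out: list[GeneClassification] = []
    for gene in genes:
        overlapping = [
            s for s in by_chrom.get(gene.chrom, ())
            if _overlap(gene.start, gene.end, s.window.start, s.window.end) > 0
        ]
        frac = gene_coverage_fraction(gene, [s.window for s in overlapping])
        if frac <= min_coverage:
            out.append(GeneClassification(gene, frac, GeneClass.NOT_ANALYSED))
            continue
        sig = [s for s in overlapping
               if s.significance is not Significance.NOT_SIGNIFICANT]
        if not sig:
            out.append(GeneClassification(gene, frac, GeneClass.ANALYSED))
            continue
        signs = {s.significance for s in sig}
        # Sign from the significant window with maximal |D|; ties positive.
        best = max(sig, key=lambda s: (abs(s.D),
                                       s.significance is Significance.SIGNIFICANT_POSITIVE))
        mixed = len(signs) > 1
        if mixed:
            log.info("gene %s overlaps significant windows of both signs; "
                     "assigned by max |D| = %.3f", gene.gene_id, best.D)
        cls = (GeneClass.SIGNIFICANT_POSITIVE
               if best.significance is Significance.SIGNIFICANT_POSITIVE
               else GeneClass.SIGNIFICANT_NEGATIVE)
        out.append(GeneClassification(
            gene, frac, cls,
            supporting_windows=[s.window.id for s in sig],
            extreme_D=best.D, mixed_signs=mixed))
    return out


def gene_class_counts(classes: Sequence[GeneClassification]) -> dict[str, int]:
    counts = {c: 0 for c in GeneClass}
    for gc in classes:
        counts[gc.gene_class] += 1
    analysed = (counts[GeneClass.ANALYSED] + counts[GeneClass.SIGNIFICANT_POSITIVE]
                + counts[GeneClass.SIGNIFICANT_NEGATIVE])
    return {
        "genes_total": len(classes),
        "genes_analysed": analysed,
        "genes_significant": counts[GeneClass.SIGNIFICANT_POSITIVE]
        + counts[GeneClass.SIGNIFICANT_NEGATIVE],
        "genes_significant_positive": counts[GeneClass.SIGNIFICANT_POSITIVE],
        "genes_significant_negative": counts[GeneClass.SIGNIFICANT_NEGATIVE],
    }
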