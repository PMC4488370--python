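"""SV-to-gene assignment, expression classes, and expression-impact tests."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core_io import GeneModel, SVCall, overlap_length

__all__ = [
    "GeneSVStatus",
    "EXPRESSION_CLASS_LABELS",
    "assign_sv_genes",
    "expression_class",
    "loss_of_expression_test",
    "dosage_fold_change_test",
    "transcriptome_correlation",
    "shared_sv_genes",
]


@dataclass(frozen=True)
class GeneSVStatus:
    gene_id: str
    status: str  # deleted | duplicated | partially_deleted | unaffected
    mode: str    # complete | half

    def __post_init__(self) -> None:
        if self.status not in ("deleted", "duplicated", "partially_deleted",
                               "unaffected"):
            raise ValueError(f"bad status {self.status!r}")
        if self.mode not in ("complete", "half"):
            raise ValueError(f"bad mode {self.mode!r}")


#: FPKM class edges: {0}, (0,1], (1,10], (10,100], >100.
EXPRESSION_CLASS_LABELS = ("zero", "(0,1]", "(1,10]", "(10,100]", ">100")
_CLASS_EDGES = (1.0, 10.0, 100.0)


def assign_sv_genes(calls: Sequence[SVCall], genes: Sequence[GeneModel],
                    mode: str = "complete") -> list[GeneSVStatus]:
    """Per-gene SV status.

    complete mode: a gene is deleted/duplicated iff its full span
    (first-to-last exon) lies inside a single call.  half mode adds, for
    deletions only, partially_deleted when a deletion covers >= 50% of the
    gene span without containing it.
    """
    if mode not in ("complete", "half"):
        raise ValueError(f"bad mode {mode!r}")
    out = []
    for g in genes:
        status = "unaffected"
        best_frac_del = 0.0
        for c in calls:
            if c.contig != g.contig:
                continue
            contained = c.start <= g.start and g.end <= c.end
            if contained:
                status = "deleted" if c.sv_type == "deletion" else "duplicated"
                break
            if mode == "half" and c.sv_type == "deletion":
                frac = overlap_length(g.start, g.end, c.start, c.end) / g.length
                best_frac_del = max(best_frac_del, frac)
        if status == "unaffected" and mode == "half" and best_frac_del >= 0.5:
            status = "partially_deleted"
        out.append(GeneSVStatus(gene_id=g.gene_id, status=status, mode=mode))
    return out


def expression_class(fpkm: float) -> str:
    """Map an FPKM value onto its order-of-magnitude class."""
    if fpkm < 0 or math.isnan(fpkm):
        raise ValueError(f"invalid FPKM {fpkm}")
    if fpkm == 0:
        return "zero"
    for edge, label in zip(_CLASS_EDGES, EXPRESSION_CLASS_LABELS[1:]):
        if fpkm <= edge:
            return label
    return ">100"


def loss_of_expression_test(affected: set[str], background: set[str],
                            expression: Mapping[str, float],
                            ) -> tuple[float, float]:
    """Two-sided Fisher's exact test on (zero vs nonzero FPKM) x
    (affected vs background).  Returns (odds_ratio, p)."""
    if not affected or not background:
        raise ValueError("both gene sets must be non-empty")
    if affected & background:
        raise ValueError("gene sets must be disjoint")
    missing = (affected | background) - set(expression)
    if missing:
        raise ValueError(f"missing expression for {len(missing)} genes")
    a_zero = sum(1 for g in affected if expression[g] == 0)
    b_zero = sum(1 for g in background if expression[g] == 0)
    table = [[a_zero, len(affected) - a_zero],
             [b_zero, len(background) - b_zero]]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def dosage_fold_change_test(duplicated: set[str], unaffected: set[str],
                            expr_ref: Mapping[str, float],
                            expr_test: Mapping[str, float]) -> float:
    """Two-sided rank-sum test of log2(test/ref) between duplicated and
    unaffected genes, restricted to genes expressed (FPKM > 0) in both
    samples."""
    def fold_changes(gene_set: set[str]) -> list[float]:
        return [math.log2(expr_test[g] / expr_ref[g]) for g in sorted(gene_set)
                if expr_ref.get(g, 0) > 0 and expr_test.get(g, 0) > 0]

    fc_dup = fold_changes(duplicated)
    fc_bg = fold_changes(unaffected)
    if len(fc_dup) < 3 or len(fc_bg) < 3:
        raise ValueError("need >= 3 expressed genes in each group")
    if fc_dup == fc_bg:
        return 1.0
    _, p = stats.mannwhitneyu(fc_dup, fc_bg, alternative="two-sided")
    return float(p)


def transcriptome_correlation(expr_a: Mapping[str, float],
                              expr_b: Mapping[str, float]) -> float:
    """Spearman rank correlation across the shared gene universe."""
    genes = sorted(set(expr_a) & set(expr_b))
    if len(genes) < 3:
        raise ValueError("need >= 3 shared genes")
    rho, _ = stats.spearmanr([expr_a[g] for g in genes],
                             [expr_b[g] for g in genes])
    return float(rho)


def shared_sv_genes(status_a: Sequence[GeneSVStatus],
                    status_b: Sequence[GeneSVStatus],
                    status: str) -> set[str]:
    """Genes carrying the same SV status in both strains (a report, not a
    test)."""
    sa = {s.gene_id for s in status_a if s.status == status}
    sb = {s.gene_id for s in status_b if s.status == status}
    return sa & sb
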