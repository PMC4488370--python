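"""Depletion/enrichment of SV-affected genes across homology classes,
domain-defined gene families, and diversity strata."""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
from scipy import stats

from .allele_bias import fdr_correct
from .core_io import DiversityRecord, DomainAnnotation, SVCall, overlap_length
from .homology import HomologyClass

logger = logging.getLogger(__name__)

__all__ = [
    "class_depletion",
    "family_enrichment",
    "family_enrichment_permutation",
    "diversity_by_sv",
]


def class_depletion(sv_genes: set[str],
                    classes: Sequence[HomologyClass]) -> dict[str, dict]:
    """Per homology class: two-sided Fisher's exact test on
    (in class vs not) x (SV-affected vs not), with direction from the odds
    ratio."""
    all_genes = {c.gene_id for c in classes}
    if not sv_genes <= all_genes:
        raise ValueError("sv_genes must be a subset of the classified genes")
    by_class: dict[str, set[str]] = {}
    for c in classes:
        by_class.setdefault(c.homology_class, set()).add(c.gene_id)
    results: dict[str, dict] = {}
    for cls, members in sorted(by_class.items()):
        if not members:
            logger.warning("class %s empty; skipped", cls)
            continue
        a = len(members & sv_genes)
        b = len(sv_genes) - a
        c_ = len(members) - a
        d = len(all_genes) - len(sv_genes) - c_
        odds, p = stats.fisher_exact([[a, b], [c_, d]], alternative="two-sided")
        direction = "enriched" if odds > 1 else ("depleted" if odds < 1 else "none")
        results[cls] = {"odds_ratio": float(odds), "p": float(p),
                        "direction": direction, "sv_in_class": a,
                        "class_size": len(members)}
    return results


def family_enrichment(domains: Sequence[DomainAnnotation], sv_genes: set[str],
                      background: set[str],
                      min_family_size: int = 2) -> list[dict]:
    """Per-domain upper-tail hypergeometric enrichment of SV genes, with
    BH correction across domains.

    For each domain: k = SV genes carrying it, K = background genes
    carrying it, n = |sv_genes|, N = |background|;
    p = P[X >= k], X ~ Hypergeom(N, K, n).
    """
    if not sv_genes <= background:
        raise ValueError("sv_genes must be a subset of background")
    fam: dict[str, set[str]] = {}
    for d in domains:
        if d.gene_id in background:
            fam.setdefault(d.domain_id, set()).add(d.gene_id)
    rows = []
    n = len(sv_genes)
    N = len(background)
    for domain_id, members in sorted(fam.items()):
        K = len(members)
        if K < max(1, min_family_size):
            continue
        k = len(members & sv_genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"domain_id": domain_id, "k": k, "K": K, "n": n, "N": N,
                     "p": p})
    for row, adj in zip(rows, fdr_correct([r["p"] for r in rows])):
        row["p_fdr"] = adj
    return rows


def family_enrichment_permutation(domains: Sequence[DomainAnnotation],
                                  sv_genes: set[str], background: set[str],
                                  n_perm: int = 10_000, seed: int = 0,
                                  min_family_size: int = 2) -> list[dict]:
    """Label-permutation alternative to the hypergeometric null: draw
    |sv_genes| genes from the background n_perm times and report the
    fraction of draws with at least the observed family count (add-one
    estimator)."""
    rng = np.random.default_rng(seed)
    fam: dict[str, set[str]] = {}
    for d in domains:
        if d.gene_id in background:
            fam.setdefault(d.domain_id, set()).add(d.gene_id)
    bg = sorted(background)
    n = len(sv_genes)
    rows = []
    draws = np.array([rng.choice(len(bg), size=n, replace=False)
                      for _ in range(n_perm)])
    idx = {g: i for i, g in enumerate(bg)}
    for domain_id, members in sorted(fam.items()):
        if len(members) < max(1, min_family_size):
            continue
        k_obs = len(members & sv_genes)
        member_idx = np.zeros(len(bg), dtype=bool)
        member_idx[[idx[g] for g in members]] = True
        k_perm = member_idx[draws].sum(axis=1)
        p = (1 + int((k_perm >= k_obs).sum())) / (n_perm + 1)
        rows.append({"domain_id": domain_id, "k": k_obs, "K": len(members),
                     "n": n, "N": len(bg), "p": float(p)})
    return rows


def diversity_by_sv(windows: Sequence[DiversityRecord],
                    calls: Sequence[SVCall]) -> dict:
    """Partition diversity windows by any-SV overlap; report the group
    medians, their ratio (with / without), and a two-sided rank-sum p."""
    with_sv, without_sv = [], []
    for w in windows:
        hit = any(c.contig == w.contig and overlap_length(w.start, w.end, c.start, c.end) > 0
                  for c in calls)
        (with_sv if hit else without_sv).append(w.pi)
    if not with_sv or not without_sv:
        raise ValueError("both window groups must be non-empty")
    median_with = float(np.median(with_sv))
    median_without = float(np.median(without_sv))
    if with_sv == without_sv:
        p = 1.0
    else:
        _, p = stats.mannwhitneyu(with_sv, without_sv, alternative="two-sided")
    return {"median_with": median_with, "median_without": median_without,
            "ratio": median_with / median_without if median_without > 0 else float("inf"),
            "n_with": len(with_sv), "n_without": len(without_sv),
            "p": float(p)}
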