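"""Copy-biased expression from DNA vs RNA allele counts.

The minor allele at a copy-segregating site is decided once, from the DNA
counts, and its frequency is then read off in both data types.  Genes are
tested with a two-sided two-sample rank-sum comparison of the per-site DNA
and RNA frequencies; with <= 20 pooled sites the p-value is computed by
exact enumeration over all rank assignments (ties handled via the
mid-rank-equivalent U statistic), otherwise by the tie-corrected normal
approximation.  Benjamini-Hochberg controls the FDR across genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import SiteAlleleCounts

logger = logging.getLogger(__name__)

__all__ = [
    "BiasResult",
    "select_segregating_sites",
    "minor_allele_freqs",
    "rank_sum_test",
    "gene_bias_test",
    "fdr_correct",
    "analyze_allele_bias",
]

_EXACT_MAX_POOLED = 20  # exact enumeration up to C(20,10) = 184756 splits


@dataclass(frozen=True)
class BiasResult:
    gene_id: str
    n_sites: int
    dna_freqs: tuple[float, ...]
    rna_freqs: tuple[float, ...]
    p_raw: float
    p_fdr: float
    biased: bool

    def __post_init__(self) -> None:
        if self.n_sites != len(self.dna_freqs) or self.n_sites != len(self.rna_freqs):
            raise ValueError("n_sites must match frequency list lengths")
        for f in (*self.dna_freqs, *self.rna_freqs):
            if not 0.0 <= f <= 1.0:
                raise ValueError("frequencies must lie in [0,1]")


def select_segregating_sites(sites: Sequence[SiteAlleleCounts],
                             min_quality: float = 20.0,
                             min_het_support: float = 0.0,
                             min_cov: int = 10) -> list[SiteAlleleCounts]:
    """Keep sites with quality >= min_quality, het support strictly above
    min_het_support, DNA and RNA depth >= min_cov, and an annotated gene."""
    out = []
    for s in sites:
        if s.het_support is None or not s.het_support > min_het_support:
            continue
        if s.site_quality < min_quality:
            continue
        if s.dna_depth < min_cov or s.rna_depth < min_cov:
            continue
        if not s.gene_id:
            continue
        out.append(s)
    return out


def minor_allele_freqs(site: SiteAlleleCounts) -> tuple[float, float]:
    """(dna_freq, rna_freq) of the DNA-minor allele.

    The minor allele is the one with the smaller DNA count; a tie goes to
    the lexicographically smaller nucleotide.  The same allele's fraction
    is reported in both data types.
    """
    if site.dna_depth == 0 or site.rna_depth == 0:
        raise ValueError("minor_allele_freqs requires depth > 0 in both data types")
    if site.dna_count_a < site.dna_count_b:
        minor = "a"
    elif site.dna_count_b < site.dna_count_a:
        minor = "b"
    else:
        minor = "a" if site.allele_a < site.allele_b else "b"
    if minor == "a":
        return (site.dna_count_a / site.dna_depth,
                site.rna_count_a / site.rna_depth)
    return (site.dna_count_b / site.dna_depth,
            site.rna_count_b / site.rna_depth)


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided two-sample rank-sum p-value.

    Exact by enumeration over all C(n+m, n) group assignments when the
    pooled size is small; the statistic is the tie-aware U
    (#{x>y} + 0.5 #{x=y}), whose permutation distribution matches the
    mid-rank rank-sum exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if n + m <= _EXACT_MAX_POOLED:
        diff = pooled[:, None] - pooled[None, :]
        gt = (diff > 0).astype(float) + 0.5 * (diff == 0)
        np.fill_diagonal(gt, 0.0)
        mu = n * m / 2.0
        combs = np.array(list(combinations(range(n + m), n)), dtype=np.intp)
        membership = np.zeros((len(combs), n + m))
        membership[np.arange(len(combs))[:, None], combs] = 1.0
        # U(S) = sum_{i in S} rowsum(i) - sum_{i,j in S} gt[i,j]
        u_all = membership @ gt.sum(axis=1) - ((membership @ gt) * membership).sum(axis=1)
        u_obs = u_all[0]  # lexicographically first combination is (0..n-1) = x
        return float(np.mean(np.abs(u_all - mu) >= np.abs(u_obs - mu) - 1e-12))
    _, p = stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(p)


def gene_bias_test(dna_freqs: Sequence[float], rna_freqs: Sequence[float],
                   paired: bool = False) -> float:
    """Raw p for one gene: rank-sum of DNA vs RNA per-site frequencies.

    Requires >= 2 sites.  paired=True switches to the Wilcoxon signed-rank
    alternative (kept for comparison; underpowered at few sites).
    """
    if len(dna_freqs) < 2 or len(dna_freqs) != len(rna_freqs):
        raise ValueError("need >= 2 paired sites")
    if tuple(dna_freqs) == tuple(rna_freqs):
        return 1.0
    if paired:
        diffs = np.asarray(dna_freqs) - np.asarray(rna_freqs)
        if np.all(diffs == 0):
            return 1.0
        _, p = stats.wilcoxon(diffs, alternative="two-sided", method="auto")
        return float(p)
    return rank_sum_test(dna_freqs, rna_freqs)


def fdr_correct(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values."""
    if len(p_values) == 0:
        return []
    _, adj, _, _ = multipletests(p_values, method="fdr_bh")
    return [float(v) for v in adj]


def analyze_allele_bias(sites: Sequence[SiteAlleleCounts], fdr: float = 0.05,
                        min_quality: float = 20.0, min_cov: int = 10,
                        paired: bool = False) -> list[BiasResult]:
    """Full per-gene analysis: filter sites, compute minor-allele
    frequencies, test each gene with >= 2 sites, BH-correct across genes."""
    kept = select_segregating_sites(sites, min_quality=min_quality,
                                    min_cov=min_cov)
    by_gene: dict[str, list[SiteAlleleCounts]] = {}
    for s in kept:
        by_gene.setdefault(s.gene_id, []).append(s)
    gene_ids, dna_all, rna_all, p_raw = [], [], [], []
    for gid in sorted(by_gene):
        gsites = by_gene[gid]
        if len(gsites) < 2:
            logger.info("gene %s skipped: only %d usable site(s)", gid, len(gsites))
            continue
        freqs = [minor_allele_freqs(s) for s in gsites]
        dna = tuple(f[0] for f in freqs)
        rna = tuple(f[1] for f in freqs)
        gene_ids.append(gid)
        dna_all.append(dna)
        rna_all.append(rna)
        p_raw.append(gene_bias_test(dna, rna, paired=paired))
    p_adj = fdr_correct(p_raw)
    return [BiasResult(gene_id=gid, n_sites=len(dna), dna_freqs=dna,
                       rna_freqs=rna, p_raw=pr, p_fdr=pa, biased=pa < fdr)
            for gid, dna, rna, pr, pa in zip(gene_ids, dna_all, rna_all,
                                             p_raw, p_adj)]
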