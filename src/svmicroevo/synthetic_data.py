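"""Simulators with planted ground truth for every pipeline input.

Each generator draws from its own child RNG stream spawned from the config
seed, so output is deterministic per component and stable when unrelated
knobs change.  Truth objects are returned alongside every dataset and are
sufficient to score the downstream stage that consumes it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_io import (
    CollinearBlock,
    DiversityRecord,
    DomainAnnotation,
    ExpressionRecord,
    GeneModel,
    GenomeAssembly,
    HitRecord,
    LabeledCall,
    SVCall,
    SiteAlleleCounts,
    WindowStat,
    overlap_length,
)

__all__ = [
    "TruthSV",
    "SimulationConfig",
    "simulate_genome",
    "plant_svs",
    "simulate_window_counts",
    "simulate_expression",
    "simulate_segregating_sites",
    "simulate_homology",
    "simulate_gene_orders",
    "simulate_domains",
    "simulate_diversity",
    "label_calls",
    "score_calls",
    "genes_fully_inside",
]

_NUCS = ("A", "C", "G", "T")

# stream ids keep each component's draws independent of the others
_STREAMS = {"genome": 0, "svs": 1, "counts": 2, "expression": 3,
            "sites": 4, "homology": 5, "orders": 6, "diversity": 7,
            "domains": 8}


@dataclass(frozen=True)
class TruthSV:
    contig: str
    start: int
    end: int
    sv_type: str  # "deletion" | "duplication"

    @property
    def copy_factor(self) -> int:
        return 0 if self.sv_type == "deletion" else 2

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    genome_length: int = 10_000_000
    n_genes: int = 2000
    n_deletions: int = 50
    n_duplications: int = 30
    sv_size_range: tuple[int, int] = (2000, 75_000)
    depth_ref: float = 16.0   # control strain mean coverage
    depth_test: float = 12.0  # strain-of-interest mean coverage
    read_length: int = 100
    window_size: int = 1000
    window_step: int | None = None  # default: window_size // 2
    nb_dispersion: float | None = None  # optional negative-binomial overdispersion
    dup_expression_scenario: str = "silent_copy"  # or "additive_dosage"
    expression_log_mean: float = np.log(10.0)
    expression_log_sd: float = 1.5
    expression_noise_sd: float = 0.1
    bias_fraction: float = 0.5
    sites_per_dup_gene: int = 5
    dna_depth: int = 30
    rna_depth: int = 30
    n_rearrangements: int = 5
    diversity_ratio: float = 10.0
    diversity_log_sd: float = 0.5
    pi_with_sv: float = 0.01

    def __post_init__(self) -> None:
        for name in ("genome_length", "n_genes", "n_deletions", "n_duplications",
                     "sites_per_dup_gene", "dna_depth", "rna_depth",
                     "n_rearrangements"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.dup_expression_scenario not in ("silent_copy", "additive_dosage"):
            raise ValueError(f"bad scenario {self.dup_expression_scenario!r}")
        if not 0.0 <= self.bias_fraction <= 1.0:
            raise ValueError("bias_fraction must lie in [0,1]")

    def rng(self, component: str) -> np.random.Generator:
        """Deterministic child RNG for a named component."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed,
                                   spawn_key=(_STREAMS[component],)))


# ---------------------------------------------------------------------------
# Genome and SV truth
# ---------------------------------------------------------------------------


def simulate_genome(cfg: SimulationConfig) -> tuple[GenomeAssembly, list[GeneModel]]:
    """Single-contig assembly with non-overlapping multi-exon genes."""
    if cfg.genome_length < 10 * cfg.sv_size_range[1]:
        raise ValueError("genome_length must be >= 10x the maximum SV size")
    rng = cfg.rng("genome")
    assembly = GenomeAssembly(contigs=(("chrS", cfg.genome_length),))
    if cfg.n_genes == 0:
        return assembly, []
    # Partition the contig into n_genes slots; gene occupies a random
    # sub-interval of its slot so genes never overlap.
    slot = cfg.genome_length // cfg.n_genes
    if slot < 400:
        raise ValueError("too many genes for genome_length (slots < 400bp)")
    genes: list[GeneModel] = []
    for i in range(cfg.n_genes):
        slot_start = i * slot
        glen = int(rng.integers(300, min(5000, slot - 50) + 1))
        gstart = slot_start + int(rng.integers(0, slot - glen + 1))
        n_exons = int(rng.integers(1, 11))
        # cut the span into 2*n_exons-1 alternating exon/intron pieces
        bounds = np.sort(rng.choice(np.arange(1, glen), size=2 * n_exons - 2,
                                    replace=False)) if n_exons > 1 else np.array([], dtype=int)
        edges = np.concatenate(([0], bounds, [glen]))
        exons = tuple((gstart + int(edges[2 * k]), gstart + int(edges[2 * k + 1]))
                      for k in range(n_exons))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(gene_id=f"g{i:05d}", contig="chrS",
                               start=gstart, end=gstart + glen,
                               strand=strand, exons=exons))
    return assembly, genes


def plant_svs(cfg: SimulationConfig, assembly: GenomeAssembly) -> list[TruthSV]:
    """Plant mutually non-overlapping deletion/duplication truth intervals
    with sizes uniform in cfg.sv_size_range."""
    rng = cfg.rng("svs")
    n_total = cfg.n_deletions + cfg.n_duplications
    if n_total == 0:
        return []
    contig, length = assembly.contigs[0]
    lo, hi = cfg.sv_size_range
    if lo < 2000:
        raise ValueError("sv sizes must be >= 2000")
    placed: list[tuple[int, int]] = []
    sizes = rng.integers(lo, hi + 1, size=n_total)
    for sz in sizes:
        for _ in range(1000):
            s = int(rng.integers(0, length - sz + 1))
            e = s + int(sz)
            if all(overlap_length(s, e, ps, pe) == 0 for ps, pe in placed):
                placed.append((s, e))
                break
        else:
            raise ValueError("could not place SVs without overlap; reduce counts")
    return ([TruthSV(contig, s, e, "deletion") for s, e in placed[:cfg.n_deletions]]
            + [TruthSV(contig, s, e, "duplication")
               for s, e in placed[cfg.n_deletions:]])


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------


def _window_copy_factors(windows: Sequence[tuple[str, int, int]],
                         truth: Sequence[TruthSV]) -> np.ndarray:
    """Length-weighted mean copy factor per window (0 in deletions, 2 in
    duplications, 1 elsewhere)."""
    factors = np.ones(len(windows))
    starts = np.array([w[1] for w in windows])
    ends = np.array([w[2] for w in windows])
    widths = (ends - starts).astype(float)
    for sv in truth:
        ov = np.clip(np.minimum(ends, sv.end) - np.maximum(starts, sv.start), 0, None)
        delta = (sv.copy_factor - 1) * ov / widths
        same = np.array([w[0] == sv.contig for w in windows])
        factors += np.where(same, delta, 0.0)
    return factors


def simulate_window_counts(cfg: SimulationConfig,
                           assembly: GenomeAssembly,
                           truth: Sequence[TruthSV],
                           windows: Sequence[tuple[str, int, int]] | None = None,
                           ) -> list[WindowStat]:
    """Poisson read counts per window for control and test samples.

    Expected count is depth * width / read_length, scaled in the test
    sample by the window's (length-weighted) planted copy factor.  An
    optional negative-binomial dispersion knob models overdispersion.
    """
    from .sv_caller import make_windows  # local import to avoid a cycle

    if windows is None:
        step = cfg.window_step if cfg.window_step is not None else max(1, cfg.window_size // 2)
        windows = make_windows(assembly, cfg.window_size, step)
    rng = cfg.rng("counts")
    widths = np.array([e - s for _, s, e in windows], dtype=float)
    mu_ref = cfg.depth_ref * widths / cfg.read_length
    factors = _window_copy_factors(windows, truth)
    mu_test = cfg.depth_test * widths / cfg.read_length * factors

    def draw(mu: np.ndarray) -> np.ndarray:
        if cfg.nb_dispersion is None:
            return rng.poisson(mu)
        r = 1.0 / cfg.nb_dispersion
        lam = np.where(mu > 0, rng.gamma(r, np.maximum(mu, 1e-300) / r), 0.0)
        return rng.poisson(lam)

    count_ref = draw(mu_ref)
    count_test = draw(mu_test)
    return [WindowStat(contig=c, start=s, end=e,
                       count_ref=int(count_ref[i]), count_test=int(count_test[i]))
            for i, (c, s, e) in enumerate(windows)]


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def genes_fully_inside(genes: Sequence[GeneModel],
                       intervals: Sequence, sv_type: str | None = None) -> set[str]:
    """Ids of genes whose full span is contained in some interval (optionally
    restricted to one sv_type)."""
    out: set[str] = set()
    for g in genes:
        for iv in intervals:
            if sv_type is not None and iv.sv_type != sv_type:
                continue
            if iv.contig == g.contig and iv.start <= g.start and g.end <= iv.end:
                out.add(g.gene_id)
                break
    return out


def simulate_expression(cfg: SimulationConfig, genes: Sequence[GeneModel],
                        truth: Sequence[TruthSV]) -> list[ExpressionRecord]:
    """Two-sample FPKM table: log-normal baseline shared between samples,
    multiplicative log-normal noise, deletion -> 0 in the test sample,
    duplication -> x2 (additive_dosage) or x1 (silent_copy)."""
    rng = cfg.rng("expression")
    deleted = genes_fully_inside(genes, truth, "deletion")
    duplicated = genes_fully_inside(genes, truth, "duplication")
    dup_scale = 2.0 if cfg.dup_expression_scenario == "additive_dosage" else 1.0
    records: list[ExpressionRecord] = []
    for g in genes:
        base = float(np.exp(rng.normal(cfg.expression_log_mean, cfg.expression_log_sd)))
        noise_ref = float(np.exp(rng.normal(0.0, cfg.expression_noise_sd)))
        noise_test = float(np.exp(rng.normal(0.0, cfg.expression_noise_sd)))
        fpkm_ref = base * noise_ref
        if g.gene_id in deleted:
            fpkm_test = 0.0
        elif g.gene_id in duplicated:
            fpkm_test = base * dup_scale * noise_test
        else:
            fpkm_test = base * noise_test
        records.append(ExpressionRecord(g.gene_id, "ref", fpkm_ref))
        records.append(ExpressionRecord(g.gene_id, "test", fpkm_test))
    return records


# ---------------------------------------------------------------------------
# Copy-segregating sites
# ---------------------------------------------------------------------------


def simulate_segregating_sites(cfg: SimulationConfig,
                               duplicated_genes: Sequence[GeneModel],
                               ) -> tuple[list[SiteAlleleCounts], set[str]]:
    """Sites segregating between duplicate copies, with DNA counts at
    Binomial(depth, 0.5) and RNA counts at Binomial(depth, p) where p = 0.5
    for unbiased genes and p = 0 (allele b silent) for a bias_fraction of
    genes.  Returns (sites, ids of biased genes)."""
    rng = cfg.rng("sites")
    sites: list[SiteAlleleCounts] = []
    biased: set[str] = set()
    n_biased = int(round(cfg.bias_fraction * len(duplicated_genes)))
    if duplicated_genes and n_biased > 0:
        idx = rng.choice(len(duplicated_genes), size=n_biased, replace=False)
        biased = {duplicated_genes[int(i)].gene_id for i in idx}
    for g in duplicated_genes:
        if cfg.sites_per_dup_gene == 0 or g.length < cfg.sites_per_dup_gene:
            continue
        positions = np.sort(rng.choice(np.arange(g.start, g.end),
                                       size=cfg.sites_per_dup_gene, replace=False))
        p_rna = 0.0 if g.gene_id in biased else 0.5
        for pos in positions:
            a, b = rng.choice(4, size=2, replace=False)
            allele_a, allele_b = _NUCS[int(a)], _NUCS[int(b)]
            dna_b = int(rng.binomial(cfg.dna_depth, 0.5))
            dna_a = cfg.dna_depth - dna_b
            # the silenced copy carries the DNA-minor allele (tie broken by
            # the lexicographically smaller nucleotide, matching the caller)
            if dna_a < dna_b or (dna_a == dna_b and allele_a < allele_b):
                minor = "a"
            else:
                minor = "b"
            rna_minor = int(rng.binomial(cfg.rna_depth, p_rna))
            rna_a = rna_minor if minor == "a" else cfg.rna_depth - rna_minor
            sites.append(SiteAlleleCounts(
                contig=g.contig, pos=int(pos), gene_id=g.gene_id,
                allele_a=allele_a, allele_b=allele_b,
                dna_count_a=dna_a, dna_count_b=dna_b,
                rna_count_a=rna_a, rna_count_b=cfg.rna_depth - rna_a,
                site_quality=float(rng.integers(20, 60)),
                het_support=float(rng.integers(1, 100))))
    return sites, biased


# ---------------------------------------------------------------------------
# Homology
# ---------------------------------------------------------------------------

_CLASSES = ("one_to_one", "singleton_with_homologs", "with_paralogs_conserved",
            "orphan_singleton", "orphan_with_paralogs")


def simulate_homology(cfg: SimulationConfig, n_genes: int | None = None,
                      focal: str = "Ppa", other: str = "Cel",
                      focal_ids: Sequence[str] | None = None,
                      ) -> tuple[list[HitRecord], dict[str, str]]:
    """Two-species hit table realizing planted homology classes.

    Returns (hits, truth) where truth maps each focal gene id to its class.
    The construction guarantees the classifier rules recover the classes:
    one_to_one pairs are clean reciprocal best hits; conserved/orphan
    paralog clusters get intra-species edges; orphans lack inter-species
    hits entirely.
    """
    rng = cfg.rng("homology")
    if focal_ids is not None:
        n_genes = len(focal_ids)
    elif n_genes is None:
        n_genes = cfg.n_genes

    def fid(k: int) -> str:
        return focal_ids[k] if focal_ids is not None else f"{focal}_{k:05d}"

    hits: list[HitRecord] = []
    truth: dict[str, str] = {}
    i = 0
    b_idx = 0

    def inter(a: str, b: str, score: float) -> None:
        hits.append(HitRecord(a, b, focal, other, score, 1e-50))
        hits.append(HitRecord(b, a, other, focal, score, 1e-50))

    def intra(a: str, b: str, score: float, sp: str) -> None:
        hits.append(HitRecord(a, b, sp, sp, score, 1e-40))

    while i < n_genes:
        cls = _CLASSES[int(rng.integers(0, len(_CLASSES)))]
        if i + 1 >= n_genes and cls in ("with_paralogs_conserved", "orphan_with_paralogs"):
            cls = "orphan_singleton"  # paralog classes need two gene slots
        if cls == "one_to_one":
            a = fid(i)
            b = f"{other}_{b_idx:05d}"
            inter(a, b, float(rng.uniform(200, 400)))
            truth[a] = cls
            i += 1
            b_idx += 1
        elif cls == "singleton_with_homologs":
            # single focal copy hitting a pair of ortholog-species inparalogs
            a = fid(i)
            b1 = f"{other}_{b_idx:05d}"
            b2 = f"{other}_{b_idx + 1:05d}"
            s = float(rng.uniform(150, 250))
            inter(a, b1, s)
            inter(a, b2, s - float(rng.uniform(5, 20)))
            intra(b1, b2, s + float(rng.uniform(10, 50)), other)
            truth[a] = cls
            i += 1
            b_idx += 2
        elif cls == "with_paralogs_conserved":
            a1 = fid(i)
            a2 = fid(i + 1)
            b = f"{other}_{b_idx:05d}"
            s = float(rng.uniform(150, 250))
            inter(a1, b, s)
            inter(a2, b, s - float(rng.uniform(5, 20)))
            intra(a1, a2, s + float(rng.uniform(10, 50)), focal)
            truth[a1] = cls
            truth[a2] = cls
            i += 2
            b_idx += 1
        elif cls == "orphan_singleton":
            a = fid(i)
            truth[a] = cls
            i += 1
        else:  # orphan_with_paralogs
            a1 = fid(i)
            a2 = fid(i + 1)
            intra(a1, a2, float(rng.uniform(100, 300)), focal)
            truth[a1] = cls
            truth[a2] = cls
            i += 2
    return hits, truth


def simulate_domains(cfg: SimulationConfig, gene_ids: Sequence[str],
                     n_families: int = 40,
                     annotated_fraction: float = 0.6) -> list[DomainAnnotation]:
    """Random PFAM-style domain annotations: an annotated_fraction of genes
    gets one domain drawn from n_families with a skewed (Zipf-like) family
    size distribution."""
    rng = cfg.rng("domains")
    weights = 1.0 / np.arange(1, n_families + 1)
    weights /= weights.sum()
    out = []
    for gid in gene_ids:
        if rng.random() < annotated_fraction:
            fam = int(rng.choice(n_families, p=weights))
            out.append(DomainAnnotation(gene_id=gid, domain_id=f"PF{fam:05d}"))
    return out


# ---------------------------------------------------------------------------
# Gene orders / collinearity truth
# ---------------------------------------------------------------------------


def simulate_gene_orders(cfg: SimulationConfig, genes: Sequence[GeneModel],
                         ) -> tuple[list[str], dict[str, str], list[CollinearBlock]]:
    """Outgroup gene order built by random inversions/translocations of runs.

    Returns (order_B of outgroup gene ids, ortholog map A->B, truth blocks).
    Truth blocks are the maximal runs of consecutive A-genes whose outgroup
    partners are consecutive (same or reversed direction) in order_B,
    computed by a direct position scan.
    """
    rng = cfg.rng("orders")
    order_a = sorted(genes, key=lambda g: (g.contig, g.start))
    ortholog_map = {g.gene_id: f"B_{g.gene_id}" for g in order_a}
    order_b = [f"B_{g.gene_id}" for g in order_a]
    n = len(order_b)
    for _ in range(cfg.n_rearrangements):
        if n < 2:
            break
        i = int(rng.integers(0, n - 1))
        j = int(rng.integers(i + 1, n + 1))
        run = order_b[i:j]
        if rng.random() < 0.5:
            order_b[i:j] = run[::-1]  # inversion
        else:  # translocation of the run to a random position
            rest = order_b[:i] + order_b[j:]
            k = int(rng.integers(0, len(rest) + 1))
            order_b = rest[:k] + run + rest[k:]
    pos_b = {gid: k for k, gid in enumerate(order_b)}
    truth_blocks = _maximal_runs(order_a, ortholog_map, pos_b)
    return order_b, ortholog_map, truth_blocks


def _maximal_runs(order_a: Sequence[GeneModel], ortholog_map: dict[str, str],
                  pos_b: dict[str, int], min_len: int = 2) -> list[CollinearBlock]:
    """Scan-based maximal-run finder used to derive truth blocks."""
    blocks: list[CollinearBlock] = []
    i = 0
    n = len(order_a)
    while i < n:
        j = i + 1
        direction = 0
        while j < n:
            d = pos_b[ortholog_map[order_a[j].gene_id]] - pos_b[ortholog_map[order_a[j - 1].gene_id]]
            if d not in (1, -1):
                break
            if direction == 0:
                direction = d
            elif d != direction:
                break
            j += 1
        if j - i >= min_len:
            members = order_a[i:j]
            blocks.append(CollinearBlock(
                pairs=tuple((g.gene_id, ortholog_map[g.gene_id]) for g in members),
                span_a=(members[0].contig, members[0].start, members[-1].end),
                orientation="same" if direction >= 0 else "reversed"))
            i = j
        else:
            i += 1
    return blocks


# ---------------------------------------------------------------------------
# Diversity
# ---------------------------------------------------------------------------


def simulate_diversity(cfg: SimulationConfig,
                       windows: Sequence[tuple[str, int, int]],
                       calls: Sequence[SVCall] | Sequence[TruthSV],
                       ) -> list[DiversityRecord]:
    """Per-window nucleotide diversity: windows overlapping any SV draw pi
    around cfg.pi_with_sv, SV-free windows around pi_with_sv / ratio."""
    rng = cfg.rng("diversity")
    records = []
    for contig, start, end in windows:
        has_sv = any(c.contig == contig and overlap_length(start, end, c.start, c.end) > 0
                     for c in calls)
        median = cfg.pi_with_sv if has_sv else cfg.pi_with_sv / cfg.diversity_ratio
        pi = float(median * np.exp(rng.normal(0.0, cfg.diversity_log_sd)))
        records.append(DiversityRecord(contig=contig, start=start, end=end, pi=pi))
    return records


# ---------------------------------------------------------------------------
# Scoring against truth
# ---------------------------------------------------------------------------


def label_calls(calls: Sequence[SVCall], truth: Sequence[TruthSV],
                min_overlap_frac: float = 0.5) -> list[LabeledCall]:
    """Label each call true_positive if >= min_overlap_frac of its length
    overlaps a truth interval of the same type, else false_positive."""
    labeled = []
    for c in calls:
        ov = sum(overlap_length(c.start, c.end, t.start, t.end)
                 for t in truth if t.contig == c.contig and t.sv_type == c.sv_type)
        label = "true_positive" if ov >= min_overlap_frac * c.length else "false_positive"
        labeled.append(LabeledCall(call=c, label=label))
    return labeled


def score_calls(calls: Sequence[SVCall], truth: Sequence[TruthSV],
                min_overlap_frac: float = 0.5) -> dict[str, dict[str, float]]:
    """Per-type TPR (truth intervals recovered) and FDR (calls not matching
    truth).  A truth interval is recovered when calls of its type cover at
    least min_overlap_frac of it."""
    out: dict[str, dict[str, float]] = {}
    for sv_type in ("deletion", "duplication"):
        truths = [t for t in truth if t.sv_type == sv_type]
        cs = [c for c in calls if c.sv_type == sv_type]
        recovered = 0
        for t in truths:
            cov = sum(overlap_length(t.start, t.end, c.start, c.end)
                      for c in cs if c.contig == t.contig)
            if cov >= min_overlap_frac * t.length:
                recovered += 1
        labeled = label_calls(cs, truth, min_overlap_frac)
        n_fp = sum(1 for lc in labeled if lc.label == "false_positive")
        out[sv_type] = {
            "n_truth": len(truths),
            "n_calls": len(cs),
            "tpr": recovered / len(truths) if truths else float("nan"),
            "fdr": n_fp / len(cs) if cs else 0.0,
        }
    return out
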