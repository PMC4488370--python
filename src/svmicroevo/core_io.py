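"""Domain types, coordinate conventions, and readers/writers.

All genomic intervals are 0-based half-open internally.  GFF3 (1-based
closed) and VCF (1-based positions) are converted on read; BED is written
natively.  TSV files carry a header line and round-trip exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeAssembly",
    "GeneModel",
    "WindowStat",
    "SVCall",
    "LabeledCall",
    "RocPoint",
    "ExpressionRecord",
    "SiteAlleleCounts",
    "HitRecord",
    "DomainAnnotation",
    "CollinearBlock",
    "DiversityRecord",
    "overlap_length",
    "read_gff",
    "write_gff",
    "read_vcf_sites",
    "write_vcf_sites",
    "read_bed_calls",
    "write_bed",
    "read_window_counts",
    "write_window_counts",
    "read_expression",
    "write_expression",
    "read_site_counts",
    "write_site_counts",
    "read_hits",
    "write_hits",
    "read_domains",
    "write_domains",
    "read_diversity",
    "write_diversity",
]


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeAssembly:
    """Reference backbone: ordered contigs with lengths in bases."""

    contigs: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        ids = [c for c, _ in self.contigs]
        if len(set(ids)) != len(ids):
            raise ValueError("contig ids must be unique")
        for cid, length in self.contigs:
            if length <= 0:
                raise ValueError(f"contig {cid!r} has non-positive length {length}")

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.contigs)

    def length_of(self, contig: str) -> int:
        for cid, length in self.contigs:
            if cid == contig:
                return length
        raise KeyError(contig)


@dataclass(frozen=True)
class GeneModel:
    """Gene span from first to last exon (introns included)."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        prev_end = None
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) outside gene span")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = e

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class WindowStat:
    """Paired coverage counts for one window, with log2 fold change and p."""

    contig: str
    start: int
    end: int
    count_ref: int
    count_test: int
    log2_fc: float = float("nan")
    p_value: float = float("nan")

    def __post_init__(self) -> None:
        if self.count_ref < 0 or self.count_test < 0:
            raise ValueError("counts must be >= 0")
        if not math.isnan(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0,1]")


@dataclass(frozen=True)
class SVCall:
    """Merged deletion/duplication interval with summary scores."""

    contig: str
    start: int
    end: int
    sv_type: str  # "deletion" | "duplication"
    strain: str = ""
    min_p: float = float("nan")
    mean_log2_fc: float = float("nan")
    polarized: str = "unknown"  # "true" | "false" | "unknown"

    def __post_init__(self) -> None:
        if self.sv_type not in ("deletion", "duplication"):
            raise ValueError(f"bad sv_type {self.sv_type!r}")
        if self.polarized not in ("true", "false", "unknown"):
            raise ValueError(f"bad polarized flag {self.polarized!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class LabeledCall:
    call: SVCall
    label: str  # "true_positive" | "false_positive"

    def __post_init__(self) -> None:
        if self.label not in ("true_positive", "false_positive"):
            raise ValueError(f"bad label {self.label!r}")


@dataclass(frozen=True)
class RocPoint:
    p_cutoff: float
    fc_cutoff: float
    tpr: float
    fpr: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.tpr <= 1.0 and 0.0 <= self.fpr <= 1.0):
            raise ValueError("tpr/fpr must lie in [0,1]")


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    sample: str
    fpkm: float

    def __post_init__(self) -> None:
        if self.fpkm < 0:
            raise ValueError(f"{self.gene_id}: negative FPKM")


@dataclass(frozen=True)
class SiteAlleleCounts:
    """An apparently heterozygous site, i.e. one segregating between copies."""

    contig: str
    pos: int
    gene_id: str
    allele_a: str
    allele_b: str
    dna_count_a: int
    dna_count_b: int
    rna_count_a: int
    rna_count_b: int
    site_quality: float
    het_support: float | None

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise ValueError("allele_a must differ from allele_b")
        for c in (self.dna_count_a, self.dna_count_b, self.rna_count_a, self.rna_count_b):
            if c < 0:
                raise ValueError("allele counts must be >= 0")

    @property
    def dna_depth(self) -> int:
        return self.dna_count_a + self.dna_count_b

    @property
    def rna_depth(self) -> int:
        return self.rna_count_a + self.rna_count_b


@dataclass(frozen=True)
class HitRecord:
    query_id: str
    subject_id: str
    query_species: str
    subject_species: str
    bitscore: float
    evalue: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if self.query_id == self.subject_id and self.query_species == self.subject_species:
            raise ValueError("self-hits are excluded")


@dataclass(frozen=True)
class DomainAnnotation:
    gene_id: str
    domain_id: str


@dataclass(frozen=True)
class CollinearBlock:
    """Maximal run of ortholog pairs with preserved order in both genomes."""

    pairs: tuple[tuple[str, str], ...]
    span_a: tuple[str, int, int]
    orientation: str  # "same" | "reversed"

    def __post_init__(self) -> None:
        if len(self.pairs) < 2:
            raise ValueError("a collinear block needs >= 2 ortholog pairs")
        if self.orientation not in ("same", "reversed"):
            raise ValueError(f"bad orientation {self.orientation!r}")


@dataclass(frozen=True)
class DiversityRecord:
    contig: str
    start: int
    end: int
    pi: float

    def __post_init__(self) -> None:
        if self.pi < 0:
            raise ValueError("pi must be >= 0")


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------


def overlap_length(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Overlap of two half-open intervals; [0,10) vs [10,20) overlaps by 0."""
    return max(0, min(a_end, b_end) - max(a_start, b_start))


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def _gff_attributes(raw: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in raw.strip().rstrip(";").split(";"):
        if not item:
            continue
        if "=" not in item:
            continue
        k, v = item.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def read_gff(path: str | Path) -> list[GeneModel]:
    """Parse a GFF3 with gene and exon features into GeneModel records.

    Coordinates are converted from 1-based closed to 0-based half-open.
    Raises :class:`ParseError` naming the line number on malformed input.
    """
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated fields")
            contig, _, ftype, start_s, end_s, _, strand, _, attrs_s = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            start, end = start1 - 1, end1  # to 0-based half-open
            attrs = _gff_attributes(attrs_s)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise ParseError(f"{path}:{lineno}: gene feature without ID")
                genes[gid] = {"contig": contig, "start": start, "end": end,
                              "strand": strand, "exons": []}
                order.append(gid)
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent is None:
                    raise ParseError(f"{path}:{lineno}: exon without Parent")
                if parent not in genes:
                    raise ParseError(f"{path}:{lineno}: exon Parent {parent!r} unknown")
                genes[parent]["exons"].append((start, end))
    out = []
    for gid in order:
        g = genes[gid]
        exons = tuple(sorted(g["exons"])) or ((g["start"], g["end"]),)
        out.append(GeneModel(gene_id=gid, contig=g["contig"], start=g["start"],
                             end=g["end"], strand=g["strand"], exons=exons))
    return out


def write_gff(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.contig}\tsvmicroevo\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(f"{g.contig}\tsvmicroevo\texon\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t.\tID={g.gene_id}.e{i};Parent={g.gene_id}\n")


# ---------------------------------------------------------------------------
# VCF — biallelic SNV sites with QUAL and an FQ-like heterozygosity score.
# DNA allele counts travel in the INFO fields DCA/DCB; RNA counts come from
# a separate TSV (see read_site_counts).
# ---------------------------------------------------------------------------

_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=FQ,Number=1,Type=Float,Description="Consensus/heterozygosity support score">
##INFO=<ID=DCA,Number=1,Type=Integer,Description="DNA read count of REF allele">
##INFO=<ID=DCB,Number=1,Type=Integer,Description="DNA read count of ALT allele">
##INFO=<ID=GENE,Number=1,Type=String,Description="Overlapping gene id">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def _parse_info(raw: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in raw.split(";"):
        if not item or item == ".":
            continue
        if "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
        else:
            out[item] = ""
    return out


def read_vcf_sites(path: str | Path) -> list[SiteAlleleCounts]:
    """Read biallelic SNV sites; multiallelic records are skipped with a warning.

    Only the DNA-side fields are populated (RNA counts default to 0 and are
    merged in from the allele-count TSV downstream).  Records lacking an
    FQ-like field get ``het_support=None`` and are excluded by the
    segregating-site filter.
    """
    sites: list[SiteAlleleCounts] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ParseError(f"{path}:{lineno}: expected >= 8 VCF fields")
            chrom, pos_s, _, ref, alt, qual_s, _, info_s = fields[:8]
            if "," in alt or len(ref) != 1 or any(len(a) != 1 for a in alt.split(",")):
                logger.warning("%s:%d: skipping non-biallelic-SNV record", path, lineno)
                continue
            info = _parse_info(info_s)
            fq = float(info["FQ"]) if "FQ" in info else None
            sites.append(SiteAlleleCounts(
                contig=chrom,
                pos=int(pos_s) - 1,
                gene_id=info.get("GENE", ""),
                allele_a=ref,
                allele_b=alt,
                dna_count_a=int(info.get("DCA", 0)),
                dna_count_b=int(info.get("DCB", 0)),
                rna_count_a=0,
                rna_count_b=0,
                site_quality=float(qual_s),
                het_support=fq,
            ))
    return sites


def write_vcf_sites(sites: Sequence[SiteAlleleCounts], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for s in sites:
            info = [f"DCA={s.dna_count_a}", f"DCB={s.dna_count_b}"]
            if s.het_support is not None:
                info.insert(0, f"FQ={s.het_support:g}")
            if s.gene_id:
                info.append(f"GENE={s.gene_id}")
            fh.write(f"{s.contig}\t{s.pos + 1}\t.\t{s.allele_a}\t{s.allele_b}\t"
                     f"{s.site_quality:g}\t.\t{';'.join(info)}\n")


# ---------------------------------------------------------------------------
# BED (SV calls)
# ---------------------------------------------------------------------------

_BED_SCORE_CAP = 1000.0


def write_bed(calls: Sequence[SVCall], path: str | Path) -> None:
    """BED6+ with name=sv_type and score = 10 * -log10(min_p) capped at 1000
    (the usual 0-1000 BED score range; p = 1e-10 maps to 100).

    Extra columns (strain, min_p, mean_log2_fc, polarized) make the write
    lossless so read_bed_calls round-trips exactly.
    """
    with open(path, "w") as fh:
        fh.write("#contig\tstart\tend\tname\tscore\tstrand\t"
                 "strain\tmin_p\tmean_log2_fc\tpolarized\n")
        for c in calls:
            if math.isnan(c.min_p):
                score = 0.0
            elif c.min_p <= 0:
                score = _BED_SCORE_CAP
            else:
                score = min(_BED_SCORE_CAP, -10.0 * math.log10(c.min_p))
            fh.write(f"{c.contig}\t{c.start}\t{c.end}\t{c.sv_type}\t{score:g}\t.\t"
                     f"{c.strain}\t{c.min_p!r}\t{c.mean_log2_fc!r}\t{c.polarized}\n")


def read_bed_calls(path: str | Path) -> list[SVCall]:
    calls: list[SVCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected >= 6 BED fields")
            contig, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            strain = fields[6] if len(fields) > 6 else ""
            min_p = float(fields[7]) if len(fields) > 7 else float("nan")
            mean_fc = float(fields[8]) if len(fields) > 8 else float("nan")
            polarized = fields[9] if len(fields) > 9 else "unknown"
            calls.append(SVCall(contig=contig, start=start, end=end, sv_type=name,
                                strain=strain, min_p=min_p, mean_log2_fc=mean_fc,
                                polarized=polarized))
    return calls


# ---------------------------------------------------------------------------
# TSV tables (pandas-backed, header always present)
# ---------------------------------------------------------------------------


def write_window_counts(stats: Sequence[WindowStat], path: str | Path) -> None:
    df = pd.DataFrame([{
        "contig": w.contig, "start": w.start, "end": w.end,
        "count_ref": w.count_ref, "count_test": w.count_test,
        "log2_fc": w.log2_fc, "p_value": w.p_value,
    } for w in stats])
    if df.empty:
        df = pd.DataFrame(columns=["contig", "start", "end", "count_ref",
                                   "count_test", "log2_fc", "p_value"])
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_window_counts(path: str | Path) -> list[WindowStat]:
    df = pd.read_csv(path, sep="\t")
    return [WindowStat(contig=str(r.contig), start=int(r.start), end=int(r.end),
                       count_ref=int(r.count_ref), count_test=int(r.count_test),
                       log2_fc=float(getattr(r, "log2_fc", float("nan"))),
                       p_value=float(getattr(r, "p_value", float("nan"))))
            for r in df.itertuples(index=False)]


def write_expression(records: Sequence[ExpressionRecord], path: str | Path) -> None:
    df = pd.DataFrame([{"gene_id": r.gene_id, "sample": r.sample, "fpkm": r.fpkm}
                       for r in records])
    if df.empty:
        df = pd.DataFrame(columns=["gene_id", "sample", "fpkm"])
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_expression(path: str | Path) -> list[ExpressionRecord]:
    df = pd.read_csv(path, sep="\t")
    return [ExpressionRecord(gene_id=str(r.gene_id), sample=str(r.sample),
                             fpkm=float(r.fpkm))
            for r in df.itertuples(index=False)]


_SITE_COLS = ["contig", "pos", "gene_id", "allele_a", "allele_b",
              "dna_count_a", "dna_count_b", "rna_count_a", "rna_count_b",
              "site_quality", "het_support"]


def write_site_counts(sites: Sequence[SiteAlleleCounts], path: str | Path) -> None:
    df = pd.DataFrame([{
        "contig": s.contig, "pos": s.pos, "gene_id": s.gene_id,
        "allele_a": s.allele_a, "allele_b": s.allele_b,
        "dna_count_a": s.dna_count_a, "dna_count_b": s.dna_count_b,
        "rna_count_a": s.rna_count_a, "rna_count_b": s.rna_count_b,
        "site_quality": s.site_quality,
        "het_support": "" if s.het_support is None else s.het_support,
    } for s in sites])
    if df.empty:
        df = pd.DataFrame(columns=_SITE_COLS)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_site_counts(path: str | Path) -> list[SiteAlleleCounts]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for r in df.itertuples(index=False):
        het = r.het_support
        het = None if het == "" else float(het)
        out.append(SiteAlleleCounts(
            contig=str(r.contig), pos=int(r.pos), gene_id=str(r.gene_id),
            allele_a=str(r.allele_a), allele_b=str(r.allele_b),
            dna_count_a=int(r.dna_count_a), dna_count_b=int(r.dna_count_b),
            rna_count_a=int(r.rna_count_a), rna_count_b=int(r.rna_count_b),
            site_quality=float(r.site_quality), het_support=het))
    return out


def write_hits(hits: Sequence[HitRecord], path: str | Path) -> None:
    df = pd.DataFrame([{
        "query_id": h.query_id, "subject_id": h.subject_id,
        "query_species": h.query_species, "subject_species": h.subject_species,
        "bitscore": h.bitscore, "evalue": h.evalue,
    } for h in hits])
    if df.empty:
        df = pd.DataFrame(columns=["query_id", "subject_id", "query_species",
                                   "subject_species", "bitscore", "evalue"])
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_hits(path: str | Path) -> list[HitRecord]:
    df = pd.read_csv(path, sep="\t")
    return [HitRecord(query_id=str(r.query_id), subject_id=str(r.subject_id),
                      query_species=str(r.query_species),
                      subject_species=str(r.subject_species),
                      bitscore=float(r.bitscore), evalue=float(r.evalue))
            for r in df.itertuples(index=False)]


def write_domains(domains: Sequence[DomainAnnotation], path: str | Path) -> None:
    df = pd.DataFrame([{"gene_id": d.gene_id, "domain_id": d.domain_id}
                       for d in domains])
    if df.empty:
        df = pd.DataFrame(columns=["gene_id", "domain_id"])
    df.to_csv(path, sep="\t", index=False)


def read_domains(path: str | Path) -> list[DomainAnnotation]:
    df = pd.read_csv(path, sep="\t")
    return [DomainAnnotation(gene_id=str(r.gene_id), domain_id=str(r.domain_id))
            for r in df.itertuples(index=False)]


def write_diversity(records: Sequence[DiversityRecord], path: str | Path) -> None:
    df = pd.DataFrame([{"contig": r.contig, "start": r.start, "end": r.end,
                        "pi": r.pi} for r in records])
    if df.empty:
        df = pd.DataFrame(columns=["contig", "start", "end", "pi"])
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_diversity(path: str | Path) -> list[DiversityRecord]:
    df = pd.read_csv(path, sep="\t")
    return [DiversityRecord(contig=str(r.contig), start=int(r.start),
                            end=int(r.end), pi=float(r.pi))
            for r in df.itertuples(index=False)]
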