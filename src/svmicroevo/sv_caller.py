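"""Differential read-coverage SV calling with ROC-calibrated thresholds.

The per-window test conditions the two Poisson counts on their sum: given
``n = count_ref + count_test``, the test count is Binomial(n, q) with
``q = total_test / (total_ref + total_test)`` under the null of equal
per-read rates.  The two-sided p-value uses the minimum-likelihood rule
(sum of outcome probabilities <= the observed one).  The log2 fold change
carries a 0.5 pseudocount on both counts so it stays finite at zero
coverage; the pseudocount never enters the p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core_io import (
    GenomeAssembly,
    LabeledCall,
    RocPoint,
    SVCall,
    WindowStat,
    overlap_length,
)

__all__ = [
    "ThresholdPolicy",
    "STRAIN_POLICIES",
    "make_windows",
    "window_test",
    "binom_minlike_pvalue",
    "compute_window_stats",
    "apply_thresholds",
    "merge_calls",
    "roc_curve",
    "pick_operating_point",
    "genome_fraction",
]

# Relative slack when comparing pmf values for the minimum-likelihood rule;
# guards against spurious tie-breaking from floating-point noise.
_MINLIKE_RTOL = 1e-7


@dataclass(frozen=True)
class ThresholdPolicy:
    """Per-strain, per-type retention cutoffs on (log2 fold change, p)."""

    strain: str
    sv_type: str  # "deletion" | "duplication"
    fc_cutoff: float
    p_cutoff: float

    def __post_init__(self) -> None:
        if self.sv_type == "deletion" and self.fc_cutoff >= 0:
            raise ValueError("deletion policies need fc_cutoff < 0")
        if self.sv_type == "duplication" and self.fc_cutoff <= 0:
            raise ValueError("duplication policies need fc_cutoff > 0")
        if self.sv_type not in ("deletion", "duplication"):
            raise ValueError(f"bad sv_type {self.sv_type!r}")


#: Pre-calibrated operating points for the two resequenced strains.
STRAIN_POLICIES: dict[tuple[str, str], ThresholdPolicy] = {
    ("RS5410", "duplication"): ThresholdPolicy("RS5410", "duplication", 1.01, 1e-15),
    ("RS5410", "deletion"): ThresholdPolicy("RS5410", "deletion", -1.66, 1e-5),
    ("RS5200", "duplication"): ThresholdPolicy("RS5200", "duplication", 0.74, 1e-15),
    ("RS5200", "deletion"): ThresholdPolicy("RS5200", "deletion", -1.63, 1e-5),
}


def make_windows(assembly: GenomeAssembly, window_size: int,
                 step: int | None = None) -> list[tuple[str, int, int]]:
    """Tile sliding windows per contig; a final partial window is kept if it
    is at least ``step`` long."""
    if window_size <= 0:
        raise ValueError("window_size must be > 0")
    if step is None:
        step = window_size
    if not 0 < step <= window_size:
        raise ValueError("need 0 < step <= window_size")
    windows: list[tuple[str, int, int]] = []
    for contig, length in assembly.contigs:
        if length <= window_size:
            windows.append((contig, 0, length))
            continue
        pos = 0
        while pos < length:
            end = min(pos + window_size, length)
            if end - pos >= step or pos == 0:
                windows.append((contig, pos, end))
            if end == length:
                break
            pos += step
    return windows


def binom_minlike_pvalue(k: np.ndarray, n: np.ndarray, q: float) -> np.ndarray:
    """Vectorized two-sided exact binomial p by the minimum-likelihood rule.

    For each observation, sums P(j) over all j in 0..n with
    P(j) <= P(k) * (1 + rtol).  Entries with n == 0 get p = 1.
    """
    k = np.asarray(k, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    p = np.ones(k.shape, dtype=float)
    for n_val in np.unique(n):
        if n_val == 0:
            continue
        mask = n == n_val
        support = np.arange(n_val + 1)
        pmf = stats.binom.pmf(support, n_val, q)
        obs = pmf[k[mask]]
        # pmf[None,:] rows vs per-observation threshold
        keep = pmf[None, :] <= obs[:, None] * (1.0 + _MINLIKE_RTOL)
        p[mask] = np.minimum(1.0, (pmf[None, :] * keep).sum(axis=1))
    return p


def window_test(count_ref: int, count_test: int, total_ref: int,
                total_test: int) -> tuple[float, float]:
    """Per-window differential coverage test.

    Returns ``(log2_fc, p_value)``.  If both counts are zero the window is
    a no-data case: p = 1, log2_fc = 0.
    """
    if total_ref <= 0 or total_test <= 0:
        raise ValueError("library totals must be > 0")
    if count_ref < 0 or count_test < 0:
        raise ValueError("counts must be >= 0")
    n = count_ref + count_test
    if n == 0:
        return 0.0, 1.0
    log2_fc = math.log2(((count_test + 0.5) / total_test)
                        / ((count_ref + 0.5) / total_ref))
    q = total_test / (total_ref + total_test)
    p = float(binom_minlike_pvalue(np.array([count_test]), np.array([n]), q)[0])
    return log2_fc, p


def compute_window_stats(windows: Sequence[WindowStat],
                         total_ref: int | None = None,
                         total_test: int | None = None) -> list[WindowStat]:
    """Fill log2_fc and p_value for every window (vectorized).

    Totals default to the column sums of the supplied windows.
    """
    if not windows:
        return []
    cr = np.array([w.count_ref for w in windows], dtype=np.int64)
    ct = np.array([w.count_test for w in windows], dtype=np.int64)
    tr = int(cr.sum()) if total_ref is None else total_ref
    tt = int(ct.sum()) if total_test is None else total_test
    if tr <= 0 or tt <= 0:
        raise ValueError("library totals must be > 0")
    fc = np.log2(((ct + 0.5) / tt) / ((cr + 0.5) / tr))
    n = cr + ct
    fc = np.where(n == 0, 0.0, fc)
    q = tt / (tr + tt)
    p = binom_minlike_pvalue(ct, n, q)
    return [
        WindowStat(contig=w.contig, start=w.start, end=w.end,
                   count_ref=w.count_ref, count_test=w.count_test,
                   log2_fc=float(fc[i]), p_value=float(p[i]))
        for i, w in enumerate(windows)
    ]


def apply_thresholds(stats_: Sequence[WindowStat],
                     policy: ThresholdPolicy) -> list[WindowStat]:
    """Keep windows with p < p_cutoff and fold change beyond the cutoff in
    the policy's direction."""
    out = []
    for w in stats_:
        if not w.p_value < policy.p_cutoff:
            continue
        if policy.sv_type == "duplication" and w.log2_fc >= policy.fc_cutoff:
            out.append(w)
        elif policy.sv_type == "deletion" and w.log2_fc <= policy.fc_cutoff:
            out.append(w)
    return out


def merge_calls(significant: Sequence[WindowStat], sv_type: str,
                strain: str = "", min_size: int = 2000) -> list[SVCall]:
    """Merge overlapping or bookended significant windows into calls.

    Windows must all be of one sv_type (callers filter per policy first).
    Calls shorter than ``min_size`` are dropped; min_p is the minimum and
    mean_log2_fc the mean over member windows.
    """
    by_contig: dict[str, list[WindowStat]] = {}
    for w in significant:
        by_contig.setdefault(w.contig, []).append(w)
    calls: list[SVCall] = []
    for contig in sorted(by_contig):
        ws = sorted(by_contig[contig], key=lambda w: (w.start, w.end))
        cluster: list[WindowStat] = []
        cur_end = -1
        for w in ws:
            if cluster and w.start <= cur_end:  # overlapping or bookended
                cluster.append(w)
                cur_end = max(cur_end, w.end)
            else:
                if cluster:
                    calls.extend(_emit(cluster, sv_type, strain, min_size))
                cluster = [w]
                cur_end = w.end
        if cluster:
            calls.extend(_emit(cluster, sv_type, strain, min_size))
    return calls


def _emit(cluster: list[WindowStat], sv_type: str, strain: str,
          min_size: int) -> list[SVCall]:
    start = min(w.start for w in cluster)
    end = max(w.end for w in cluster)
    if end - start < min_size:
        return []
    return [SVCall(contig=cluster[0].contig, start=start, end=end,
                   sv_type=sv_type, strain=strain,
                   min_p=min(w.p_value for w in cluster),
                   mean_log2_fc=float(np.mean([w.log2_fc for w in cluster])))]


def roc_curve(labeled: Sequence[LabeledCall], p_grid: Sequence[float],
              fc_grid: Sequence[float]) -> list[RocPoint]:
    """TPR/FPR over a grid of (p, fold-change) cutoff pairs.

    A call is retained at (p, fc) if its min_p < p and its mean fold change
    is at least as extreme as fc (direction taken from fc's sign; fc = 0
    retains every call regardless of direction).
    """
    tp = [lc.call for lc in labeled if lc.label == "true_positive"]
    fp = [lc.call for lc in labeled if lc.label == "false_positive"]
    if not tp or not fp:
        raise ValueError("roc_curve needs both true and false positives")

    def retained(call: SVCall, p: float, fc: float) -> bool:
        if not call.min_p < p:
            return False
        if fc > 0:
            return call.mean_log2_fc >= fc
        if fc < 0:
            return call.mean_log2_fc <= fc
        return True

    points = []
    for p in p_grid:
        for fc in fc_grid:
            tpr = sum(retained(c, p, fc) for c in tp) / len(tp)
            fpr = sum(retained(c, p, fc) for c in fp) / len(fp)
            points.append(RocPoint(p_cutoff=p, fc_cutoff=fc, tpr=tpr, fpr=fpr))
    return sorted(points, key=lambda pt: (pt.fpr, -pt.tpr, pt.p_cutoff))


def pick_operating_point(roc: Sequence[RocPoint], max_fpr: float,
                         strain: str = "", sv_type: str = "duplication") -> ThresholdPolicy:
    """Maximize TPR subject to FPR <= max_fpr; ties broken by smaller FPR,
    then by more stringent (smaller) p cutoff."""
    if not roc:
        raise ValueError("empty ROC")
    feasible = [pt for pt in roc if pt.fpr <= max_fpr]
    if not feasible:
        raise ValueError(f"no ROC point with FPR <= {max_fpr}; relax max_fpr")
    best = min(feasible, key=lambda pt: (-pt.tpr, pt.fpr, pt.p_cutoff))
    return ThresholdPolicy(strain=strain, sv_type=sv_type,
                           fc_cutoff=best.fc_cutoff, p_cutoff=best.p_cutoff)


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    cur_s = cur_e = None
    for s, e in sorted(intervals):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def genome_fraction(calls: Sequence[SVCall], assembly: GenomeAssembly,
                    window: int = 100_000) -> list[dict]:
    """Per non-overlapping window: fraction deleted (negative, plotting
    convention) and duplicated (positive)."""
    rows = []
    for contig, length in assembly.contigs:
        pos = 0
        while pos < length:
            end = min(pos + window, length)
            fracs = {}
            for sv_type in ("deletion", "duplication"):
                pieces = []
                for c in calls:
                    if c.contig != contig or c.sv_type != sv_type:
                        continue
                    ov = overlap_length(pos, end, c.start, c.end)
                    if ov > 0:
                        pieces.append((max(pos, c.start), min(end, c.end)))
                fracs[sv_type] = _union_length(pieces) / (end - pos)
            rows.append({"contig": contig, "start": pos, "end": end,
                         "frac_deleted": -fracs["deletion"],
                         "frac_duplicated": fracs["duplication"]})
            pos = end
    return rows
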