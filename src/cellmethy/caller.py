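"""Concordantly methylated region (CMR) calling.

The caller scans each chromosome with a sliding window of ``window_w``
consecutive CpGs (step one CpG, adjacent gaps at most ``max_gap`` bp). For a
window, the *common reads* are the reads covering every window CpG; ``f`` is
the fraction of common reads methylated at all of them. Windows with fewer
than ``min_depth`` common reads carry an undefined ``f``.

Local maxima of ``f`` seed *hot spots*, which are extended over adjacent
windows in both directions until ``f`` reaches zero, becomes undefined, or
the anchor-to-anchor distance exceeds ``max_gap``. The extended region is
quantified by the trapezoidal integral ``I`` of ``f`` over the window anchors;
by the mean value theorem ``CM = I / (b - a)`` lies between the smallest and
largest ``f`` of the region and estimates the fraction of the cell population
carrying the fully methylated epiallele.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .epiread import EpiRead, site_levels

__all__ = [
    "CallerConfig",
    "WindowScore",
    "CMRegion",
    "build_windows",
    "find_hot_spots",
    "extend_hot_spot",
    "quantify_region",
    "call_cmrs",
]


@dataclass(frozen=True)
class CallerConfig:
    """Caller parameters; the defaults are the method's published choices."""

    window_w: int = 5        # CpGs per sliding window
    min_depth: int = 10      # minimum common reads for a defined f
    max_gap: int = 100       # bp; max adjacent-CpG / adjacent-window distance
    read_length: int = 100   # bp

    def __post_init__(self) -> None:
        if self.window_w < 2:
            raise ValueError("window_w must be >= 2")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if self.max_gap <= 0 or self.read_length <= 0:
            raise ValueError("max_gap and read_length must be positive")


@dataclass(frozen=True)
class WindowScore:
    """One sliding window: its CpGs, common-read count and CM fraction f.

    ``f`` is None when fewer than ``min_depth`` reads cover every window CpG.
    ``anchor_p`` — the genomic coordinate representing the window on the
    physical axis — is the midpoint of the first and last window CpG.
    """

    chrom: str
    cpg_positions: tuple[int, ...]
    anchor_p: float
    n_common_reads: int
    f: float | None

    @property
    def start(self) -> int:
        return self.cpg_positions[0]

    @property
    def end(self) -> int:
        return self.cpg_positions[-1] + 1


@dataclass(frozen=True)
class CMRegion:
    """An extended hot-spot region [a, b) with its integral quantification."""

    chrom: str
    a: int                 # region start (first CpG), 0-based
    b: int                 # region end, half-open
    integral_I: float      # trapezoidal integral of f over window anchors
    cm_fraction: float     # I / (anchor span); f itself for a single window
    avg_meth: float        # mean per-CpG pileup methylation over [a, b)
    n_cpgs: int
    window_count: int
    hot_f: float           # f of the seeding hot spot


def build_windows(reads: Iterable[EpiRead], cfg: CallerConfig | None = None) -> list[WindowScore]:
    """Score every eligible sliding window on one chromosome.

    A window is eligible when all adjacent CpG gaps within it are at most
    ``max_gap``; windows spanning a larger gap are not emitted at all. Reads
    covering a contiguous run of the chromosome's CpGs are counted with O(1)
    difference-array updates; reads with internal missing calls fall back to
    an explicit per-window check (they are common only for windows whose every
    CpG they cover).
    """
    cfg = cfg or CallerConfig()
    reads = list(reads)
    if not reads:
        return []
    chroms = {r.chrom for r in reads}
    if len(chroms) > 1:
        raise ValueError(f"build_windows expects one chromosome, got {sorted(chroms)}")
    chrom = chroms.pop()

    positions = np.array(sorted({p for r in reads for p in r.positions}), dtype=np.int64)
    w = cfg.window_w
    n = positions.size
    if n < w:
        return []
    nwin = n - w + 1
    index = {int(p): i for i, p in enumerate(positions)}

    common_d = np.zeros(nwin + 1, dtype=np.int64)
    ones_d = np.zeros(nwin + 1, dtype=np.int64)
    gapped: list[EpiRead] = []
    for r in reads:
        lo = index[r.positions[0]]
        hi = index[r.positions[-1]]
        if hi - lo + 1 != len(r.positions):
            gapped.append(r)
            continue
        if hi - lo + 1 >= w:
            common_d[lo] += 1
            common_d[hi - w + 2] -= 1
        # windows fully inside a maximal all-methylated run count toward f's numerator
        run_start = None
        states = r.states
        for k, s in enumerate(states):
            if s == 1 and run_start is None:
                run_start = k
            if run_start is not None and (s == 0 or k == len(states) - 1):
                run_end = k if s == 1 else k - 1
                u, v = lo + run_start, lo + run_end
                if v - u + 1 >= w:
                    ones_d[u] += 1
                    ones_d[v - w + 2] -= 1
                run_start = None
    common = np.cumsum(common_d[:-1])
    ones = np.cumsum(ones_d[:-1])

    for r in gapped:
        covered = dict(zip(r.positions, r.states))
        lo = index[r.positions[0]]
        hi = index[r.positions[-1]]
        for i in range(lo, min(hi - w + 1, nwin - 1) + 1):
            winpos = positions[i : i + w]
            if all(int(p) in covered for p in winpos):
                common[i] += 1
                if all(covered[int(p)] == 1 for p in winpos):
                    ones[i] += 1

    gaps_bad = np.concatenate([[0], np.cumsum(np.diff(positions) > cfg.max_gap)])
    out: list[WindowScore] = []
    for i in range(nwin):
        if gaps_bad[i + w - 1] - gaps_bad[i] != 0:
            continue
        winpos = tuple(int(p) for p in positions[i : i + w])
        nc = int(common[i])
        f = int(ones[i]) / nc if nc >= cfg.min_depth else None
        out.append(WindowScore(chrom, winpos, (winpos[0] + winpos[-1]) / 2.0, nc, f))
    return out


def find_hot_spots(windows: Sequence[WindowScore], cfg: CallerConfig | None = None) -> list[WindowScore]:
    """Windows that are local maxima of f (> 0) within +/- max_gap of their anchor.

    Ties break to the leftmost window; the result is ordered by descending f
    then ascending anchor, the order in which regions are grown.
    """
    cfg = cfg or CallerConfig()
    ws = sorted((x for x in windows if x.f is not None), key=lambda x: x.anchor_p)
    anchors = [x.anchor_p for x in ws]
    hots: list[WindowScore] = []
    for i, x in enumerate(ws):
        if x.f <= 0:
            continue
        lo = bisect.bisect_left(anchors, x.anchor_p - cfg.max_gap)
        hi = bisect.bisect_right(anchors, x.anchor_p + cfg.max_gap)
        if all(
            j == i or ws[j].f < x.f or (ws[j].f == x.f and j > i)
            for j in range(lo, hi)
        ):
            hots.append(x)
    hots.sort(key=lambda x: (-x.f, x.anchor_p))
    return hots


def extend_hot_spot(
    hot: WindowScore,
    windows: Sequence[WindowScore],
    cfg: CallerConfig | None = None,
    claimed: set[WindowScore] | None = None,
) -> tuple[int, int, list[WindowScore]]:
    """Extend a hot spot over adjacent windows in both directions.

    Extension on a side stops when the next window's f is zero or undefined,
    when the anchor-to-anchor step exceeds ``max_gap``, or when the next
    window already belongs to a previously grown (higher-f) region. Returns
    ``(a, b, covered_windows)`` where [a, b) spans from the first CpG of the
    leftmost included window to just past the last CpG of the rightmost.
    """
    cfg = cfg or CallerConfig()
    claimed = claimed or set()
    ws = sorted(windows, key=lambda x: x.anchor_p)
    i = ws.index(hot)
    left = i
    while left - 1 >= 0:
        nxt = ws[left - 1]
        if nxt.f is None or nxt.f == 0 or nxt in claimed:
            break
        if ws[left].anchor_p - nxt.anchor_p > cfg.max_gap:
            break
        left -= 1
    right = i
    while right + 1 < len(ws):
        nxt = ws[right + 1]
        if nxt.f is None or nxt.f == 0 or nxt in claimed:
            break
        if nxt.anchor_p - ws[right].anchor_p > cfg.max_gap:
            break
        right += 1
    covered = ws[left : right + 1]
    a = covered[0].cpg_positions[0]
    b = covered[-1].cpg_positions[-1] + 1
    return a, b, covered


def quantify_region(
    covered_windows: Sequence[WindowScore],
    levels: Mapping[int, float] | None = None,
    hot_f: float | None = None,
) -> CMRegion:
    """Quantify an extended region by the integral mean of f.

    With >= 2 windows, ``I`` is the trapezoidal integral of f over the window
    anchors and ``CM = I / (anchor span)``; a single window degenerates to
    ``CM = f`` (the limit of the mean-value formula). ``levels`` supplies the
    per-CpG pileup methylation used for ``avg_meth``.
    """
    ws = sorted((x for x in covered_windows if x.f is not None), key=lambda x: x.anchor_p)
    if not ws:
        raise ValueError("quantify_region needs at least one window with defined f")
    fs = np.array([x.f for x in ws], dtype=float)
    anchors = np.array([x.anchor_p for x in ws], dtype=float)
    if len(ws) == 1:
        integral, cm = 0.0, float(fs[0])
    else:
        integral = float(np.trapezoid(fs, anchors))
        cm = integral / float(anchors[-1] - anchors[0])
    cpgs = sorted({p for x in ws for p in x.cpg_positions})
    avg = float(np.mean([levels[p] for p in cpgs])) if levels is not None else float("nan")
    return CMRegion(
        chrom=ws[0].chrom,
        a=cpgs[0],
        b=cpgs[-1] + 1,
        integral_I=integral,
        cm_fraction=cm,
        avg_meth=avg,
        n_cpgs=len(cpgs),
        window_count=len(ws),
        hot_f=float(hot_f) if hot_f is not None else float(fs.max()),
    )


def call_cmrs(
    reads: Iterable[EpiRead],
    cfg: CallerConfig | None = None,
    return_windows: bool = False,
):
    """Full pipeline: windows -> hot spots -> greedy extension -> quantification.

    Hot spots are consumed in descending-f order and each window belongs to at
    most one region: extension stops at windows already claimed by a stronger
    region, so regions never double-count. Output is sorted by coordinate and
    deterministic for fixed input. With ``return_windows=True``, returns
    ``(region, covered_windows)`` pairs instead.
    """
    cfg = cfg or CallerConfig()
    by_chrom: dict[str, list[EpiRead]] = {}
    for r in reads:
        by_chrom.setdefault(r.chrom, []).append(r)

    results = []
    for chrom in sorted(by_chrom):
        chrom_reads = sorted(by_chrom[chrom], key=lambda r: r.positions[0])
        windows = build_windows(chrom_reads, cfg)
        if not windows:
            continue
        hots = find_hot_spots(windows, cfg)
        if not hots:
            continue
        levels = site_levels(chrom_reads)[chrom]
        claimed: set[WindowScore] = set()
        chrom_out = []
        for h in hots:
            if h in claimed:
                continue
            _, _, covered = extend_hot_spot(h, windows, cfg, claimed=claimed)
            claimed.update(covered)
            chrom_out.append((quantify_region(covered, levels, hot_f=h.f), covered))
        chrom_out.sort(key=lambda t: t[0].a)
        results.extend(chrom_out)
    if return_windows:
        return results
    return [region for region, _ in results]
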