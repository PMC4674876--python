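"""Two-sample differential calling: DMRs and DCMRs.

Regions called in either sample are merged into a union of fixed intervals,
re-quantified in *both* samples on those coordinates, and classified by an
inclusive +/-0.2 difference: an H-DCMR (L-DCMR) gains (loses) at least 0.2 of
CM fraction in the case sample relative to the control, and hyper-/hypo-DMRs
are the symmetric classes on the average methylation level. The two notions
are deliberately independent — a region can change its read-level concordance
substantially while its average methylation barely moves, and vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .caller import CallerConfig, WindowScore, build_windows, call_cmrs
from .epiread import EpiRead, site_levels

__all__ = [
    "DiffRegion",
    "DIFF_THRESHOLD",
    "classify_deltas",
    "call_differential",
    "crosstab",
    "write_diff_bed",
]

DIFF_THRESHOLD = 0.2


@dataclass(frozen=True)
class DiffRegion:
    chrom: str
    start: int
    end: int
    cm_a: float
    cm_b: float
    meth_a: float
    meth_b: float
    dcmr_class: str   # 'H-DCMR' | 'L-DCMR' | 'none'
    dmr_class: str    # 'hyper-DMR' | 'hypo-DMR' | 'none'
    assessable: bool = True

    @property
    def delta_cm(self) -> float:
        return self.cm_a - self.cm_b

    @property
    def delta_meth(self) -> float:
        return self.meth_a - self.meth_b


def classify_deltas(
    delta_cm: float, delta_meth: float, threshold: float = DIFF_THRESHOLD
) -> tuple[str, str]:
    """Classify a (delta CM, delta methylation) pair; thresholds are inclusive."""
    if delta_cm >= threshold:
        dcmr = "H-DCMR"
    elif delta_cm <= -threshold:
        dcmr = "L-DCMR"
    else:
        dcmr = "none"
    if delta_meth >= threshold:
        dmr = "hyper-DMR"
    elif delta_meth <= -threshold:
        dmr = "hypo-DMR"
    else:
        dmr = "none"
    return dcmr, dmr


def _merge(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _quantify_interval(
    windows: Sequence[WindowScore],
    levels: Mapping[int, float],
    start: int,
    end: int,
) -> tuple[float | None, float | None]:
    """(cm, avg_meth) of one sample on a fixed interval; (None, None) if no coverage.

    cm is the trapezoidal integral mean of f over the defined windows lying
    fully inside the interval (f itself for a single window) and 0.0 when no
    window passes the depth filter — "no detection", not missing data.
    """
    pos = [p for p in levels if start <= p < end]
    if not pos:
        return None, None
    meth = float(np.mean([levels[p] for p in pos]))
    sel = sorted(
        (
            w
            for w in windows
            if w.f is not None and w.cpg_positions[0] >= start and w.cpg_positions[-1] < end
        ),
        key=lambda w: w.anchor_p,
    )
    if not sel:
        return 0.0, meth
    if len(sel) == 1:
        return float(sel[0].f), meth
    fs = np.array([w.f for w in sel], dtype=float)
    anchors = np.array([w.anchor_p for w in sel], dtype=float)
    return float(np.trapezoid(fs, anchors) / (anchors[-1] - anchors[0])), meth


def call_differential(
    reads_a: Iterable[EpiRead],
    reads_b: Iterable[EpiRead],
    cfg: CallerConfig | None = None,
    threshold: float = DIFF_THRESHOLD,
) -> list[DiffRegion]:
    """Call differential regions between case (A) and control (B) samples.

    CMRs are called per sample, overlapping intervals are merged into a union
    coordinate frame, and each union interval is re-quantified in both samples
    (coordinates are not re-optimised per sample). Intervals without coverage
    in one sample are flagged not assessable and excluded from counts.
    """
    cfg = cfg or CallerConfig()
    reads_a = list(reads_a)
    reads_b = list(reads_b)
    cmrs_a = call_cmrs(reads_a, cfg)
    cmrs_b = call_cmrs(reads_b, cfg)

    union: dict[str, list[tuple[int, int]]] = {}
    for r in [*cmrs_a, *cmrs_b]:
        union.setdefault(r.chrom, []).append((r.a, r.b))

    by_chrom_a: dict[str, list[EpiRead]] = {}
    for r in reads_a:
        by_chrom_a.setdefault(r.chrom, []).append(r)
    by_chrom_b: dict[str, list[EpiRead]] = {}
    for r in reads_b:
        by_chrom_b.setdefault(r.chrom, []).append(r)

    out: list[DiffRegion] = []
    for chrom in sorted(union):
        ra = by_chrom_a.get(chrom, [])
        rb = by_chrom_b.get(chrom, [])
        windows_a = build_windows(ra, cfg) if ra else []
        windows_b = build_windows(rb, cfg) if rb else []
        levels_a = site_levels(ra).get(chrom, {}) if ra else {}
        levels_b = site_levels(rb).get(chrom, {}) if rb else {}
        for start, end in _merge(union[chrom]):
            cm_a, meth_a = _quantify_interval(windows_a, levels_a, start, end)
            cm_b, meth_b = _quantify_interval(windows_b, levels_b, start, end)
            if cm_a is None or cm_b is None:
                out.append(
                    DiffRegion(
                        chrom, start, end,
                        float("nan"), float("nan"), float("nan"), float("nan"),
                        "none", "none", assessable=False,
                    )
                )
                continue
            dcmr, dmr = classify_deltas(cm_a - cm_b, meth_a - meth_b, threshold)
            out.append(
                DiffRegion(chrom, start, end, cm_a, cm_b, meth_a, meth_b, dcmr, dmr)
            )
    return out


def crosstab(regions: Sequence[DiffRegion]) -> pd.DataFrame:
    """DCMR-class x DMR-class counts over the assessable union regions."""
    assessable = [r for r in regions if r.assessable]
    dcmr = pd.Categorical(
        [r.dcmr_class for r in assessable], categories=["H-DCMR", "L-DCMR", "none"]
    )
    dmr = pd.Categorical(
        [r.dmr_class for r in assessable], categories=["hyper-DMR", "hypo-DMR", "none"]
    )
    return pd.crosstab(dcmr, dmr, rownames=["dcmr"], colnames=["dmr"], dropna=False)


DIFF_BED_HEADER = (
    "#chrom\tstart\tend\tname\tscore\tstrand\tdelta_cm\tdelta_meth\tdcmr_class\tdmr_class"
)


def write_diff_bed(regions: Sequence[DiffRegion], path) -> None:
    """Write assessable differential regions as BED6+4 (delta columns + classes)."""
    keys = [(r.chrom, r.start) for r in regions]
    if keys != sorted(keys):
        raise ValueError("regions must be sorted by chromosome then start")
    with open(path, "w") as fh:
        fh.write(DIFF_BED_HEADER + "\n")
        for i, r in enumerate(regions, start=1):
            if not r.assessable:
                continue
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\tDIFF_{i}\t"
                f"{round(1000 * abs(r.delta_cm))}\t.\t"
                f"{r.delta_cm:.4f}\t{r.delta_meth:.4f}\t{r.dcmr_class}\t{r.dmr_class}\n"
            )
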