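"""Genomic annotation tracks and CMR occupancy rates.

Promoters are derived as the 2 kb upstream of each transcription start site
(strand-aware) and CpG-island shores (CGS) as the 2 kb flanks of each island
minus the island itself. The occupancy rate of a track is the total CMR
length attributed to it divided by the track's total length; by the default
midpoint convention a CMR contributes its *full* length to the track
containing its midpoint, so rates can exceed 1 when CMRs outgrow small
intervals (CpG islands, typically). A strict-intersection alternative is
available via ``mode="intersection"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Annotation",
    "read_bed",
    "merge_intervals",
    "derive_promoters",
    "derive_shores",
    "occupancy_rates",
]


@dataclass(frozen=True)
class Annotation:
    """A named track of merged, sorted half-open intervals per chromosome."""

    name: str
    intervals: Mapping[str, np.ndarray]  # chrom -> (n, 2) int array

    @property
    def total_length(self) -> int:
        return int(sum((arr[:, 1] - arr[:, 0]).sum() for arr in self.intervals.values()))


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> np.ndarray:
    """Merge overlapping/adjacent-at-a-point half-open intervals."""
    merged: list[list[int]] = []
    for s, e in sorted((int(s), int(e)) for s, e in intervals):
        if e <= s:
            raise ValueError(f"empty interval [{s}, {e})")
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.array(merged, dtype=np.int64).reshape(-1, 2)


def _as_annotation(name: str, per_chrom: Mapping[str, Iterable[tuple[int, int]]]) -> Annotation:
    return Annotation(name, {c: merge_intervals(iv) for c, iv in per_chrom.items() if list(iv)})


def read_bed(path, with_strand: bool = False):
    """Read a BED file into (chrom, start, end[, strand]) tuples."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if with_strand:
                strand = fields[5] if len(fields) >= 6 else None
                rows.append((chrom, start, end, strand))
            else:
                rows.append((chrom, start, end))
    return rows


def derive_promoters(
    tss: Iterable[tuple], upstream: int = 2000, name: str = "promoter"
) -> Annotation:
    """Promoters as the ``upstream`` bp 5' of each TSS (strand-aware).

    ``tss`` rows are (chrom, start, end, strand); the TSS is the interval
    start on '+' and the last base on '-'. Intervals are clipped at 0 and
    merged. A missing strand is an error.
    """
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for row in tss:
        chrom, start, end, strand = row[0], int(row[1]), int(row[2]), row[3]
        if strand == "+":
            site = start
            iv = (max(0, site - upstream), site)
        elif strand == "-":
            site = end - 1
            iv = (site + 1, site + 1 + upstream)
        else:
            raise ValueError(f"TSS record {chrom}:{start}-{end} lacks a strand")
        if iv[1] > iv[0]:
            per_chrom.setdefault(chrom, []).append(iv)
    return _as_annotation(name, per_chrom)


def derive_shores(
    cgi: Iterable[tuple], flank: int = 2000, name: str = "CGS",
    chrom_sizes: Mapping[str, int] | None = None,
) -> Annotation:
    """CpG-island shores: ``flank`` bp on each side of every island, minus islands.

    Flanks are clipped at 0 (and at the chromosome end when sizes are given)
    and merged before the merged islands are subtracted, so nested or
    adjacent islands never leave island bases inside a shore.
    """
    islands: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end, *_ in cgi:
        islands.setdefault(chrom, []).append((int(start), int(end)))

    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivs in islands.items():
        merged_cgi = merge_intervals(ivs)
        limit = None if chrom_sizes is None else chrom_sizes.get(chrom)
        flanks = []
        for s, e in merged_cgi:
            left = (max(0, s - flank), s)
            right = (e, e + flank if limit is None else min(limit, e + flank))
            for iv in (left, right):
                if iv[1] > iv[0]:
                    flanks.append(iv)
        if not flanks:
            continue
        shore = []
        for s, e in merge_intervals(flanks):
            cursor = s
            for cs, ce in merged_cgi:
                if ce <= cursor or cs >= e:
                    continue
                if cs > cursor:
                    shore.append((cursor, cs))
                cursor = max(cursor, ce)
            if cursor < e:
                shore.append((cursor, e))
        per_chrom[chrom] = shore
    return _as_annotation(name, per_chrom)


def _regions_as_tuples(cmrs) -> list[tuple[str, int, int]]:
    out = []
    for r in cmrs:
        if hasattr(r, "chrom") and hasattr(r, "a"):
            out.append((r.chrom, r.a, r.b))
        else:
            chrom, start, end = r[0], int(r[1]), int(r[2])
            out.append((chrom, start, end))
    return out


def occupancy_rates(
    cmrs, annotations: Sequence[Annotation], mode: str = "midpoint"
) -> dict[str, float | None]:
    """Occupancy rate per annotation track.

    ``midpoint`` (default): a CMR contributes its full length to the track
    interval containing its midpoint — rates can exceed 1. ``intersection``:
    only the overlapping bases count. Empty tracks report ``None``.
    """
    if mode not in ("midpoint", "intersection"):
        raise ValueError("mode must be 'midpoint' or 'intersection'")
    regions = _regions_as_tuples(cmrs)
    rates: dict[str, float | None] = {}
    for ann in annotations:
        total = ann.total_length
        if total == 0:
            rates[ann.name] = None
            continue
        covered = 0
        for chrom, start, end in regions:
            arr = ann.intervals.get(chrom)
            if arr is None or arr.size == 0:
                continue
            if mode == "midpoint":
                mid = (start + end) / 2.0
                j = int(np.searchsorted(arr[:, 0], mid, side="right")) - 1
                if j >= 0 and mid < arr[j, 1]:
                    covered += end - start
            else:
                overlap = np.minimum(arr[:, 1], end) - np.maximum(arr[:, 0], start)
                covered += int(overlap[overlap > 0].sum())
        rates[ann.name] = covered / total
    return rates
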