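"""Epiread I/O: per-read CpG methylation calls and related on-disk formats.

The central object is the :class:`EpiRead` — one sequencing read's binary
methylation states at the CpGs it covers, i.e. the read's *epiallele*. All
genomic coordinates are 0-based (the forward-strand C of each CpG) and BED
output is 0-based half-open.

Canonical epiread TSV (one read per line, ``#`` lines are comments)::

    chrom  read_id  positions(comma-separated, 0-based)  states('0'/'1' string)

A CpG with an ambiguous or missing call inside a read's span is simply absent
from that read's position list; such a read never counts as a "common read"
for any window containing that CpG.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence


class EpireadFormatError(ValueError):
    """Raised on malformed epiread / CpG-map input (carries the line number)."""


@dataclass(frozen=True)
class EpiRead:
    """One read's methylation states (1 = methylated) at the CpGs it covers."""

    chrom: str
    read_id: str
    positions: tuple[int, ...]
    states: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", tuple(int(p) for p in self.positions))
        object.__setattr__(self, "states", tuple(int(s) for s in self.states))
        if len(self.positions) != len(self.states) or len(self.positions) < 1:
            raise ValueError(
                f"read {self.read_id}: need equal, nonzero numbers of positions and states"
            )
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError(f"read {self.read_id}: CpG positions must be strictly increasing")
        if any(s not in (0, 1) for s in self.states):
            raise ValueError(f"read {self.read_id}: states must be 0 or 1")

    @property
    def span(self) -> int:
        """Distance from first to last covered CpG (bp)."""
        return self.positions[-1] - self.positions[0]

    def state_at(self, position: int) -> int | None:
        try:
            return self.states[self.positions.index(position)]
        except ValueError:
            return None


@dataclass(frozen=True)
class CpGSite:
    """Per-site summary: pileup depth and methylation level of one CpG."""

    chrom: str
    position: int
    depth: int = 0
    meth_level: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.meth_level <= 1.0:
            raise ValueError(f"meth_level {self.meth_level} outside [0, 1]")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")


def _sort_key(read: EpiRead):
    return (read.chrom, read.positions[0], read.read_id)


def read_epiread_file(path, read_length: int = 100) -> Iterator[EpiRead]:
    """Parse the canonical epiread TSV, yielding reads sorted by (chrom, start).

    Raises :class:`EpireadFormatError` (with the 1-based line number) on
    non-binary state characters, non-monotone positions, column-count
    mismatches, or a span exceeding ``read_length``.
    """
    reads: list[EpiRead] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise EpireadFormatError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            chrom, read_id, pos_s, state_s = fields
            try:
                positions = tuple(int(p) for p in pos_s.split(","))
            except ValueError as exc:
                raise EpireadFormatError(f"{path}:{lineno}: bad position list {pos_s!r}") from exc
            if any(c not in "01" for c in state_s):
                raise EpireadFormatError(f"{path}:{lineno}: states must be '0'/'1' characters")
            states = tuple(int(c) for c in state_s)
            try:
                read = EpiRead(chrom, read_id, positions, states)
            except ValueError as exc:
                raise EpireadFormatError(f"{path}:{lineno}: {exc}") from exc
            if read.span > read_length:
                raise EpireadFormatError(
                    f"{path}:{lineno}: span {read.span} bp exceeds read length {read_length} bp"
                )
            reads.append(read)
    yield from sorted(reads, key=_sort_key)


def write_epiread_file(reads: Iterable[EpiRead], path) -> None:
    """Write the canonical epiread TSV (sorted; round-trips exactly)."""
    with open(path, "w") as fh:
        fh.write("#chrom\tread_id\tpositions\tstates\n")
        for r in sorted(reads, key=_sort_key):
            fh.write(
                f"{r.chrom}\t{r.read_id}\t"
                f"{','.join(str(p) for p in r.positions)}\t"
                f"{''.join(str(s) for s in r.states)}\n"
            )


def read_cpg_map(path) -> list[CpGSite]:
    """Read a CpG-map TSV (chrom, position, meth_level) into sorted sites.

    Levels outside [0, 1] and duplicate positions are errors; out-of-order rows
    are re-sorted with a warning.
    """
    sites: list[CpGSite] = []
    seen: set[tuple[str, int]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise EpireadFormatError(f"{path}:{lineno}: expected 3 columns")
            chrom, pos_s, level_s = fields[0], fields[1], fields[2]
            try:
                position, level = int(pos_s), float(level_s)
            except ValueError as exc:
                raise EpireadFormatError(f"{path}:{lineno}: bad position/level") from exc
            if not 0.0 <= level <= 1.0:
                raise EpireadFormatError(f"{path}:{lineno}: meth_level {level} outside [0, 1]")
            if (chrom, position) in seen:
                raise EpireadFormatError(f"{path}:{lineno}: duplicate position {chrom}:{position}")
            seen.add((chrom, position))
            sites.append(CpGSite(chrom, position, 0, level))
    ordered = sorted(sites, key=lambda s: (s.chrom, s.position))
    if [s.position for s in sites] != [s.position for s in ordered]:
        warnings.warn(f"{path}: CpG map rows were out of order; re-sorted", stacklevel=2)
    return ordered


def write_cpg_map(sites: Iterable[CpGSite], path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tposition\tmeth_level\n")
        for s in sorted(sites, key=lambda s: (s.chrom, s.position)):
            fh.write(f"{s.chrom}\t{s.position}\t{s.meth_level:.6g}\n")


def pileup(reads: Iterable[EpiRead]) -> dict[str, dict[int, tuple[int, int]]]:
    """Per-CpG pileup: ``{chrom: {position: (n_methylated, depth)}}``."""
    out: dict[str, dict[int, tuple[int, int]]] = {}
    for r in reads:
        sites = out.setdefault(r.chrom, {})
        for p, s in zip(r.positions, r.states):
            m, n = sites.get(p, (0, 0))
            sites[p] = (m + s, n + 1)
    return out


def site_levels(reads: Iterable[EpiRead]) -> dict[str, dict[int, float]]:
    """Per-CpG methylation level (methylated / depth) over all covering reads."""
    return {
        chrom: {p: m / n for p, (m, n) in sites.items()}
        for chrom, sites in pileup(reads).items()
    }


BED_HEADER = "#chrom\tstart\tend\tname\tscore\tstrand\tcm_fraction\tavg_meth\tn_cpgs"


def write_cmr_bed(regions: Sequence, path) -> None:
    """Write called regions as BED6+3 (score = round(1000 * CM fraction)).

    ``regions`` must be sorted by (chrom, start); extra columns are the CM
    fraction, the average methylation level, and the CpG count.
    """
    keys = [(r.chrom, r.a) for r in regions]
    if keys != sorted(keys):
        raise ValueError("regions must be sorted by chromosome then start")
    with open(path, "w") as fh:
        fh.write(BED_HEADER + "\n")
        for i, r in enumerate(regions, start=1):
            fh.write(
                f"{r.chrom}\t{r.a}\t{r.b}\tCMR_{i}\t{round(1000 * r.cm_fraction)}\t.\t"
                f"{r.cm_fraction:.4f}\t{r.avg_meth:.4f}\t{r.n_cpgs}\n"
            )


def read_bismark_extractor(path, read_length: int = 100) -> Iterator[EpiRead]:
    """Adapt Bismark methylation-extractor per-read CpG output to EpiReads.

    Expects the tab-separated columns ``read_id, strand(+/-), chrom,
    position(1-based), call`` where the call is ``Z`` (methylated CpG) or
    ``z`` (unmethylated CpG); other context calls are ignored. CpGs reported
    on the reverse strand (the G) are collapsed to the forward-strand C
    coordinate, so both strands describe the same CpG unit.
    """
    grouped: dict[tuple[str, str], dict[int, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "Bismark")):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise EpireadFormatError(f"{path}:{lineno}: expected 5 columns")
            read_id, strand, chrom, pos_s, call = fields
            if call not in ("Z", "z"):
                continue
            try:
                pos1 = int(pos_s)
            except ValueError as exc:
                raise EpireadFormatError(f"{path}:{lineno}: bad position {pos_s!r}") from exc
            # 1-based -> 0-based, and reverse-strand G -> forward-strand C.
            pos0 = pos1 - 1 - (1 if strand == "-" else 0)
            calls = grouped.setdefault((read_id, chrom), {})
            if pos0 in calls and calls[pos0] != (1 if call == "Z" else 0):
                raise EpireadFormatError(
                    f"{path}:{lineno}: conflicting calls for read {read_id} at {chrom}:{pos0}"
                )
            calls[pos0] = 1 if call == "Z" else 0
    reads = []
    for (read_id, chrom), calls in grouped.items():
        positions = tuple(sorted(calls))
        read = EpiRead(chrom, read_id, positions, tuple(calls[p] for p in positions))
        if read.span > read_length:
            raise EpireadFormatError(
                f"{path}: read {read_id} spans {read.span} bp > read length {read_length} bp"
            )
        reads.append(read)
    yield from sorted(reads, key=_sort_key)
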