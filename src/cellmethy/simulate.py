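"""Read-level bisulfite read simulation over a CpG map.

The generator scans a CpG map 5'->3' maintaining a pool of active reads. Each
read covers the current CpG at a uniformly random offset within its span, so
reads split naturally into the set that reaches the next CpG and the set that
does not. At the first CpG a read covers, its state is drawn Bernoulli(site
level); at subsequent CpGs a *random*-pattern read draws an independent
Bernoulli(level of that CpG), while a *concordant*-pattern read copies its own
previous state — the two patterns are indistinguishable site-wise (the
marginal per-CpG level matches the map) and differ only read-wise. Whenever
the pool covering a CpG falls below the configured coverage, new reads are
created and back-filled at every already-passed CpG they cover using the same
per-pattern rule. A CpG more than one read length past its predecessor starts
a fresh segment (no read can bridge the gap).

Sequencing error, bisulfite non-conversion, fragment-end bias and PCR
duplicates are deliberately not modelled.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .epiread import CpGSite, EpiRead

__all__ = [
    "SimConfig",
    "SimRegion",
    "simulate_reads",
    "simulate_eval_region",
    "synthetic_cpg_map",
]

PATTERNS = ("random", "concordant")


@dataclass(frozen=True)
class SimConfig:
    pattern: str = "random"
    coverage: int = 50       # fold depth; every CpG is covered by >= this many reads
    read_length: int = 100   # bp
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"pattern must be one of {PATTERNS}")
        if self.coverage < 1:
            raise ValueError("coverage must be >= 1")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")


@dataclass(frozen=True)
class SimRegion:
    """A simulated evaluation region with its ground truth."""

    chrom: str
    positions: tuple[int, ...]
    theta: float              # theoretical methylation level == true CM fraction (positives)
    label: str                # 'positive' (concordant) or 'negative' (random)

    @property
    def n_cpgs(self) -> int:
        return len(self.positions)

    @property
    def start(self) -> int:
        return self.positions[0]

    @property
    def end(self) -> int:
        return self.positions[-1] + 1


class _Read:
    __slots__ = ("start", "end", "rid", "positions", "states", "last")

    def __init__(self, start: int, end: int, rid: int):
        self.start = start
        self.end = end
        self.rid = rid
        self.positions: list[int] = []
        self.states: list[int] = []
        self.last = -1


def _normalize_map(cpg_map) -> list[tuple[str, int, float]]:
    rows = []
    for site in cpg_map:
        if isinstance(site, CpGSite):
            rows.append((site.chrom, site.position, site.meth_level))
        else:
            chrom, pos, level = site
            rows.append((str(chrom), int(pos), float(level)))
    for _, pos, level in rows:
        if not 0.0 <= level <= 1.0:
            raise ValueError(f"methylation level {level} outside [0, 1]")
    return rows


def simulate_reads(
    cpg_map: Iterable, cfg: SimConfig | None = None, rng: np.random.Generator | None = None
) -> list[EpiRead]:
    """Simulate epireads over a sorted CpG map; see the module docstring.

    Every CpG ends up covered by exactly ``cfg.coverage`` reads. Returns reads
    sorted by (chrom, first position); seeded runs are exactly reproducible.
    """
    cfg = cfg or SimConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    rows = _normalize_map(cpg_map)
    if not rows:
        return []

    by_chrom: dict[str, list[tuple[int, float]]] = {}
    for chrom, pos, level in rows:
        by_chrom.setdefault(chrom, []).append((pos, level))

    length = cfg.read_length
    concordant = cfg.pattern == "concordant"
    out: list[EpiRead] = []
    counter = 0

    for chrom in sorted(by_chrom):
        sites = by_chrom[chrom]
        if any(b <= a for (a, _), (b, _) in zip(sites, sites[1:])):
            raise ValueError(f"CpG map for {chrom} must be sorted with unique positions")
        active: list[_Read] = []
        history: deque[tuple[int, float]] = deque()  # passed CpGs still reachable by a new read

        def emit(read: _Read) -> None:
            nonlocal counter
            out.append(
                EpiRead(chrom, f"r{read.rid:07d}", tuple(read.positions), tuple(read.states))
            )

        for pos, level in sites:
            survivors = []
            for r in active:
                if r.end <= pos:
                    emit(r)
                else:
                    survivors.append(r)
            active = survivors

            if active:
                if concordant:
                    for r in active:
                        r.positions.append(pos)
                        r.states.append(r.last)
                else:
                    draws = rng.random(len(active)) < level
                    for r, s in zip(active, draws):
                        s = int(s)
                        r.positions.append(pos)
                        r.states.append(s)
                        r.last = s

            deficit = cfg.coverage - len(active)
            if deficit > 0:
                offsets = rng.integers(1, length + 1, size=deficit)
                for off in offsets:
                    start = pos - int(off) + 1
                    r = _Read(start, start + length, counter)
                    counter += 1
                    passed = [(p, lv) for p, lv in history if p >= start]
                    if concordant:
                        base = passed[0][1] if passed else level
                        s = int(rng.random() < base)
                        for p, _ in passed:
                            r.positions.append(p)
                            r.states.append(s)
                        r.positions.append(pos)
                        r.states.append(s)
                        r.last = s
                    else:
                        for p, lv in passed:
                            r.positions.append(p)
                            r.states.append(int(rng.random() < lv))
                        s = int(rng.random() < level)
                        r.positions.append(pos)
                        r.states.append(s)
                        r.last = s
                    active.append(r)

            history.append((pos, level))
            while history and history[0][0] <= pos - length:
                history.popleft()

        for r in active:
            emit(r)

    out.sort(key=lambda r: (r.chrom, r.positions[0], r.read_id))
    return out


def simulate_eval_region(
    theta: float,
    label: str,
    cfg: SimConfig | None = None,
    rng: np.random.Generator | None = None,
    n_cpg_range: tuple[int, int] = (6, 20),
    gap_range: tuple[int, int] = (2, 20),
    chrom: str = "sim",
) -> tuple[SimRegion, list[EpiRead]]:
    """Simulate one accuracy-evaluation region at uniform level ``theta``.

    Positives use the concordant pattern, negatives the random pattern. The
    CpG count is drawn uniformly from ``n_cpg_range`` (> 5 by default) and
    inter-CpG gaps uniformly from ``gap_range`` bp, so every region admits
    5-CpG windows with common reads at the default 100 bp read length.
    """
    if not 0.1 <= theta <= 0.9:
        raise ValueError(f"theta {theta} outside [0.1, 0.9]")
    if label not in ("positive", "negative"):
        raise ValueError("label must be 'positive' or 'negative'")
    cfg = cfg or SimConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n = int(rng.integers(n_cpg_range[0], n_cpg_range[1] + 1))
    gaps = rng.integers(gap_range[0], gap_range[1] + 1, size=n - 1)
    positions = 1000 + np.concatenate([[0], np.cumsum(gaps)]).astype(int)
    pattern = "concordant" if label == "positive" else "random"
    reads = simulate_reads(
        [(chrom, int(p), theta) for p in positions], replace(cfg, pattern=pattern), rng
    )
    return SimRegion(chrom, tuple(int(p) for p in positions), float(theta), label), reads


def synthetic_cpg_map(
    n_clusters: int = 40,
    cluster_size: tuple[int, int] = (10, 30),
    gap_range: tuple[int, int] = (2, 20),
    cluster_spacing: tuple[int, int] = (200, 800),
    chrom: str = "simg",
    levels: str | float = "bimodal",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[CpGSite]:
    """A fully synthetic RRBS-like CpG map.

    CpGs come in dense clusters (gaps 2-20 bp, emulating CpG-rich restriction
    fragments) separated by more than one read length, so clusters are
    independent. With ``levels='bimodal'`` each cluster draws a mean level
    from a mixture of a low Beta(1.5, 8), a high Beta(8, 1.5) and a uniform
    intermediate component (0.4/0.4/0.2), matching the strongly bimodal level
    distribution of real methylomes; sites jitter around the cluster mean.
    ``levels='uniform'`` draws cluster means from U(0, 1); a float pins every
    site to that level.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    sites: list[CpGSite] = []
    pos = 1000
    for _ in range(n_clusters):
        size = int(rng.integers(cluster_size[0], cluster_size[1] + 1))
        if levels == "bimodal":
            u = rng.random()
            if u < 0.4:
                mu = rng.beta(1.5, 8.0)
            elif u < 0.8:
                mu = rng.beta(8.0, 1.5)
            else:
                mu = rng.random()
        elif levels == "uniform":
            mu = rng.random()
        else:
            mu = float(levels)
        site_levels = np.clip(mu + rng.normal(0.0, 0.05, size=size), 0.0, 1.0)
        for lv in site_levels:
            sites.append(CpGSite(chrom, pos, 0, float(lv)))
            pos += int(rng.integers(gap_range[0], gap_range[1] + 1))
        pos += int(rng.integers(cluster_spacing[0], cluster_spacing[1] + 1))
    return sites
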