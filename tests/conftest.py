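"""Shared fixtures: hand-built epiread sets and a brute-force window oracle."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cellmethy import CallerConfig, EpiRead

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

FIVE_CPGS = (100, 110, 120, 130, 140)


def reads_from_matrix(matrix, positions=FIVE_CPGS, chrom="chr1", prefix="r") -> list[EpiRead]:
    """Rows of 0/1/None -> EpiReads (None = missing call at that CpG)."""
    reads = []
    for i, row in enumerate(matrix):
        pos = tuple(p for p, s in zip(positions, row) if s is not None)
        states = tuple(s for s in row if s is not None)
        reads.append(EpiRead(chrom, f"{prefix}{i:04d}", pos, states))
    return reads


@pytest.fixture
def concordant_mixture_reads() -> list[EpiRead]:
    """100 reads over 5 CpGs: 49 fully methylated epialleles + 51 discordant
    reads carrying 30 scattered methylated calls, so the per-CpG pileup level
    is exactly 0.55 at every site while the all-methylated read fraction is 0.49."""
    matrix = [[1] * 5 for _ in range(49)]
    for k in range(30):  # one methylated CpG each, cycled across columns
        row = [0] * 5
        row[k % 5] = 1
        matrix.append(row)
    matrix.extend([[0] * 5 for _ in range(21)])
    return reads_from_matrix(matrix)


@pytest.fixture
def discordant_mixture_reads() -> list[EpiRead]:
    """100 reads, same per-CpG pileup level 0.55, but no read fully methylated:
    68 reads with four methylated CpGs, one with three, 31 unmethylated."""
    matrix = []
    for k in range(68):
        row = [1] * 5
        row[k % 5] = 0
        matrix.append(row)
    row = [1, 1, 1, 0, 0]
    matrix.append(row)
    matrix.extend([[0] * 5 for _ in range(31)])
    total = sum(sum(r) for r in matrix)
    assert total == 275 and all(sum(r) < 5 for r in matrix)
    return reads_from_matrix(matrix)


def brute_force_windows(reads, cfg: CallerConfig):
    """Enumerate every read per window: the independent f oracle."""
    positions = sorted({p for r in reads for p in r.positions})
    out = []
    for i in range(len(positions) - cfg.window_w + 1):
        winpos = tuple(positions[i : i + cfg.window_w])
        if any(b - a > cfg.max_gap for a, b in zip(winpos, winpos[1:])):
            continue
        common = [r for r in reads if all(p in r.positions for p in winpos)]
        ones = [
            r for r in common if all(r.states[r.positions.index(p)] == 1 for p in winpos)
        ]
        n = len(common)
        f = len(ones) / n if n >= cfg.min_depth else None
        out.append((winpos, n, f))
    return out


def random_epiread_matrix(rng: np.random.Generator, chrom="chrR"):
    """A random small epiread set plus a compatible caller config.

    Positions may exceed the 100 bp gap rule; reads may skip CpGs inside
    their span (exercising the non-contiguous fallback path).
    """
    n_pos = int(rng.integers(2, 9))
    gaps = rng.integers(1, 151, size=n_pos - 1)
    positions = tuple(int(p) for p in 100 + np.concatenate([[0], np.cumsum(gaps)]))
    n_reads = int(rng.integers(1, 16))
    reads = []
    for i in range(n_reads):
        k = int(rng.integers(1, n_pos + 1))
        idx = sorted(rng.choice(n_pos, size=k, replace=False))
        pos = tuple(positions[j] for j in idx)
        states = tuple(int(s) for s in rng.integers(0, 2, size=k))
        reads.append(EpiRead(chrom, f"m{i:03d}", pos, states))
    cfg = CallerConfig(
        window_w=int(rng.integers(2, min(4, n_pos) + 1)),
        min_depth=int(rng.integers(1, 4)),
        max_gap=100,
    )
    return reads, cfg
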