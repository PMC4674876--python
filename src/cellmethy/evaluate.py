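"""Accuracy evaluation and parameter sweeps on simulated data.

``run_accuracy_experiment`` reproduces the benchmark design: paired positive
(concordant-pattern) and negative (random-pattern) regions share a theoretical
methylation level theta ~ U(0.1, 0.9), are sequenced at the configured depth,
and are scored by the called CM fraction and, as a null comparator, by the
average methylation level. Because both labels share theta, average
methylation carries no class signal (AUC ~ 0.5) while the CM fraction
separates the patterns.

``sweep_parameters`` characterises the caller across window sizes and
coverages on a synthetic genome map, including distribution-shape diagnostics
of f: a Kolmogorov-Smirnov distance to U(0, 1) and Sarle's bimodality
coefficient, both computed over windows with defined f > 0 (zero-f windows
are the non-signal background the caller never integrates).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .caller import CallerConfig, build_windows, call_cmrs
from .epiread import site_levels
from .simulate import SimConfig, simulate_eval_region, simulate_reads, synthetic_cpg_map

__all__ = [
    "EvalResult",
    "run_accuracy_experiment",
    "geometry_sensitivity",
    "sweep_parameters",
    "bimodality_coefficient",
    "ks_uniform_statistic",
    "is_near_uniform",
    "is_bimodal",
]

# a priori shape-diagnostic thresholds: uniform samples give KS distances well
# below 0.1, and the uniform distribution's bimodality coefficient is 5/9.
KS_UNIFORM_THRESHOLD = 0.2
BIMODALITY_THRESHOLD = 0.65


@dataclass(frozen=True)
class EvalResult:
    auc_cm: float        # AUC of the called CM fraction score
    auc_meth: float      # AUC of the average-methylation score (null comparator)
    r_squared: float     # OLS R^2 of predicted CM on theta, positives only
    n_pos: int
    n_neg: int
    seed: int | None

    def to_dict(self) -> dict:
        return asdict(self)


def _region_scores(region, reads, caller_cfg: CallerConfig) -> tuple[float, float]:
    """(CM score, average-methylation score) for one simulated region.

    The CM score is the largest cm_fraction among called CMRs overlapping the
    region, 0.0 when none is called; the methylation score is the mean
    per-CpG pileup level over the region's CpGs.
    """
    cmrs = call_cmrs(reads, caller_cfg)
    overlapping = [c.cm_fraction for c in cmrs if c.b > region.start and c.a < region.end]
    cm_score = max(overlapping, default=0.0)
    levels = site_levels(reads)[region.chrom]
    meth_score = float(np.mean([levels[p] for p in region.positions if p in levels]))
    return cm_score, meth_score


def run_accuracy_experiment(
    n_regions: int = 1000,
    coverage: int = 50,
    seed: int | None = None,
    caller_cfg: CallerConfig | None = None,
    n_cpg_range: tuple[int, int] = (6, 20),
    gap_range: tuple[int, int] = (2, 20),
) -> EvalResult:
    """Simulate ``n_regions`` positive/negative pairs and measure AUC and R^2."""
    if n_regions < 10:
        raise ValueError("n_regions < 10: AUC would be meaningless")
    caller_cfg = caller_cfg or CallerConfig()
    rng = np.random.default_rng(seed)
    sim_cfg = SimConfig(coverage=coverage)

    labels: list[int] = []
    cm_scores: list[float] = []
    meth_scores: list[float] = []
    pos_theta: list[float] = []
    pos_pred: list[float] = []
    for _ in range(n_regions):
        theta = float(rng.uniform(0.1, 0.9))
        for label in ("positive", "negative"):
            region, reads = simulate_eval_region(
                theta, label, sim_cfg, rng, n_cpg_range=n_cpg_range, gap_range=gap_range
            )
            cm, meth = _region_scores(region, reads, caller_cfg)
            labels.append(1 if label == "positive" else 0)
            cm_scores.append(cm)
            meth_scores.append(meth)
            if label == "positive":
                pos_theta.append(theta)
                pos_pred.append(cm)

    fit = stats.linregress(pos_theta, pos_pred)
    return EvalResult(
        auc_cm=float(roc_auc_score(labels, cm_scores)),
        auc_meth=float(roc_auc_score(labels, meth_scores)),
        r_squared=float(fit.rvalue**2),
        n_pos=n_regions,
        n_neg=n_regions,
        seed=seed,
    )


def geometry_sensitivity(
    n_regions: int = 200,
    coverage: int = 50,
    seed: int | None = None,
    geometries: Sequence[tuple[tuple[int, int], tuple[int, int]]] = (
        ((6, 20), (2, 20)),
        ((6, 12), (2, 10)),
        ((12, 20), (10, 20)),
    ),
) -> pd.DataFrame:
    """Report AUC/R^2 across region-geometry choices (CpG-count and gap ranges).

    The evaluation-region geometry is not pinned down beyond "> 5 CpGs"; this
    sweep quantifies how sensitive the headline numbers are to it.
    """
    rows = []
    for k, (n_cpg_range, gap_range) in enumerate(geometries):
        res = run_accuracy_experiment(
            n_regions=n_regions,
            coverage=coverage,
            seed=None if seed is None else seed + k,
            n_cpg_range=n_cpg_range,
            gap_range=gap_range,
        )
        rows.append(
            {
                "n_cpg_min": n_cpg_range[0],
                "n_cpg_max": n_cpg_range[1],
                "gap_min": gap_range[0],
                "gap_max": gap_range[1],
                "auc_cm": res.auc_cm,
                "auc_meth": res.auc_meth,
                "r_squared": res.r_squared,
            }
        )
    return pd.DataFrame(rows)


def ks_uniform_statistic(values: Iterable[float]) -> float:
    """Kolmogorov-Smirnov distance of the sample to U(0, 1)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        return float("nan")
    return float(stats.kstest(arr, "uniform").statistic)


def bimodality_coefficient(values: Iterable[float]) -> float:
    """Sarle's bimodality coefficient (skewness^2 + 1) / adjusted kurtosis.

    5/9 for the uniform distribution; clearly two-moded samples exceed ~0.65.
    """
    arr = np.asarray(list(values), dtype=float)
    n = arr.size
    if n < 4 or np.ptp(arr) == 0:
        return float("nan")
    g1 = stats.skew(arr, bias=False)
    g2 = stats.kurtosis(arr, bias=False)  # excess kurtosis
    return float((g1**2 + 1.0) / (g2 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))))


def is_near_uniform(values: Iterable[float], threshold: float = KS_UNIFORM_THRESHOLD) -> bool:
    return ks_uniform_statistic(values) < threshold


def is_bimodal(values: Iterable[float], threshold: float = BIMODALITY_THRESHOLD) -> bool:
    return bimodality_coefficient(values) > threshold


def sweep_parameters(
    window_sizes: Iterable[int] = range(2, 11),
    coverages: Iterable[int] = (10, 20, 50, 100),
    seed: int | None = None,
    map_kwargs: dict | None = None,
    caller_cfg: CallerConfig | None = None,
) -> pd.DataFrame:
    """Characterise called regions per (window size, coverage, pattern).

    One synthetic genome map is shared by all conditions (only the reads are
    re-simulated), so rows are comparable. Columns report the number of
    regions, CpGs per region, mean CM fraction, the mean of defined f, and
    the f-distribution shape diagnostics.
    """
    base_cfg = caller_cfg or CallerConfig()
    window_sizes = list(window_sizes)
    coverages = list(coverages)
    seeds = np.random.SeedSequence(seed).spawn(1 + len(coverages) * 2)
    cmap = synthetic_cpg_map(rng=np.random.default_rng(seeds[0]), **(map_kwargs or {}))
    chrom = cmap[0].chrom

    rows = []
    child = 1
    for coverage in coverages:
        for pattern in ("random", "concordant"):
            reads = simulate_reads(
                cmap,
                SimConfig(pattern=pattern, coverage=coverage),
                np.random.default_rng(seeds[child]),
            )
            child += 1
            chrom_reads = [r for r in reads if r.chrom == chrom]
            for w in window_sizes:
                cfg = replace(base_cfg, window_w=w)
                windows = build_windows(chrom_reads, cfg)
                fs = np.array([x.f for x in windows if x.f is not None], dtype=float)
                pos_fs = fs[fs > 0]
                regions = call_cmrs(reads, cfg)
                rows.append(
                    {
                        "window_w": w,
                        "coverage": coverage,
                        "pattern": pattern,
                        "n_windows": len(windows),
                        "n_defined": int(fs.size),
                        "n_regions": len(regions),
                        "mean_cpgs_per_region": float(
                            np.mean([r.n_cpgs for r in regions]) if regions else np.nan
                        ),
                        "mean_cm": float(
                            np.mean([r.cm_fraction for r in regions]) if regions else np.nan
                        ),
                        "mean_f": float(fs.mean()) if fs.size else np.nan,
                        "ks_uniform": ks_uniform_statistic(pos_fs),
                        "bimodality": bimodality_coefficient(pos_fs),
                    }
                )
    return pd.DataFrame(rows)
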