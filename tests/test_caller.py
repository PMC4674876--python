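"""Sliding windows, hot spots, extension and integral quantification."""

import math

import numpy as np
import pytest

from cellmethy import (
    CallerConfig,
    EpiRead,
    WindowScore,
    build_windows,
    call_cmrs,
    extend_hot_spot,
    find_hot_spots,
    quantify_region,
    write_cmr_bed,
)
from cellmethy.simulate import SimConfig, simulate_eval_region

from conftest import FIVE_CPGS, brute_force_windows, random_epiread_matrix, reads_from_matrix


def _window(anchor, f, chrom="chr1", n=20, positions=None):
    positions = positions or (int(anchor) - 2, int(anchor) + 2)
    return WindowScore(chrom, tuple(positions), float(anchor), n, f)


class TestBuildWindows:
    def test_all_methylated_single_window(self):
        reads = reads_from_matrix([[1] * 5 for _ in range(10)])
        (w,) = build_windows(reads, CallerConfig())
        assert (w.n_common_reads, w.f) == (10, 1.0)
        assert w.cpg_positions == FIVE_CPGS
        assert w.anchor_p == 120.0

    def test_f_counts_fully_methylated_common_reads(self):
        # 4 fully methylated reads, 6 with at least one unmethylated CpG
        matrix = [[1] * 5 for _ in range(4)] + [
            [1, 1, 0, 1, 1],
            [0, 1, 1, 1, 1],
            [1, 0, 1, 1, 0],
            [1, 1, 1, 1, 0],
            [0, 0, 0, 0, 0],
            [1, 0, 0, 1, 1],
        ]
        (w,) = build_windows(reads_from_matrix(matrix), CallerConfig())
        assert w.f == pytest.approx(0.4)

    def test_large_gap_excludes_window(self):
        positions = (100, 120, 140, 290, 310)  # 150 bp gap between CpG 3 and 4
        reads = reads_from_matrix([[1] * 5 for _ in range(10)], positions=positions)
        assert build_windows(reads, CallerConfig()) == []

    def test_fewer_cpgs_than_window_is_empty(self):
        reads = reads_from_matrix([[1, 1]], positions=(100, 110))
        assert build_windows(reads, CallerConfig(window_w=5)) == []

    def test_underdepth_window_has_undefined_f(self):
        reads = reads_from_matrix([[1] * 5 for _ in range(9)])
        (w,) = build_windows(reads, CallerConfig(min_depth=10))
        assert w.f is None and w.n_common_reads == 9

    def test_read_missing_internal_cpg_is_not_common(self):
        matrix = [[1] * 5 for _ in range(3)] + [[1, 1, None, 1, 1]]
        (w,) = build_windows(reads_from_matrix(matrix), CallerConfig(min_depth=1))
        assert w.n_common_reads == 3

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        reads, cfg = random_epiread_matrix(rng)
        got = [(w.cpg_positions, w.n_common_reads, w.f) for w in build_windows(reads, cfg)]
        assert got == brute_force_windows(reads, cfg)

    def test_f_dominated_by_per_cpg_common_levels(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            reads, cfg = random_epiread_matrix(rng)
            for w in build_windows(reads, cfg):
                if w.f is None:
                    continue
                common = [r for r in reads if all(p in r.positions for p in w.cpg_positions)]
                for p in w.cpg_positions:
                    level = sum(r.states[r.positions.index(p)] for r in common) / len(common)
                    assert w.f <= level + 1e-12


class TestHotSpots:
    def test_unique_maximum(self):
        ws = [_window(100, 0.1), _window(110, 0.5), _window(120, 0.2)]
        assert find_hot_spots(ws, CallerConfig()) == [ws[1]]

    def test_all_zero_f_gives_no_hot_spot(self):
        ws = [_window(100, 0.0), _window(110, 0.0)]
        assert find_hot_spots(ws, CallerConfig()) == []

    def test_plateau_selects_leftmost(self):
        ws = [_window(100, 0.5), _window(110, 0.5)]
        assert find_hot_spots(ws, CallerConfig()) == [ws[0]]

    def test_distant_equal_maxima_both_kept_ordered(self):
        ws = [_window(100, 0.5), _window(400, 0.5), _window(420, 0.9)]
        hots = find_hot_spots(ws, CallerConfig())
        assert hots == [ws[2], ws[0]]  # descending f, then ascending anchor


class TestExtension:
    def test_isolated_hot_spot_spans_its_own_cpgs(self):
        ws = [_window(100, None), _window(110, 0.8, positions=(105, 115)), _window(120, None)]
        a, b, covered = extend_hot_spot(ws[1], ws, CallerConfig())
        assert (a, b) == (105, 116)
        assert covered == [ws[1]]

    def test_extension_stops_at_zero_f(self):
        ws = [
            _window(100, 0.0),
            _window(110, 0.3, positions=(105, 115)),
            _window(120, 0.8),
            _window(130, 0.4, positions=(125, 135)),
            _window(140, 0.0),
        ]
        a, b, covered = extend_hot_spot(ws[2], ws, CallerConfig())
        assert covered == ws[1:4]
        assert (a, b) == (105, 136)

    def test_extension_respects_distance_rule(self):
        ws = [_window(100, 0.3), _window(260, 0.8)]  # 160 bp apart
        _, _, covered = extend_hot_spot(ws[1], ws, CallerConfig())
        assert covered == [ws[1]]

    def test_extension_stops_at_claimed_windows(self):
        ws = [_window(100, 0.9), _window(110, 0.4), _window(120, 0.6)]
        _, _, covered = extend_hot_spot(ws[2], ws, CallerConfig(), claimed={ws[0], ws[1]})
        assert covered == [ws[2]]


class TestQuantify:
    def test_constant_f_gives_cm_equal_to_constant(self):
        ws = [_window(100 + 10 * k, 0.37) for k in range(5)]
        region = quantify_region(ws)
        assert region.cm_fraction == pytest.approx(0.37)

    def test_linear_ramp_gives_half(self):
        n = 101
        ws = [_window(1000 + 2 * k, k / (n - 1)) for k in range(n)]
        assert quantify_region(ws).cm_fraction == pytest.approx(0.5)

    def test_hand_trapezoid(self):
        ws = [_window(0, 0.3, positions=(0, 1)), _window(10, 0.8), _window(20, 0.4)]
        region = quantify_region(ws)
        assert region.integral_I == pytest.approx(11.5)
        assert region.cm_fraction == pytest.approx(0.575)

    def test_single_window_degenerates_to_f(self):
        region = quantify_region([_window(100, 0.42)])
        assert region.cm_fraction == pytest.approx(0.42)
        assert math.isnan(region.avg_meth)  # no pileup supplied

    def test_requires_a_defined_window(self):
        with pytest.raises(ValueError):
            quantify_region([_window(100, None)])


class TestCallCmrs:
    def test_fully_methylated_reads_tile_with_cm_one(self):
        matrix = [[1] * 12 for _ in range(10)]
        positions = tuple(100 + 10 * k for k in range(12))
        regions = call_cmrs(reads_from_matrix(matrix, positions=positions))
        assert regions and all(r.cm_fraction == pytest.approx(1.0) for r in regions)
        covered = {p for r in regions for p in range(r.a, r.b)}
        assert positions[0] in covered and positions[-1] in covered

    def test_fully_unmethylated_reads_give_no_region(self):
        matrix = [[0] * 8 for _ in range(10)]
        positions = tuple(100 + 10 * k for k in range(8))
        assert call_cmrs(reads_from_matrix(matrix, positions=positions)) == []

    def test_concordant_mixture_recovers_cm_and_meth(self, concordant_mixture_reads):
        (region,) = call_cmrs(concordant_mixture_reads)
        assert region.cm_fraction == pytest.approx(0.49)
        assert region.avg_meth == pytest.approx(0.55)

    def test_mean_value_bound_on_simulated_regions(self):
        rng = np.random.default_rng(21)
        for theta, label in [(0.3, "positive"), (0.8, "positive"), (0.5, "negative")]:
            _, reads = simulate_eval_region(theta, label, SimConfig(coverage=50), rng)
            for region, covered in call_cmrs(reads, return_windows=True):
                fs = [w.f for w in covered if w.f is not None]
                assert min(fs) - 1e-12 <= region.cm_fraction <= max(fs) + 1e-12

    def test_deterministic_bed_output(self, tmp_path, concordant_mixture_reads):
        paths = []
        for name in ("a.bed", "b.bed"):
            p = tmp_path / name
            write_cmr_bed(call_cmrs(list(concordant_mixture_reads)), p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_windows_claimed_once_across_regions(self):
        rng = np.random.default_rng(3)
        _, reads = simulate_eval_region(0.6, "negative", SimConfig(coverage=50), rng)
        pairs = call_cmrs(reads, return_windows=True)
        seen = set()
        for _, covered in pairs:
            for w in covered:
                assert w not in seen
                seen.add(w)
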