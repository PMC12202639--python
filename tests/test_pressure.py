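"""Pressure-map metrics: worked examples, brute-force oracle equivalence,
and the SPD algebraic properties."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ergoseat.pressure import (
    bin_histogram,
    classify_comfort,
    compute_metrics,
    compute_spd,
    contact_cells,
    partition_backrest,
    partition_cushion,
)
from ergoseat.types import (
    ComfortClass,
    InvariantError,
    NoContactError,
    PressureMap,
    PressureMetrics,
    RegionName,
)
from .conftest import random_pressure_grid


def brute_force_metrics(grid, cell_pitch, threshold=0.0):
    """Independent single-pass loop oracle over all cells."""
    vals = []
    for r in range(grid.shape[0]):
        for c in range(grid.shape[1]):
            if grid[r, c] > threshold:
                vals.append(grid[r, c])
    n = len(vals)
    if n == 0:
        return None
    p_ave = sum(vals) / n
    spd = sum((v - p_ave) ** 2 for v in vals) / (4 * n * p_ave**2)
    return {
        "p_max": max(vals), "p_ave": p_ave, "n": n,
        "area": n * cell_pitch[0] * cell_pitch[1] / 100.0, "spd": spd,
    }


def cushion(grid, pitch=(10.0, 10.0)):
    return PressureMap(grid, pitch, "cushion")


class TestContactCells:
    def test_strict_threshold(self):
        pm = cushion([[0, 1], [2, 3]])
        assert len(contact_cells(pm)) == 3
        assert contact_cells(pm, threshold=2.0) == {(1, 1)}
        assert contact_cells(cushion([[0.0, 0.0]])) == set()


class TestSPD:
    def test_uniform_pressure_gives_zero(self):
        assert compute_spd(cushion(np.full((4, 5), 5.0))) == 0.0

    def test_two_cell_hand_example(self):
        # pressures {1, 3}: p_ave=2, sum of squares 2, denominator 4*2*4=32
        assert compute_spd(cushion([[1.0, 3.0]])) == pytest.approx(0.0625, abs=1e-15)
        # scale invariance: {2, 6} is {1, 3} doubled
        assert compute_spd(cushion([[2.0, 6.0]])) == pytest.approx(0.0625, abs=1e-15)

    def test_no_contact_raises(self):
        with pytest.raises(NoContactError):
            compute_spd(cushion([[0.0]]))

    def test_scale_invariance_on_random_maps(self, rng):
        for _ in range(100):
            grid = random_pressure_grid(rng)
            if not (grid > 0).any():
                continue
            pm = cushion(grid)
            c = rng.uniform(0.1, 10.0)
            assert compute_spd(cushion(c * grid)) == pytest.approx(
                compute_spd(pm), abs=1e-12)

    def test_zero_iff_uniform(self, rng):
        for _ in range(100):
            grid = random_pressure_grid(rng)
            if not (grid > 0).any():
                continue
            vals = grid[grid > 0]
            spd = compute_spd(cushion(grid))
            if np.ptp(vals) < 1e-12:
                assert spd <= 1e-12
            else:
                assert spd > 1e-12

    def test_adding_average_cell_decreases_spd(self, rng):
        for _ in range(50):
            grid = random_pressure_grid(rng)
            vals = grid[grid > 0]
            if len(vals) < 2 or np.ptp(vals) < 1e-9:
                continue
            spd = compute_spd(cushion(grid))
            bigger = np.concatenate([vals, [vals.mean()]])[None, :]
            assert compute_spd(cushion(bigger)) < spd


class TestMetrics:
    def test_single_cell(self):
        m = compute_metrics(cushion([[10.0]]))
        assert (m.p_max, m.p_ave, m.contact_area, m.n_contact, m.spd) == \
            (10.0, 10.0, 1.0, 1, 0.0)

    def test_small_grid_arithmetic(self):
        m = compute_metrics(cushion([[0, 1], [2, 3]]))
        assert m.p_max == 3.0 and m.p_ave == 2.0 and m.n_contact == 3

    def test_oracle_equivalence_on_random_maps(self, rng):
        checked = 0
        for _ in range(100):
            grid = random_pressure_grid(rng)
            pitch = (float(rng.uniform(5, 15)), float(rng.uniform(5, 15)))
            threshold = float(rng.choice([0.0, 1.0]))
            expected = brute_force_metrics(grid, pitch, threshold)
            pm = PressureMap(grid, pitch, "cushion")
            if expected is None:
                with pytest.raises(NoContactError):
                    compute_metrics(pm, threshold=threshold)
                continue
            m = compute_metrics(pm, threshold=threshold)
            assert m.p_max == pytest.approx(expected["p_max"], abs=1e-12)
            assert m.p_ave == pytest.approx(expected["p_ave"], abs=1e-12)
            assert m.n_contact == expected["n"]
            assert m.contact_area == pytest.approx(expected["area"], rel=1e-12)
            assert m.spd == pytest.approx(expected["spd"], abs=1e-12)
            assert m.one_minus_spd == pytest.approx(1 - expected["spd"], abs=1e-12)
            checked += 1
        assert checked > 50


class TestHistogram:
    def test_hand_example_and_half_open_bins(self):
        counts = bin_histogram(cushion([[1.0, 5.0, 9.0]]), bin_width=4.0)
        assert counts.tolist() == [1, 1, 1]
        counts = bin_histogram(cushion([[4.0]]), bin_width=4.0)
        assert counts.tolist() == [0, 1]  # 4.0 falls in [4, 8)

    def test_empty_region_all_zero(self):
        assert bin_histogram(cushion([[0.0, 0.0]])).sum() == 0

    def test_counts_sum_to_n_contact(self, rng):
        for _ in range(100):
            grid = random_pressure_grid(rng)
            pm = cushion(grid)
            w = float(rng.uniform(0.5, 6.0))
            thr = float(rng.choice([0.0, 2.0]))
            counts = bin_histogram(pm, bin_width=w, threshold=thr)
            assert counts.sum() == len(contact_cells(pm, threshold=thr))


class TestPartitions:
    def test_backrest_rows_below_line_are_waist(self):
        pm = PressureMap(np.ones((10, 4)), (10, 10), "backrest")
        parts = partition_backrest(pm, l1_row=4)
        back_rows = {r for r, _ in parts[RegionName.BACK].member_cells}
        waist_rows = {r for r, _ in parts[RegionName.WAIST].member_cells}
        assert back_rows == set(range(5)) and waist_rows == set(range(5, 10))

    def test_backrest_boundary_row_warns(self):
        pm = PressureMap(np.ones((10, 4)), (10, 10), "backrest")
        with pytest.warns(UserWarning, match="empty"):
            parts = partition_backrest(pm, l1_row=9)
        assert not parts[RegionName.WAIST].member_cells

    def test_cushion_even_split(self):
        pm = PressureMap(np.ones((10, 4)), (10, 10), "cushion")
        parts = partition_cushion(pm, split_row=5)
        assert len({r for r, _ in parts[RegionName.HIP].member_cells}) == 5
        assert len({r for r, _ in parts[RegionName.LEGS].member_cells}) == 5

    def test_cushion_split_zero_warns_hip_empty(self):
        pm = PressureMap(np.ones((10, 4)), (10, 10), "cushion")
        with pytest.warns(UserWarning, match="hip"):
            parts = partition_cushion(pm, split_row=0)
        assert not parts[RegionName.HIP].member_cells

    @pytest.mark.parametrize("which", ["cushion", "backrest"])
    def test_disjoint_and_exhaustive_for_every_row(self, which):
        pm = PressureMap(np.ones((20, 3)), (10, 10), which)
        whole = {(r, c) for r in range(20) for c in range(3)}
        split = partition_cushion if which == "cushion" else partition_backrest
        for row in range(20):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                parts = split(pm, row)
            a, b = [set(m.member_cells) for m in parts.values()]
            assert a | b == whole and not (a & b)

    def test_out_of_range_row_rejected(self):
        pm = PressureMap(np.ones((5, 3)), (10, 10), "backrest")
        with pytest.raises(InvariantError):
            partition_backrest(pm, 5)
        with pytest.raises(InvariantError):
            partition_backrest(PressureMap(np.ones((5, 3)), (10, 10), "cushion"), 2)


def _metrics(p_max):
    return PressureMetrics(p_max=p_max, p_ave=min(p_max, 1.0), contact_area=1.0,
                           n_contact=1, spd=0.0, one_minus_spd=1.0)


class TestComfortClassification:
    @pytest.mark.parametrize("region,p_max,expected", [
        ("hip", 9.0, ComfortClass.WITHIN_IDEAL),      # buttocks ideal 7-11 kPa
        ("waist", 8.55, ComfortClass.ABOVE_IDEAL),    # beyond the 4-8 kPa window
        ("waist", 4.0, ComfortClass.WITHIN_IDEAL),    # closed lower bound
        ("waist", 8.0, ComfortClass.WITHIN_IDEAL),    # closed upper bound
        ("hip", 6.9, ComfortClass.BELOW_IDEAL),
    ])
    def test_default_windows(self, region, p_max, expected):
        assert classify_comfort(_metrics(p_max), region) == expected

    def test_unconfigured_region_rejected(self):
        with pytest.raises(InvariantError, match="legs"):
            classify_comfort(_metrics(5.0), "legs")

    def test_custom_ranges(self):
        got = classify_comfort(_metrics(5.0), "legs", {"legs": (1.0, 4.0)})
        assert got == ComfortClass.ABOVE_IDEAL


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(0.1, 50.0), min_size=1, max_size=30),
       st.floats(0.1, 10.0))
def test_spd_scale_invariance_property(pressures, scale):
    """SPD(c·p) == SPD(p): pure algebraic identity of the uniformity index."""
    grid = np.array(pressures)[None, :]
    a = compute_spd(cushion(grid))
    b = compute_spd(cushion(scale * grid))
    assert b == pytest.approx(a, abs=1e-10, rel=1e-9)
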