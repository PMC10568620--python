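"""Tests for the switch-time, proportion, map, sensitivity and area studies."""

import numpy as np
import pytest

import tkiswitch as tk
from tkiswitch.experiments import _strategy_regimens

from helpers import rel


@pytest.fixture(scope="module")
def full_sweeps(table, standard):
    """Integer-day switch sweeps over 1..999 for both sequential strategies."""
    days = np.arange(1, 1000)
    return {
        s: tk.sweep_switch_time(s, days, table, standard) for s in ("A-first", "B-first")
    }


class TestSwitchSweep:
    def test_switch_at_zero_equals_second_line_monotherapy(self, table, standard):
        res = tk.sweep_switch_time("A-first", [0.0], table, standard)
        mono = tk.final_total(
            standard, tk.TreatmentSchedule.monotherapy("B", 1000), table
        )
        assert rel(res.finals[0], mono) < 1e-12

    def test_b_first_minimum_beats_a_first(self, full_sweeps):
        assert full_sweeps["B-first"].min_final < full_sweeps["A-first"].min_final

    def test_b_first_plateau_covers_published_window(self, full_sweeps):
        """Switching any time in days 250-850 under osimertinib-first stays
        within 10% of the optimum (the published 'acceptable' window)."""
        res = full_sweeps["B-first"]
        window = res.finals[(res.switch_days >= 250) & (res.switch_days <= 850)]
        assert window.max() <= 1.1 * res.min_final

    def test_a_first_acceptable_window_is_narrower(self, full_sweeps):
        """Erlotinib-first tolerates a narrower band of switch days than
        osimertinib-first, as reported."""
        widths = {}
        for s, res in full_sweeps.items():
            ok = res.switch_days[res.finals <= 1.1 * res.min_final]
            widths[s] = ok.max() - ok.min()
            assert np.all(np.diff(ok) == 1), "within-10% region is contiguous"
        assert widths["A-first"] < widths["B-first"]

    def test_argmin_reported(self, full_sweeps):
        res = full_sweeps["A-first"]
        assert res.finals[list(res.switch_days).index(res.argmin_day)] == res.min_final

    def test_rejects_days_outside_horizon(self, table, standard):
        with pytest.raises(ValueError):
            tk.sweep_switch_time("A-first", [1500.0], table, standard)


class TestProportionSweep:
    def test_requires_increasing_proportions_in_unit_interval(self, table):
        with pytest.raises(ValueError):
            tk.sweep_initial_proportion("X", [1e-3, 1e-4], params_table=table)
        with pytest.raises(ValueError):
            tk.sweep_initial_proportion("X", [0.5, 1.5], params_table=table)

    def test_exhausted_composition_rejected(self, table):
        with pytest.raises(tk.InvalidCompositionError):
            tk.sweep_initial_proportion("X", [0.5, 0.9999999999], params_table=table)

    def test_flat_then_rising_for_type_x_under_a_first(self, table):
        """Raising the Type-X seed leaves the erlotinib-first outcome flat
        at low fractions and drives it up steeply from ~1e-4, while the
        osimertinib-first and combination outcomes stay within a percent
        through 1e-2."""
        decades = 10.0 ** np.arange(-8, 0)  # 1e-8 .. 1e-1
        res = tk.sweep_initial_proportion("X", decades, params_table=table)
        a = res.finals_per_strategy["A-first"]
        assert a[:3].max() / a[0] < 1.1          # flat through 1e-6
        assert np.all(np.diff(a[4:]) > 0)        # strictly rising from 1e-4
        assert a[5] / a[0] > 2.0                 # steep a decade past 1e-4
        for s in ("B-first", "C"):
            f = res.finals_per_strategy[s]
            assert f[:7].max() / f[0] < 1.01     # within 1% through 1e-2
            assert f.max() / f[0] < 1.1

    def test_long_frame_layout(self, table):
        res = tk.sweep_initial_proportion("Z", np.logspace(-9, -6, 4), params_table=table)
        frame = res.to_frame()
        assert set(frame["strategy"]) == set(tk.STRATEGIES)
        assert len(frame) == 4 * 3


@pytest.fixture(scope="module")
def small_map(table):
    fracs = np.logspace(-8, -1, 5)
    return tk.build_selection_map(fracs, fracs, table)


class TestSelectionMap:
    def test_labels_match_independently_recomputed_argmin(self, table, small_map):
        schedules = tk.standard_schedules()
        for i, xp_ in enumerate(small_map.x_props):
            for j, yp in enumerate(small_map.y_props):
                initial = tk.standard_initial_state(1e9, xp_ * 1e9, yp * 1e9, 10)
                finals = np.array(
                    [tk.final_total(initial, schedules[s], table) for s in tk.STRATEGIES]
                )
                assert np.allclose(finals, small_map.finals[i, j], rtol=1e-12)
                assert small_map.best[i, j] == tk.STRATEGIES[int(np.argmin(finals))]

    def test_label_transitions_monotone_along_y(self, small_map):
        """At a small fixed Type-X fraction, raising the Type-Y fraction
        moves the best label away from B-first and never back."""
        labels = list(small_map.best[0, :])
        left_b = False
        for lab in labels:
            if lab != "B-first":
                left_b = True
            else:
                assert not left_b, f"label sequence returned to B-first: {labels}"

    def test_area_fractions_partition_the_map(self, small_map):
        assert sum(small_map.area_fractions().values()) == pytest.approx(1.0, abs=1e-9)

    def test_fraction_grids_must_be_in_unit_interval(self, table):
        with pytest.raises(ValueError):
            tk.build_selection_map([0.1, 2.0], [0.1], table)


class TestSensitivity:
    def test_final_nondecreasing_in_w_growth_under_a_first(self, table):
        axis = np.linspace(-0.27, -0.07, 5)
        grid = tk.parameter_sensitivity_grid("a", axis, table, strategy="A-first")
        assert np.all(np.diff(grid.finals, axis=0) >= 0)

    def test_final_nondecreasing_in_z_growth_under_combination(self, table):
        grid = tk.parameter_sensitivity_grid(
            "f", np.linspace(-0.078, 0.122, 5), table, strategy="C"
        )
        assert grid.axis2 is None
        assert np.all(np.diff(grid.finals) >= 0)

    def test_single_point_grid_recovers_default_final(self, table, standard):
        grid = tk.parameter_sensitivity_grid(
            "a", ([table["A"].a], [table["B"].a]), table, strategy="A-first"
        )
        expected = tk.final_total(standard, tk.strategy_schedule("A-first"), table)
        assert grid.finals.shape == (1, 1)
        assert rel(grid.finals[0, 0], expected) < 1e-12

    def test_unknown_parameter_rejected(self, table):
        with pytest.raises(tk.UnknownParameterError):
            tk.parameter_sensitivity_grid("m", [0.0], table, strategy="C")

    def test_axis_orientation_follows_first_line_regimen(self, table, standard):
        """Row index varies the first-line regimen's value: under B-first,
        changing only axis1 must change the pre-switch (regimen B) rates."""
        grid = tk.parameter_sensitivity_grid(
            "a", ([-0.4, -0.2], [table["A"].a]), table, strategy="B-first"
        )
        assert grid.finals[0, 0] != grid.finals[1, 0]
        assert _strategy_regimens("B-first") == ("B", "A")


class TestAreaComposition:
    def test_fractions_sum_to_one(self, table):
        comp = tk.selection_area_composition(
            "k_A", np.array([1e-8, 1e-7, 1e-6]), table,
            x_props=np.logspace(-8, -1, 5), y_props=np.logspace(-8, -1, 5),
        )
        for fracs in comp.fractions:
            assert sum(fracs.values()) == pytest.approx(1.0, abs=1e-9)

    def test_b_first_dominates_across_mutation_rate_values(self, table):
        comp = tk.selection_area_composition(
            "k_B", np.array([1e-8, 1e-7, 1e-6]), table,
            x_props=np.logspace(-8, -1, 7), y_props=np.logspace(-8, -1, 7),
        )
        dominant = [max(f, key=f.get) for f in comp.fractions]
        assert dominant.count("B-first") >= 2

    def test_weak_drug_b_shrinks_b_first_area(self, table):
        """When osimertinib loses its effect on Type-W (a_B strongly
        positive), erlotinib-first takes over map area from B-first;
        verified by brute-force map rebuilds on a 5x5 grid."""
        fracs = np.logspace(-8, -1, 5)
        comp = tk.selection_area_composition(
            "a_B", np.array([-0.32, 0.1]), table, x_props=fracs, y_props=fracs
        )
        default_b, weak_b = (f["B-first"] for f in comp.fractions)
        assert weak_b < default_b

    def test_requires_rate_and_regimen(self, table):
        with pytest.raises(tk.UnknownParameterError):
            tk.selection_area_composition("a", [0.1], table)
        with pytest.raises(tk.UnknownParameterError):
            tk.selection_area_composition("a_D", [0.1], table)


def test_experiments_are_deterministic(table, standard):
    days = np.arange(1, 1000, 97)
    r1 = tk.sweep_switch_time("A-first", days, table, standard)
    r2 = tk.sweep_switch_time("A-first", days, table, standard)
    assert np.array_equal(r1.finals, r2.finals)
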