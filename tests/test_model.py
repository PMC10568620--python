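"""Unit and property tests for the closed-form growth-mutation dynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tkiswitch as tk
from tkiswitch.scenarios import ScenarioConfig, sample_scenario

from helpers import max_rel_err, rel


class TestDefaultTable:
    @pytest.mark.parametrize(
        "regimen, rate, expected",
        [
            ("A", "a", -0.17), ("A", "b", 0.045), ("A", "c", -0.13), ("A", "f", 0.022),
            ("B", "a", -0.32), ("B", "b", -0.15), ("B", "c", 0.024), ("B", "f", 0.022),
            ("C", "a", -0.064), ("C", "b", -0.0335), ("C", "c", -0.0335), ("C", "f", 0.022),
        ],
    )
    def test_published_growth_rates(self, table, regimen, rate, expected):
        assert getattr(table[regimen], rate) == expected

    def test_all_mutation_rates_1e_minus_7(self, table):
        for params in table.values():
            assert params.mutation_rates == (1e-7,) * 5

    def test_table_from_file_matches_bundled(self, table, tmp_path):
        import yaml

        path = tmp_path / "params.yaml"
        path.write_text(yaml.safe_dump({r: p.as_dict() for r, p in table.items()}))
        assert tk.load_parameter_table(path) == table


class TestStandardInitialState:
    def test_w_is_the_remainder(self):
        s = tk.standard_initial_state(1e9, 1e4, 1e4, 10)
        assert (s.w, s.x, s.y, s.z, s.t) == (1e9 - 2e4 - 10, 1e4, 1e4, 10, 0.0)

    def test_pure_sensitive_tumor(self):
        s = tk.standard_initial_state(100, 0, 0, 0)
        assert (s.w, s.x, s.y, s.z) == (100, 0, 0, 0)

    @pytest.mark.parametrize("counts", [(10, 5, 5, 5), (10, 10, 0, 0), (1e4, 1e4, 1e4, 1e4)])
    def test_overdrawn_composition_rejected(self, counts):
        with pytest.raises(tk.InvalidCompositionError):
            tk.standard_initial_state(*counts)


class TestClosedForm:
    def test_zero_mutation_exponential_limit(self, table):
        """With all mutation rates zero, each genotype grows as a pure
        exponential at its own rate."""
        params = table["A"].replace(g=0, h=0, k=0, p=0, q=0)
        initial = tk.TumorState(w=1e9, x=1e4, y=1e4, z=10)
        out = tk.closed_form_state(initial, params, 123.0)
        for name, rate, v0 in (("w", params.a, 1e9), ("x", params.b, 1e4),
                               ("y", params.c, 1e4), ("z", params.f, 10)):
            assert rel(getattr(out, name), v0 * math.exp(rate * 123.0)) < 1e-12

    def test_decoupled_decay_of_pure_sensitive_tumor(self):
        params = tk.RegimenParameters("A", a=-0.17, b=0.05, c=-0.1, f=0.02,
                                      g=0, h=0, k=0, p=0, q=0)
        out = tk.closed_form_state(tk.TumorState(1e9, 0, 0, 0), params, 10.0)
        assert rel(out.w, 1e9 * math.exp(-1.7)) < 1e-14
        assert (out.x, out.y, out.z) == (0.0, 0.0, 0.0)

    @pytest.mark.parametrize("regimen", ["A", "B", "C"])
    @pytest.mark.parametrize("dt", [307.0, 567.0, 1000.0])
    def test_matches_ode_oracle_at_defaults(self, table, standard, regimen, dt):
        cf = tk.closed_form_state(standard, table[regimen], dt)
        nm = tk.numeric_reference_state(standard, table[regimen], dt, rel_tol=1e-10)
        assert max_rel_err(cf, nm) < 1e-6

    def test_matches_ode_oracle_on_random_scenarios(self):
        """Closed form and adaptive integration agree on random draws that
        respect the model's sign structure (compact version; the full
        100-scenario sweep runs in the acceptance suite)."""
        cfg = ScenarioConfig(seed=20240901)
        rng = cfg.rng()
        for i in range(20):
            scen = sample_scenario(cfg, rng)
            dt = (10.0, 100.0, 1000.0)[i % 3]
            params = scen.params_table[("A", "B", "C")[i % 3]]
            cf = tk.closed_form_state(scen.initial, params, dt)
            nm = tk.numeric_reference_state(scen.initial, params, dt, rel_tol=1e-10)
            assert max_rel_err(cf, nm) < 1e-6

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        alpha=st.floats(0.0, 5.0),
        beta=st.floats(0.0, 5.0),
        dt=st.floats(0.0, 500.0),
    )
    def test_linearity_in_the_initial_state(self, alpha, beta, dt):
        """The dynamics are linear: propagating a cone combination of two
        states equals the cone combination of the propagated states."""
        params = tk.default_parameter_table()["A"]
        s1 = tk.TumorState(1e9, 1e4, 2e4, 10)
        s2 = tk.TumorState(5e8, 3e3, 1e2, 40)
        mixed = tk.TumorState.from_array(alpha * s1.as_array() + beta * s2.as_array())
        lhs = tk.closed_form_state(mixed, params, dt).as_array()
        rhs = (alpha * tk.closed_form_state(s1, params, dt).as_array()
               + beta * tk.closed_form_state(s2, params, dt).as_array())
        denom = np.maximum(np.maximum(np.abs(lhs), np.abs(rhs)), 1e-300)
        assert np.max(np.abs(lhs - rhs) / denom) < 1e-9 or np.allclose(lhs, rhs)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(dt1=st.floats(0.0, 600.0), dt2=st.floats(0.0, 600.0))
    def test_semigroup_property(self, standard, dt1, dt2):
        """Advancing dt1 then dt2 equals advancing dt1+dt2 in one step."""
        params = tk.default_parameter_table()["B"]
        two_step = tk.closed_form_state(
            tk.closed_form_state(standard, params, dt1), params, dt2
        )
        one_step = tk.closed_form_state(standard, params, dt1 + dt2)
        assert max_rel_err(two_step, one_step) < 1e-9

    def test_nonnegativity_on_random_scenarios(self):
        cfg = ScenarioConfig(seed=7)
        rng = cfg.rng()
        for _ in range(10):
            scen = sample_scenario(cfg, rng)
            for params in scen.params_table.values():
                out = tk.closed_form_state(scen.initial, params, 1000.0)
                assert min(out.w, out.x, out.y, out.z) >= 0

    @pytest.mark.parametrize("rate", list("abcfghkpq"))
    def test_total_monotone_in_each_rate(self, table, standard, rate):
        """Raising any growth or mutation rate can only raise the total."""
        base = table["A"]
        value = getattr(base, rate)
        bumped = base.replace(**{rate: value + 0.01 if rate in "abcf" else value * 10})
        t_base = tk.closed_form_state(standard, base, 1000.0).total()
        t_bump = tk.closed_form_state(standard, bumped, 1000.0).total()
        assert t_bump >= t_base


class TestDegenerateRates:
    def test_fallback_matches_oracle_and_is_logged(self, standard, caplog):
        params = tk.RegimenParameters("A", a=-0.1, b=-0.1, c=0.02, f=0.03,
                                      g=1e-7, h=1e-7, k=1e-7, p=1e-7, q=1e-7)
        assert params.is_degenerate()
        tk.reset_degeneracy_fallback_count()
        with caplog.at_level("WARNING", logger="tkiswitch.model"):
            out = tk.closed_form_state(standard, params, 250.0)
        assert tk.degeneracy_fallback_count() == 1
        assert any("numerical oracle" in r.message for r in caplog.records)
        nm = tk.numeric_reference_state(standard, params, 250.0, rel_tol=1e-12)
        assert max_rel_err(out, nm) < 1e-8

    def test_defaults_are_never_degenerate(self, table):
        assert not any(p.is_degenerate() for p in table.values())


class TestNumericReference:
    def test_zero_elapsed_time_returns_input(self, table, standard):
        out = tk.numeric_reference_state(standard, table["A"], 0.0)
        assert out == standard

    def test_frozen_dynamics_leave_state_unchanged(self, standard):
        params = tk.RegimenParameters("A", *([0.0] * 9))
        out = tk.numeric_reference_state(standard, params, 500.0)
        assert max_rel_err(out, standard) < 1e-9

    def test_invalid_arguments(self, table, standard):
        with pytest.raises(ValueError):
            tk.numeric_reference_state(standard, table["A"], -1.0)
        with pytest.raises(ValueError):
            tk.numeric_reference_state(standard, table["A"], 1.0, rel_tol=0.0)


def test_mutation_rates_must_be_nonnegative():
    with pytest.raises(ValueError):
        tk.RegimenParameters("A", a=-0.1, b=0.1, c=-0.1, f=0.02,
                             g=-1e-7, h=1e-7, k=1e-7, p=1e-7, q=1e-7)
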