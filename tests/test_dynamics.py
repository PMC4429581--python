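"""Single-cell model: geometry, transcription, derivatives, phase machine."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import budsizer as bz
from budsizer import (CellState, ModelParams, area_to_volume,
                      biomass_derivatives, check_transition,
                      cyclin_derivatives, divide, step, total_geometry,
                      transcription_step)
from budsizer.dynamics import G1, S, G2, M


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

class TestGeometry:
    def test_zero_area_zero_volume(self):
        assert area_to_volume(0.0) == 0.0

    def test_power_law(self):
        # V = A^{3/2} in model volume units
        assert area_to_volume(100.0) == pytest.approx(1000.0)
        assert area_to_volume(4.0) == pytest.approx(8.0)

    def test_monotone(self):
        areas = np.linspace(0.1, 50, 40)
        vols = [area_to_volume(a) for a in areas]
        assert np.all(np.diff(vols) > 0)

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            area_to_volume(-1.0)

    def test_total_geometry_no_bud(self):
        s = CellState(A_m=9.0, A_d=0.0, B_R=1.0)
        a, v_m, v_d, v = total_geometry(s)
        assert a == 9.0 and v_d == 0.0 and v == v_m

    def test_total_geometry_symmetric(self):
        s = CellState(A_m=6.0, B_R=1.0)
        s.A_d = 6.0
        a, v_m, v_d, v = total_geometry(s)
        assert v_d / v == pytest.approx(0.5)
        assert a == 12.0

    def test_compartments_summed_separately(self):
        s = CellState(A_m=9.0, B_R=1.0)
        s.A_d = 4.0
        _, v_m, v_d, v = total_geometry(s)
        assert v == pytest.approx(area_to_volume(9.0) + area_to_volume(4.0))
        assert v < area_to_volume(13.0)  # two bodies hold less than one


# ---------------------------------------------------------------------------
# stochastic transcription
# ---------------------------------------------------------------------------

class TestTranscription:
    def test_pure_decay(self):
        # no burst possible: one Euler decay step
        assert transcription_step(5.0, True, 0.0, 0.1, 1.0, u=0.99) == 4.5

    def test_inactive_phase_decays(self):
        m = 10.0
        for _ in range(50):
            m = transcription_step(m, False, 0.4, 0.1, 1.0, u=0.0)
        assert m == pytest.approx(10.0 * 0.9 ** 50)
        assert m == pytest.approx(0.0515, abs=2e-4)

    def test_burst_before_decay(self):
        # burst (+1) applied before the decay of the same step
        assert transcription_step(5.0, True, 0.4, 0.1, 1.0, u=0.1) == \
            pytest.approx(6.0 * 0.9)

    def test_stationary_mean_matches_closed_form(self, rng):
        # E[mRNA] -> P_x (1 - k_d dt) / (k_d dt) under continuous activity
        p_x, k_d, dt, n = 0.4, 0.1, 1.0, 200_000
        m, total = 0.0, 0.0
        burn = 200
        u = rng.random(n + burn)
        for i in range(n + burn):
            m = transcription_step(m, True, p_x, k_d, dt, u[i])
            if i >= burn:
                total += m
        expected = p_x * (1 - k_d * dt) / (k_d * dt)
        # MC standard error of the mean of an AR(1) chain
        se = math.sqrt(expected / (n * k_d * dt / 2))
        assert abs(total / n - expected) < 3 * se
        assert expected == pytest.approx(3.6)


# ---------------------------------------------------------------------------
# derivatives
# ---------------------------------------------------------------------------

def _state_aov_half(b_r=10.0):
    # A/V = A^{-1/2} = 0.5  ->  A = 4
    return CellState(A_m=4.0, A_d=0.0, B_R=b_r)


class TestBiomassDerivatives:
    def test_no_bud_growth_in_g1(self):
        p = bz.best_fit_params("model2")
        db_r, db_am, db_ad = biomass_derivatives(_state_aov_half(), p, G1)
        assert db_ad == 0.0 and db_am > 0 and db_r > 0

    def test_no_mother_growth_in_budded_phase(self):
        p = bz.best_fit_params("model2")
        s = _state_aov_half()
        s.A_d = 1.0
        db_r, db_am, db_ad = biomass_derivatives(s, p, S)
        assert db_am == 0.0 and db_ad > 0

    def test_zero_growth_freezes_biomass(self):
        p = bz.best_fit_params("model2").with_(growth=0.0)
        assert biomass_derivatives(_state_aov_half(), p, G1) == (0, 0, 0)

    def test_direct_evaluation(self):
        # growth*(k_R/(k_R+k_Am+k_Ad))*m_BR*B_R*(A/V)
        p = ModelParams(variant="model2", growth=0.029, k_r_g1=4.098)
        db_r, _, _ = biomass_derivatives(_state_aov_half(10.0), p, G1)
        assert db_r == pytest.approx(0.029 * (4.098 / 5.098) * 10 * 0.5)
        assert db_r == pytest.approx(0.11656, abs=1e-5)

    def test_allocation_fractions_sum_to_one(self):
        p = bz.best_fit_params("model1")
        for ph in (G1, S):
            db = biomass_derivatives(_state_aov_half(), p, ph)
            total = sum(db)
            ks = bz.dynamics.allocation(p, ph)
            base = p.growth * 10.0 * 0.5
            assert total == pytest.approx(base)  # fractions sum to 1
            assert sum(k / sum(ks) for k in ks) == pytest.approx(1.0)


class TestCyclinDerivatives:
    def test_decay_only_without_mrna(self):
        p = ModelParams(variant="model1", k_d=0.1)
        s = _state_aov_half()
        s.Cln = 20.0
        d_cln, d_clb = cyclin_derivatives(s, p, G1)
        assert d_cln == pytest.approx(-2.0)

    def test_model2_needs_a_bud(self):
        # no bud -> V_d/V = 0 -> zero Clb production in model2
        p = ModelParams(variant="model2")
        s = _state_aov_half()
        s.mCLB = 5.0
        _, d_clb = cyclin_derivatives(s, p, G2)
        assert d_clb == 0.0

    def test_direct_evaluation(self):
        p = ModelParams(variant="model1", k_p1=0.452)
        s = _state_aov_half(10.0)
        s.mCLN = 4.0
        d_cln, _ = cyclin_derivatives(s, p, G1)
        assert d_cln == pytest.approx(0.452 * 4 * 10 * 0.5)
        assert d_cln == pytest.approx(9.04)

    def test_translation_confined_to_cognate_phase(self):
        p = ModelParams(variant="model1")
        s = _state_aov_half(10.0)
        s.mCLN = 4.0
        s.mCLB = 4.0
        for ph in (S, G2, M):
            d_cln, _ = cyclin_derivatives(s, p, ph)
            assert d_cln == 0.0  # no Cln production outside G1
        _, d_clb_g1 = cyclin_derivatives(s, p, G1)
        assert d_clb_g1 == 0.0  # no Clb production outside G2


# ---------------------------------------------------------------------------
# the Euler step
# ---------------------------------------------------------------------------

class TestStep:
    def test_vanishing_step_leaves_state(self):
        p = bz.best_fit_params("model2").with_(dt=1e-12)
        s = CellState(A_m=4.0, B_R=10.0)
        before = (s.A_m, s.B_R, s.Cln)
        step(s, p, uniforms=(0.99, 0.99))
        assert s.A_m == pytest.approx(before[0], rel=1e-9)
        assert s.B_R == pytest.approx(before[1], rel=1e-9)

    @pytest.mark.parametrize("dt,tol", [(1.0, 0.06), (0.25, 0.02)])
    def test_cln_matches_linear_ode_closed_form(self, dt, tol):
        """Frozen geometry, clamped mRNA: Cln(t) = (p/kd)(1 - e^{-kd t})."""
        p = ModelParams(variant="model1", growth=0.0, p_cln=0.0, dt=dt)
        s = _state_aov_half(10.0)
        t_end = 30.0
        n = int(t_end / dt)
        for _ in range(n):
            # clamp the mRNA: pre-compensate the in-step Euler decay so the
            # production term sees a constant mCLN = 4
            s.mCLN = 4.0 / (1.0 - p.k_d * dt)
            step(s, p, uniforms=(0.9, 0.9))
        prod = p.k_p1 * 4.0 * 10.0 * 0.5
        exact = (prod / p.k_d) * (1 - math.exp(-p.k_d * t_end))
        assert s.Cln == pytest.approx(exact, rel=tol)

    def test_refinement_consistency(self):
        """Two half steps agree with one full step to first order."""
        def run(dt, n):
            p = ModelParams(variant="model1", growth=0.029, p_cln=0.0, dt=dt)
            s = _state_aov_half(10.0)
            s.mCLN = 4.0
            for _ in range(n):
                step(s, p, uniforms=(0.9, 0.9))
            return s
        a, b = run(1.0, 1), run(0.5, 2)
        assert b.Cln == pytest.approx(a.Cln, rel=0.05)
        assert b.B_R == pytest.approx(a.B_R, rel=0.01)

    def test_areas_never_decrease_and_grow_by_phase(self):
        p = bz.best_fit_params("model2")
        s = CellState(A_m=10.0, B_R=4.0)
        rng = np.random.default_rng(5)
        t = 0.0
        for _ in range(600):
            am0, ad0 = s.A_m, s.A_d
            step(s, p, rng=rng)
            t += p.dt
            assert s.A_m >= am0 and s.A_d >= ad0
            if s.phase == G1:
                assert s.A_d == ad0      # bud grows only when budded
            else:
                assert s.A_m == am0      # mother grows only in G1
            check_transition(s, p, t)

    def test_non_finite_state_rejected(self):
        p = bz.best_fit_params("model2")
        s = _state_aov_half()
        s.B_R = math.nan
        with pytest.raises(FloatingPointError):
            step(s, p, uniforms=(0.5, 0.5))


class TestEulerStepSize:
    def test_halving_dt_changes_deterministic_g1_little(self):
        """With the mRNA clamped at its stationary mean the G1 length is
        deterministic; halving dt moves it by well under 2%."""
        def t_g1(dt):
            p = bz.best_fit_params("model2").with_(p_cln=0.0, dt=dt)
            s = CellState(A_m=14.0, B_R=12.0)
            t = 0.0
            while s.phase == G1:
                s.mCLN = 3.6 / (1.0 - p.k_d * dt)
                step(s, p, uniforms=(0.9, 0.9))
                t += dt
                check_transition(s, p, t)
                assert t < 5000
            return t
        a, b = t_g1(1.0), t_g1(0.5)
        assert abs(a - b) / a < 0.02


# ---------------------------------------------------------------------------
# phase machine
# ---------------------------------------------------------------------------

class TestTransitions:
    def _cell(self, phase, entry=0.0):
        s = CellState(A_m=9.0, A_d=1.0 if phase != G1 else 0.0, B_R=5.0)
        s.phase = phase
        s.phase_entry_time = entry
        return s

    def test_start_fires_at_threshold(self):
        p = bz.best_fit_params("model2")
        s = self._cell(G1)
        s.Cln = 150.0
        assert check_transition(s, p, t=10.0) == "START"
        assert s.phase == S and s.t_start == 10.0
        assert s.v_start == pytest.approx(s.volume)

    def test_threshold_is_strict(self):
        p = bz.best_fit_params("model2")
        s = self._cell(G2)
        s.Clb = 149.99
        assert check_transition(s, p, t=10.0) is None
        s.Clb = 150.0
        assert check_transition(s, p, t=10.0) == "G2M"

    def test_s_phase_fixed_duration(self):
        p = bz.best_fit_params("model2")
        s = self._cell(S, entry=100.0)
        assert check_transition(s, p, t=124.0) is None
        assert check_transition(s, p, t=125.0) == "S_end"

    def test_mitosis_fixed_duration_ends_in_division(self):
        p = bz.best_fit_params("model2")
        s = self._cell(M, entry=200.0)
        assert check_transition(s, p, t=204.0) is None
        assert check_transition(s, p, t=205.0) == "division"


class TestDivision:
    def _ready(self):
        s = CellState(A_m=9.0, B_R=8.0)
        s.A_d = 4.0
        s.phase = M
        s.mCLN, s.mCLB, s.Cln, s.Clb = 1.5, 2.5, 10.0, 80.0
        s.t_start, s.v_start = 40.0, area_to_volume(9.0)
        s.cycle_start_time = 0.0
        return s

    def test_conservation_of_solubles_and_area(self):
        s = self._ready()
        pre = {k: getattr(s, k) for k in ("B_R", "mCLN", "mCLB", "Cln", "Clb")}
        area_pre = s.A_m + s.A_d
        mother, daughter, rec = divide(s, t=100.0, next_id=7)
        for k, v in pre.items():
            total = getattr(mother, k) + getattr(daughter, k)
            assert abs(total - v) <= 1e-9 * abs(v)
        assert mother.A_m + daughter.A_m == pytest.approx(area_pre, rel=1e-12)
        assert mother.A_d == 0.0 and daughter.A_d == 0.0

    def test_split_by_volume_ratio(self):
        s = self._ready()
        v_m, v_d = area_to_volume(s.A_m), area_to_volume(s.A_d)
        r = v_d / (v_m + v_d)
        _, daughter, _ = divide(self._ready(), t=100.0, next_id=7)
        assert daughter.B_R == pytest.approx(8.0 * r)
        assert daughter.Clb == pytest.approx(80.0 * r)

    def test_quarter_split(self):
        s = self._ready()
        # pick bud so that V_d/V = 1/4 exactly: V_d = V_m / 3
        s.A_d = (area_to_volume(s.A_m) / 3.0) ** (2.0 / 3.0)
        _, daughter, _ = divide(s, t=100.0, next_id=7)
        assert daughter.B_R == pytest.approx(2.0)

    def test_ages_and_identity(self):
        s = self._ready()
        s.replicative_age = 3
        s.cycle_start_age = 3
        mother, daughter, rec = divide(s, t=100.0, next_id=42)
        assert mother.replicative_age == 4
        assert daughter.replicative_age == 0
        assert daughter.id == 42 and daughter.parent_id == s.id
        assert rec.role == "mother" and rec.replicative_age == 3
        assert mother.phase == G1 and daughter.phase == G1

    def test_division_without_bud_invalid(self):
        s = CellState(A_m=9.0, B_R=1.0)
        with pytest.raises(ValueError):
            divide(s, t=10.0, next_id=1)

    @given(a_m=st.floats(1.0, 100.0), a_d=st.floats(0.1, 80.0),
           b_r=st.floats(0.1, 1000.0))
    @settings(max_examples=50, deadline=None)
    def test_conservation_property(self, a_m, a_d, b_r):
        s = CellState(A_m=a_m, B_R=b_r)
        s.A_d = a_d
        s.Cln = 3.0
        s.t_start, s.v_start = 1.0, 5.0
        s.cycle_start_time = 0.0
        mother, daughter, _ = divide(s, t=10.0, next_id=1)
        assert mother.B_R + daughter.B_R == pytest.approx(b_r, rel=1e-9)


# ---------------------------------------------------------------------------
# arrest without transcription
# ---------------------------------------------------------------------------

def test_no_bursts_means_permanent_g1_arrest():
    """With P_x = 0 no cyclin is ever produced: 10,000 simulated minutes
    leave the cell in G1 with zero Cln."""
    p = bz.best_fit_params("model2").with_(p_cln=0.0, p_clb=0.0)
    s = CellState(A_m=10.0, B_R=5.0)
    rng = np.random.default_rng(0)
    for t in range(1, 10_001):
        step(s, p, rng=rng)
        check_transition(s, p, float(t))
    assert s.phase == G1
    assert s.Cln == 0.0 and s.Clb == 0.0
    assert s.A_d == 0.0


# ---------------------------------------------------------------------------
# parameter validation
# ---------------------------------------------------------------------------

class TestModelParams:
    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            ModelParams(variant="model3")

    def test_negative_rate(self):
        with pytest.raises(ValueError):
            ModelParams(growth=-0.01)

    def test_burst_probability_bounded(self):
        with pytest.raises(ValueError):
            ModelParams(p_cln=1.5)

    def test_presets_match_published_values(self):
        m1 = bz.best_fit_params("model1")
        assert (m1.growth, m1.k_p1, m1.k_p2) == (0.028, 0.452, 0.342)
        assert (m1.k_r_g1, m1.k_r_sg2m) == (4.92, 1.495)
        m2 = bz.best_fit_params("model2")
        assert (m2.growth, m2.k_p1, m2.k_p2) == (0.029, 0.589, 1.606)
        assert m2.threshold == 150 and m2.s_dur == 25 and m2.m_dur == 5
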