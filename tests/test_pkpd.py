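"""Structural model: drug amount kinetics, effect model, turnover solution."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from acetapop import (
    DoseEvent,
    EffectParameters,
    PKConstants,
    TurnoverState,
    amount_iv,
    amount_oral,
    effect_multiplier,
    oracle_bicarbonate,
    solve_bicarbonate,
)
from acetapop._engine import ProfileEngine
from conftest import random_iv_regimen


class TestAmountIV:
    def test_half_life_default_is_quarter_day(self):
        assert PKConstants().half_life == 0.25

    @pytest.mark.parametrize("t, expected", [
        (0.0, 500.0),      # instantaneous bolus
        (0.25, 250.0),     # one half-life
        (0.5, 125.0),      # two half-lives
    ])
    def test_single_bolus_decay(self, t, expected):
        reg = [DoseEvent(0.0, 500.0)]
        assert amount_iv(reg, t, PKConstants()) == pytest.approx(expected)

    def test_two_dose_superposition_around_second_dose(self):
        reg = [DoseEvent(0.0, 500.0), DoseEvent(0.5, 500.0)]
        pk = PKConstants()
        assert amount_iv(reg, 0.5 - 1e-12, pk) == pytest.approx(125.0, abs=1e-6)
        assert amount_iv(reg, 0.5, pk) == pytest.approx(625.0)

    def test_zero_before_first_dose(self):
        reg = [DoseEvent(1.0, 500.0)]
        assert amount_iv(reg, 0.5, PKConstants()) == 0.0

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            amount_iv([DoseEvent(0.0, 500.0)], -0.1, PKConstants())

    def test_negative_amount_rejected(self):
        with pytest.raises(ValueError):
            DoseEvent(0.0, -5.0)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000), t=st.floats(0.0, 4.0))
    def test_superposition_of_merged_regimens(self, seed, t):
        """A(t) of a merged regimen equals the sum over its parts."""
        rng = np.random.default_rng(seed)
        pk = PKConstants()
        r1 = random_iv_regimen(rng)
        r2 = random_iv_regimen(rng)
        total = amount_iv(r1 + r2, t, pk)
        assert total == pytest.approx(amount_iv(r1, t, pk) + amount_iv(r2, t, pk),
                                      rel=1e-12)


class TestAmountOral:
    def test_zero_at_dose_time(self):
        pk = PKConstants(k_a=10.0)
        assert amount_oral([DoseEvent(0.0, 500.0)], 0.0, pk) == 0.0

    def test_fast_absorption_approaches_iv(self):
        pk_fast = PKConstants(k_a=1e5)
        pk = PKConstants()
        reg = [DoseEvent(0.0, 500.0)]
        t = 0.5
        assert amount_oral(reg, t, pk_fast) == pytest.approx(
            amount_iv(reg, t, pk), rel=1e-3)

    def test_washout(self):
        pk = PKConstants(k_a=5.0)
        assert amount_oral([DoseEvent(0.0, 500.0)], 50.0, pk) < 1e-9

    def test_equal_rates_limit_form_is_continuous(self):
        ke = PKConstants().k_elim
        reg = [DoseEvent(0.0, 500.0)]
        exact = amount_oral(reg, 0.3, PKConstants(k_a=ke))
        near = amount_oral(reg, 0.3, PKConstants(k_a=ke * (1 + 1e-7)))
        assert exact == pytest.approx(near, rel=1e-5)


class TestEffectMultiplier:
    @pytest.mark.parametrize("amount, expected", [
        (0.0, 1.0),
        (117.0, 1.5),     # half-maximal at A = A50
        (1e12, 2.0),      # asymptote with Emax = 1
    ])
    def test_reference_values(self, amount, expected):
        eff = EffectParameters(e_max=1.0, a50=117.0)
        assert effect_multiplier(amount, eff) == pytest.approx(expected, rel=1e-6)

    def test_strictly_increasing_and_bounded(self):
        eff = EffectParameters()
        a = np.linspace(0, 5000, 200)
        e = effect_multiplier(a, eff)
        assert np.all(np.diff(e) > 0)
        assert np.all((e >= 1.0) & (e <= 2.0))

    def test_negative_amount_rejected(self):
        with pytest.raises(ValueError):
            effect_multiplier(-1.0, EffectParameters())


class TestTurnover:
    def test_empty_regimen_stays_at_equilibrium(self):
        state = TurnoverState(35.5, 0.395)
        times = np.linspace(0, 5, 11)
        b = solve_bicarbonate(state, EffectParameters(), [], PKConstants(), times)
        assert b == pytest.approx(np.full_like(times, 35.5), abs=1e-8)

    def test_kin_equals_equilibrium_product(self):
        state = TurnoverState(35.5, 0.395)
        assert state.k_in == pytest.approx(14.0225)

    def test_sustained_maximal_effect_decays_to_half_baseline(self):
        """With A >> A50 held constant, E = 2 and B -> bicar0/2 monotonically."""
        state = TurnoverState(35.5, 0.395)
        # near-zero elimination keeps the amount (and E ~ 2) constant
        pk = PKConstants(k_elim=1e-9)
        reg = [DoseEvent(0.0, 1e9)]
        times = np.linspace(0, 40, 60)
        b = solve_bicarbonate(state, EffectParameters(), reg, pk, times)
        assert np.all(np.diff(b) < 1e-9)
        assert b[-1] == pytest.approx(35.5 / 2, rel=1e-4)

    def test_oracle_reduces_to_baseline_without_doses(self):
        state = TurnoverState(35.5, 0.395)
        b = oracle_bicarbonate(state, EffectParameters(), [], PKConstants(),
                               [0.0, 1.0, 3.0])
        assert b == pytest.approx([35.5] * 3, abs=1e-10)

    def test_ode_matches_oracle_on_published_parameters(self):
        state = TurnoverState(35.5, 0.395)
        pk = PKConstants()
        reg = [DoseEvent(0.0, 500.0)]
        times = np.array([0.0, 0.1, 0.25, 0.5, 1.0, 2.0])
        b_ode = solve_bicarbonate(state, EffectParameters(), reg, pk, times)
        b_orc = oracle_bicarbonate(state, EffectParameters(), reg, pk, times)
        assert np.max(np.abs(b_ode - b_orc)) < 1e-6

    def test_trajectory_bounds_and_washout(self):
        state = TurnoverState(35.5, 0.395)
        pk = PKConstants()
        reg = [DoseEvent(0.5 * i, 500.0) for i in range(6)]
        times = np.linspace(0, 30, 200)
        b = solve_bicarbonate(state, EffectParameters(), reg, pk, times)
        assert np.all(b <= 35.5 + 1e-8)
        assert np.all(b >= 35.5 / 2 - 1e-8)
        assert abs(b[-1] - 35.5) / 35.5 < 0.01  # recovery after washout

    def test_monotone_dose_response(self):
        """Scaling every dose up never raises any bicarbonate value."""
        state = TurnoverState(35.5, 0.395)
        pk = PKConstants()
        times = np.linspace(0.1, 4, 20)
        rng = np.random.default_rng(5)
        reg = random_iv_regimen(rng)
        lo = solve_bicarbonate(state, EffectParameters(), reg, pk, times)
        hi_reg = [DoseEvent(d.time, d.amount * 2.0) for d in reg]
        hi = solve_bicarbonate(state, EffectParameters(), hi_reg, pk, times)
        assert np.all(hi <= lo + 1e-9)

    def test_unsorted_times_rejected(self):
        state = TurnoverState(35.5, 0.395)
        with pytest.raises(ValueError):
            solve_bicarbonate(state, EffectParameters(), [], PKConstants(),
                              [1.0, 0.5])


class TestProfileEngine:
    """The fast integrating-factor evaluator agrees with both slow routes."""

    @pytest.mark.parametrize("seed", range(5))
    def test_three_way_agreement_on_random_regimens(self, seed):
        rng = np.random.default_rng(seed)
        reg = random_iv_regimen(rng)
        b0 = float(rng.uniform(25, 45))
        kout = float(rng.uniform(0.1, 1.5))
        a50 = float(rng.uniform(50, 300))
        state = TurnoverState(b0, kout)
        eff = EffectParameters(a50=a50)
        pk = PKConstants()
        times = np.sort(rng.uniform(0.0, 4.0, size=5))

        class S:
            dose_times = np.array([d.time for d in reg])
            dose_amounts = np.array([d.amount for d in reg])
            obs_times = times

        eng = ProfileEngine([S()], k_elim=pk.k_elim, a50=a50)
        b_eng = eng.eval(np.array([b0]), np.array([kout]))[0, :5]
        b_ode = solve_bicarbonate(state, eff, reg, pk, times)
        b_orc = oracle_bicarbonate(state, eff, reg, pk, times)
        assert np.max(np.abs(b_eng - b_orc)) < 1e-6
        assert np.max(np.abs(b_eng - b_ode)) < 1e-6

    def test_linear_in_baseline(self):
        rng = np.random.default_rng(9)
        reg = random_iv_regimen(rng)

        class S:
            dose_times = np.array([d.time for d in reg])
            dose_amounts = np.array([d.amount for d in reg])
            obs_times = np.array([0.5, 1.5])

        eng = ProfileEngine([S()], k_elim=PKConstants().k_elim, a50=117.0)
        b1 = eng.eval(np.array([30.0]), np.array([0.4]))
        b2 = eng.eval(np.array([60.0]), np.array([0.4]))
        assert b2 == pytest.approx(2.0 * b1, rel=1e-12)
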