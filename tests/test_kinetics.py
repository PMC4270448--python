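"""Closed-form kinetics vs. independent numerical oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from junctionfit import (
    CruciformRates,
    DomainError,
    convert_rate,
    cruciform_fractions,
    exp_progress,
    nicked_peak,
    ode_trajectory,
)
from junctionfit.errors import UnitError

rates_st = st.tuples(
    st.floats(1e-3, 10.0), st.floats(1e-3, 10.0)
).map(lambda ks: CruciformRates(*ks))


class TestExpProgress:
    @pytest.mark.parametrize(
        "Ff, kc, t, expected",
        [
            (0.9, 0.01, 0.0, 0.0),                  # no time elapsed
            (0.9, 0.01, 1e7, 0.9),                  # plateau equals Ff
            (1.0, 0.01, np.log(2) / 0.01, 0.5),     # half-life identity
        ],
    )
    def test_known_values(self, Ff, kc, t, expected):
        assert exp_progress(Ff, kc, t) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "Ff, kc, t",
        [(0.9, 0.01, -1.0), (0.9, -0.01, 1.0), (0.9, 0.0, 1.0),
         (0.0, 0.01, 1.0), (1.5, 0.01, 1.0)],
    )
    def test_domain_errors(self, Ff, kc, t):
        with pytest.raises(DomainError):
            exp_progress(Ff, kc, t)

    @given(Ff=st.floats(0.05, 1.0), kc=st.floats(1e-4, 10.0))
    def test_monotone_and_bounded(self, Ff, kc):
        t = np.linspace(0, 5.0 / kc, 50)
        F = exp_progress(Ff, kc, t)
        assert np.all(np.diff(F) >= 0)
        assert np.all(F <= Ff + 1e-15)
        assert np.all(F >= 0)


class TestCruciformFractions:
    def test_initial_condition(self):
        st0 = cruciform_fractions(CruciformRates(0.019, 0.20), 0.0)
        assert (st0.fS, st0.fN, st0.fL) == (1.0, 0.0, 0.0)

    def test_degenerate_limit_value(self):
        # k1 = k2 = 0.1, t = 10: fN = k1*t*exp(-k1*t) = e^-1
        st10 = cruciform_fractions(CruciformRates(0.1, 0.1), 10.0)
        assert st10.fN == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_degenerate_limit_matches_ode(self):
        rates = CruciformRates(0.1, 0.1)
        grid = np.linspace(0.5, 60, 40)
        traj = ode_trajectory(rates, grid)
        an = cruciform_fractions(rates, grid)
        assert np.max(np.abs(an.fN - traj.fN)) < 1e-6

    def test_reported_rates_peak_value_against_ode(self):
        # fN at t = 13 min for (0.019, 0.20) min^-1, near the peak
        rates = CruciformRates(0.019, 0.20)
        an = cruciform_fractions(rates, 13.0)
        traj = ode_trajectory(rates, np.array([13.0]))
        assert an.fN == pytest.approx(float(traj.fN[0]), abs=1e-8)
        assert an.fN == pytest.approx(0.074, abs=5e-4)

    def test_negative_time_rejected(self):
        with pytest.raises(DomainError):
            cruciform_fractions(CruciformRates(0.1, 0.2), -1.0)

    @given(rates=rates_st, t=st.floats(0.0, 1e3))
    def test_conservation(self, rates, t):
        s = cruciform_fractions(rates, t)
        assert abs(s.fS + s.fN + s.fL - 1.0) <= 1e-12

    @given(rates=rates_st)
    def test_monotonicity(self, rates):
        t = np.linspace(0, 10.0 / min(rates.k1, rates.k2), 200)
        s = cruciform_fractions(rates, t)
        # strict until the exponentials underflow / the reaction completes
        active = (s.fS[:-1] > 1e-12) & (s.fL[:-1] < 1 - 1e-12)
        assert np.all(np.diff(s.fS)[active] < 0)
        assert np.all(np.diff(s.fL)[active] > 0)
        assert np.all(np.diff(s.fS) <= 0)
        assert np.all(np.diff(s.fL) >= 0)

    @given(rates=rates_st)
    def test_nicked_unimodality(self, rates):
        t = np.linspace(0, 10.0 / min(rates.k1, rates.k2), 2000)
        fN = cruciform_fractions(rates, t).fN
        rising = np.diff(fN) > 0
        # exactly one switch from rising to falling
        assert np.sum(np.diff(rising.astype(int)) == -1) == 1

    def test_continuity_at_degeneracy(self):
        t = np.linspace(0, 50, 101)
        near = cruciform_fractions(CruciformRates(0.1, 0.1 * (1 + 1e-9)), t).fN
        limit = 0.1 * t * np.exp(-0.1 * t)
        assert np.max(np.abs(near - limit)) <= 1e-8


class TestNickedPeak:
    def test_degenerate_peak_time(self):
        t_star, height = nicked_peak(CruciformRates(0.1, 0.1))
        assert t_star == pytest.approx(10.0, rel=1e-12)
        assert height == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_peak_matches_dense_grid_argmax(self):
        rates = CruciformRates(0.019, 0.20)
        t_star, height = nicked_peak(rates)
        grid = np.linspace(0.01, 120, 200_000)
        fN = cruciform_fractions(rates, grid).fN
        assert t_star == pytest.approx(grid[np.argmax(fN)], abs=1e-2)
        assert t_star == pytest.approx(13.0, abs=0.05)
        assert height < 1.0

    @given(rates=rates_st)
    def test_maximality(self, rates):
        t_star, height = nicked_peak(rates)
        eps = 1e-4 * t_star
        for t in (t_star - eps, t_star + eps):
            assert cruciform_fractions(rates, t).fN <= height + 1e-15


class TestOdeOracle:
    def test_initial_condition(self):
        traj = ode_trajectory(CruciformRates(0.3, 0.7), np.array([0.0]))
        assert (traj.fS[0], traj.fN[0], traj.fL[0]) == (1.0, 0.0, 0.0)

    def test_agreement_over_random_rate_pairs(self, rng):
        # 100 rate pairs spanning 4 orders of magnitude
        for k1, k2 in 10 ** rng.uniform(-2, 2, size=(100, 2)):
            rates = CruciformRates(k1, k2)
            grid = np.linspace(0, 10.0 / min(k1, k2), 25)[1:]
            traj = ode_trajectory(rates, grid)
            an = cruciform_fractions(rates, grid)
            dev = max(
                np.max(np.abs(an.fS - traj.fS)),
                np.max(np.abs(an.fN - traj.fN)),
                np.max(np.abs(an.fL - traj.fL)),
            )
            assert dev <= 1e-6, (k1, k2, dev)

    def test_invalid_grid_rejected(self):
        rates = CruciformRates(0.1, 0.2)
        with pytest.raises(DomainError):
            ode_trajectory(rates, np.array([1.0, 0.5]))
        with pytest.raises(DomainError):
            ode_trajectory(rates, np.array([-1.0, 2.0]))


class TestUnits:
    def test_rate_conversion_s_to_min(self):
        assert convert_rate(0.008, "s", "min") == pytest.approx(0.48)
        assert convert_rate(0.48, "min", "s") == pytest.approx(0.008)

    def test_unknown_unit_rejected(self):
        with pytest.raises(UnitError):
            convert_rate(1.0, "s", "fortnight")

    def test_rates_require_valid_unit(self):
        with pytest.raises(UnitError):
            CruciformRates(0.1, 0.2, time_unit="parsec")

    def test_acceleration_is_exact_ratio(self):
        r = CruciformRates(0.019, 0.20)
        assert r.acceleration == 0.20 / 0.019
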