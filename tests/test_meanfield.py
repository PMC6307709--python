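import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import p_of_m_brute, richardson_p2
from qvoter.meanfield import (
    DegenerateStationaryError,
    NoTransitionError,
    classify_transition,
    critical_p,
    critical_r,
    critical_r_scan,
    critical_z,
    effective_force,
    is_discontinuous,
    meanfield_trajectory,
    p2_coefficient,
    p_series,
    potential_profile,
    spinodals,
    stationary_curve,
    stationary_p,
    tricritical_q,
)


class TestStationaryP:
    def test_closed_form_independence(self):
        # q=3, r=w=3, z=1: p(m) = (1 - m^2)/(3 - m^2)
        assert stationary_p(0.5, 3, 3, 3, 1.0) == pytest.approx(3 / 11)
        for m in np.linspace(0.05, 0.95, 19):
            assert stationary_p(m, 3, 3, 3, 1.0) == pytest.approx((1 - m**2) / (3 - m**2), abs=1e-14)

    def test_closed_form_anticonformity(self):
        # q=3, r=w=3, z=0: p(m) = (1 - m^2)/(3 + m^2)
        assert stationary_p(0.5, 3, 3, 3, 0.0) == pytest.approx(3 / 13)
        for m in np.linspace(0.05, 0.95, 19):
            assert stationary_p(m, 3, 3, 3, 0.0) == pytest.approx((1 - m**2) / (3 + m**2), abs=1e-14)

    def test_closed_form_general_q_z1(self):
        # z=1, r=w=q: p(m) = A/(A + m/2) for every q on a fine grid
        for q in (2, 4, 6, 9):
            for m in np.linspace(0.05, 0.95, 10):
                x, v = (1 + m) / 2, (1 - m) / 2
                A = v * x**q - x * v**q
                assert stationary_p(m, q, q, q, 1.0) == pytest.approx(A / (A + m / 2), abs=1e-13)

    @given(m=st.floats(0.01, 0.99), q=st.integers(2, 8), z=st.floats(0, 1), data=st.data())
    @settings(max_examples=100)
    def test_flip_symmetry_and_brute_oracle(self, m, q, z, data):
        r = data.draw(st.integers(q // 2 + 1, q))
        w = data.draw(st.integers(1, q))
        p = stationary_p(m, q, r, w, z)
        assert stationary_p(-m, q, r, w, z) == pytest.approx(p, abs=1e-12)
        assert p == pytest.approx(p_of_m_brute(m, q, r, w, z), abs=1e-10)

    def test_m_zero_rejected(self):
        with pytest.raises(ValueError):
            stationary_p(0.0, 3, 3, 3, 1.0)

    def test_curve_physical_and_symmetric_storage(self):
        curve = stationary_curve(6, 6, 6, 1.0)
        assert np.all(curve.m > 0)
        assert np.all((curve.p >= 0) & (curve.p <= 1))


class TestCriticalP:
    @pytest.mark.parametrize("q,r,w,z,expected", [
        (3, 3, 3, 1.0, 1 / 3),
        (4, 4, 4, 1.0, 3 / 11),
        (3, 3, 3, 0.0, 1 / 3),
    ])
    def test_examples(self, q, r, w, z, expected):
        assert critical_p(q, r, w, z) == pytest.approx(expected, abs=1e-14)

    def test_closed_forms_unanimity(self):
        for q in range(2, 11):
            assert critical_p(q, q, q, 1.0) == pytest.approx((q - 1) / (q - 1 + 2 ** (q - 1)))
            assert critical_p(q, q, q, 0.0) == pytest.approx((q - 1) / (2 * q))

    def test_monotonicity_in_q(self):
        ps1 = [critical_p(q, q, q, 1.0) for q in range(2, 11)]
        ps0 = [critical_p(q, q, q, 0.0) for q in range(2, 11)]
        # independence: non-increasing (flat only at q=2->3), anticonformity: increasing
        assert all(b <= a + 1e-15 for a, b in zip(ps1, ps1[1:]))
        assert ps1[-1] < ps1[0]
        assert all(b > a for a, b in zip(ps0, ps0[1:]))

    def test_exact_mode(self):
        assert critical_p(3, 3, 3, 1, exact=True) == Fraction(1, 3)


class TestPSeries:
    def test_against_frozen_sympy_values(self):
        # computed once with an independent sympy series expansion
        p0, p2, _, _ = (float(c) for c in p_series(10, 8, 8, Fraction(1, 2)))
        assert p0 == pytest.approx(0.3958333333333333, abs=1e-15)
        assert p2 == pytest.approx(-0.43212890625, abs=1e-12)
        p0, p2, _, _ = (float(c) for c in p_series(50, 29, 25, Fraction(0)))
        assert p0 == pytest.approx(0.3186844325249903, abs=1e-15)
        assert p2 == pytest.approx(0.702589676186576, abs=1e-12)

    @pytest.mark.parametrize("q,r,w,z", [(6, 6, 6, 1.0), (4, 3, 2, 0.5), (7, 5, 3, 0.25)])
    def test_against_richardson_fallback(self, q, r, w, z):
        assert float(p2_coefficient(q, r, w, z)) == pytest.approx(
            richardson_p2(q, r, w, z, eps=0.02), rel=1e-4)

    def test_q5_unanimity_quadratic_term_vanishes(self):
        # C(5,3) = C(5,2) makes the cubic coefficient of A vanish exactly;
        # the quartic term decides the type: p(m) = (1-m^4)/(5-m^4).
        p0, p2, p4, _ = p_series(5, 5, 5, 1)
        assert p0 == Fraction(1, 5)
        assert p2 == 0
        assert p4 == Fraction(-4, 25)


class TestClassification:
    @pytest.mark.parametrize("q,expected", [
        (2, "continuous"), (3, "continuous"), (4, "continuous"), (5, "continuous"),
        (6, "discontinuous"), (7, "discontinuous"),
    ])
    def test_independence_special_case(self, q, expected):
        assert classify_transition(q, q, q, 1.0).transition_type == expected

    @pytest.mark.parametrize("q", range(2, 11))
    def test_anticonformity_always_continuous(self, q):
        assert classify_transition(q, q, q, 0.0).transition_type == "continuous"

    def test_spinodal_ordering(self):
        cls = classify_transition(6, 6, 6, 1.0)
        assert cls.p_upper > cls.p_star
        cls = classify_transition(4, 4, 4, 1.0)
        assert cls.p_upper == cls.p_star

    def test_consistency_with_potential_minima(self):
        # discontinuous: three minima just below the upper spinodal
        p_lo, p_hi = spinodals(6, 6, 6, 1.0)
        grid = np.linspace(-1, 1, 2001)
        prof = potential_profile(grid, 6, 6, 6, p_hi - 0.002, 1.0)
        n_min = _count_local_minima(prof.V)
        assert n_min == 3
        # continuous at the same relative position: a single symmetric pair
        p_star = critical_p(4, 4, 4, 1.0)
        prof = potential_profile(grid, 4, 4, 4, p_star - 0.02, 1.0)
        assert _count_local_minima(prof.V) == 2

    def test_half_threshold_column_continuous_at_larger_q(self):
        # r = q/2 yields only continuous transitions once q is moderately
        # large (q = 4 is a genuine exception of the equations; see ledger).
        for q in (8, 16):
            for w in (q // 2, (3 * q) // 4, q):
                for z in (0.0, 0.5, 1.0):
                    assert classify_transition(q, q // 2, w, z).transition_type == "continuous"

    def test_q4_half_threshold_exception_is_discontinuous(self):
        # regression: documented deviation from the narrative claim that the
        # half-threshold column is always continuous
        assert classify_transition(4, 2, 2, 0.5).transition_type == "discontinuous"

    def test_no_transition_for_weak_conformity(self):
        with pytest.raises(NoTransitionError):
            classify_transition(2, 1, 2, 1.0)


def _count_local_minima(V):
    return int(np.sum((V[1:-1] < V[:-2]) & (V[1:-1] < V[2:])))


class TestSpinodals:
    def test_continuous_collapse(self):
        assert spinodals(3, 3, 3, 1.0) == pytest.approx((1 / 3, 1 / 3))

    def test_discontinuous_gap(self):
        lo, hi = spinodals(6, 6, 6, 1.0)
        assert lo == pytest.approx(5 / 37, abs=1e-12)
        assert hi - lo > 0.01

    def test_gap_vanishes_at_critical_z(self):
        z_star = critical_z(6, 6, 6)
        lo, hi = spinodals(6, 6, 6, z_star + 0.01)
        assert 0 < hi - lo < 5e-3
        assert classify_transition(6, 6, 6, z_star - 0.01).transition_type == "continuous"

    def test_gap_continuous_in_z(self):
        zs = np.linspace(0.5, 1.0, 6)
        gaps = [spinodals(6, 6, 6, z)[1] - spinodals(6, 6, 6, z)[0] for z in zs]
        assert all(g2 > g1 - 1e-9 for g1, g2 in zip(gaps, gaps[1:]))


class TestPotentialProfile:
    def test_pure_independence_quadratic(self):
        grid = np.linspace(-1, 1, 401)
        prof = potential_profile(grid, 3, 3, 3, 1.0, 1.0)
        assert prof.F == pytest.approx(-grid / 2, abs=1e-12)
        assert prof.V == pytest.approx(grid**2 / 4, abs=1e-5)

    def test_pure_conformity_consensus_minima(self):
        grid = np.linspace(-1, 1, 2001)
        prof = potential_profile(grid, 3, 3, 3, 0.0, 1.0)
        assert _count_local_minima(prof.V) == 0  # interior has none ...
        assert prof.V[0] < prof.V.min() + 1e-12 and prof.V[-1] < prof.V.min() + 1e-12

    def test_force_odd_potential_even(self):
        grid = np.linspace(-1, 1, 801)
        prof = potential_profile(grid, 5, 4, 3, 0.3, 0.7)
        assert prof.F == pytest.approx(-prof.F[::-1], abs=1e-12)
        assert prof.V == pytest.approx(prof.V[::-1], abs=1e-8)

    def test_quadrature_consistency(self):
        grid = np.linspace(-1, 1, 4001)
        prof = potential_profile(grid, 4, 3, 2, 0.4, 0.3)
        dV = np.gradient(prof.V, grid)
        assert dV[50:-50] == pytest.approx(-prof.F[50:-50], abs=1e-4)

    def test_asymmetric_grid_rejected(self):
        with pytest.raises(ValueError):
            potential_profile(np.linspace(-0.9, 1, 100), 3, 3, 3, 0.5, 0.5)


class TestMeanfieldTrajectory:
    def test_symmetry_fixed_point(self):
        traj = meanfield_trajectory(0.0, 3, 3, 3, 0.2, 1.0, t_max=50)
        assert np.all(traj[:, 1] == 0.0)

    def test_consensus_fixed_point(self):
        traj = meanfield_trajectory(1.0, 3, 3, 3, 0.0, 1.0, t_max=50)
        assert np.all(traj[:, 1] == pytest.approx(1.0, abs=1e-12))

    def test_converges_to_closed_form_root(self):
        # (1 - m^2)/(3 - m^2) = 0.1  =>  m = sqrt(7)/3
        traj = meanfield_trajectory(0.9, 3, 3, 3, 0.1, 1.0, t_max=400, dt=0.05)
        assert traj[-1, 1] == pytest.approx(math.sqrt(7) / 3, abs=1e-6)

    def test_bad_dt(self):
        with pytest.raises(ValueError):
            meanfield_trajectory(0.5, 3, 3, 3, 0.1, 1.0, t_max=1.0, dt=0.0)


class TestCriticalSurfaces:
    def test_critical_z_examples(self):
        assert critical_z(5, 5, 5) == 1.0
        z6 = critical_z(6, 6, 6)
        assert 0.0 < z6 < 1.0
        for w in (1, 5, 10):
            assert critical_z(10, 7, w) == 1.0

    def test_critical_z_boundary_is_sharp(self):
        z6 = critical_z(6, 6, 6)
        assert not is_discontinuous(6, 6, 6, z6 - 1e-4)
        assert is_discontinuous(6, 6, 6, z6 + 1e-4)

    def test_critical_r_q10(self):
        assert critical_r(10) == 8
        assert critical_r(10, require="any") == 8

    def test_critical_r_fixed_w(self):
        assert critical_r(10, w_policy="fixed", w=10) == 8

    def test_critical_r_scan_records_w_dependence(self):
        scan = critical_r_scan(10)
        assert set(scan) == set(range(6, 11))
        assert not any(scan[7].values())
        assert all(scan[8].values())

    def test_r_star_ratio_decreases_with_q(self):
        r10, r15 = critical_r(10), critical_r(15)
        assert r10 == 8 and r15 == 11
        assert r15 / 15 < r10 / 10

    def test_tricritical_examples(self):
        assert tricritical_q(1.0, 1.0, 1.0) == 6
        assert tricritical_q(1.0, 1.0, 0.0) is None

    def test_tricritical_self_consistent_with_dense_scan(self):
        got = tricritical_q(0.75, 0.75, 0.5, q_max=50)
        dense = None
        for q in range(2, 51):
            r, w = math.ceil(0.75 * q), math.ceil(0.75 * q)
            if is_discontinuous(q, r, w, 0.5):
                dense = q
                break
        assert got == dense is not None
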