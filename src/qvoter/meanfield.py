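"""Stationary-state analysis in the infinite-population limit.

The stationarity condition ``lambda_plus = lambda_minus`` is linear in the
nonconformity probability ``p``: with ``A(m) = alpha_plus - alpha_minus`` and
``C(m) = (1-z)*(beta_plus - beta_minus) + z*(gamma_plus - gamma_minus)`` the
ordered branch satisfies ``p = A/(A - C)``.

Both ``A`` and ``C`` are odd polynomials in ``m`` that vanish at ``m = 0``, so
the ``m -> 0`` limit of ``p(m)`` (the lower spinodal ``p*``) and the quadratic
coefficient ``p2`` of the expansion ``p(m) = p* + p2*m**2 + O(m**4)`` are
obtained from exact rational polynomial coefficients rather than numerical
differentiation at the removable singularity.  The sign of ``p2`` classifies
the transition: ``p2 < 0`` (``p(m)`` has a maximum at ``m = 0``) means a
continuous transition, ``p2 > 0`` a discontinuous one with an interior
maximum of ``p(m)`` acting as the upper spinodal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from typing import Optional

import numpy as np

from .rates import infinite_rates, total_rates

__all__ = [
    "DegenerateStationaryError",
    "TricriticalBoundaryError",
    "NoTransitionError",
    "MultipleSignChangesError",
    "StationaryCurve",
    "PhaseClassification",
    "PotentialProfile",
    "series_coefficients",
    "p_series",
    "p2_coefficient",
    "stationary_p",
    "stationary_curve",
    "critical_p",
    "p2_coefficient",
    "classify_transition",
    "is_discontinuous",
    "spinodals",
    "potential_profile",
    "meanfield_trajectory",
    "critical_z",
    "critical_r",
    "critical_r_scan",
    "tricritical_q",
]


class DegenerateStationaryError(ValueError):
    """A - C vanishes where a finite p(m) root was requested."""


class TricriticalBoundaryError(ValueError):
    """The quadratic coefficient p2 is exactly zero: tricritical boundary."""


class NoTransitionError(ValueError):
    """No order-disorder transition exists for these parameters."""


class MultipleSignChangesError(ValueError):
    """The coarse z-scan found more than one continuous/discontinuous boundary."""


# ---------------------------------------------------------------------------
# Exact truncated power series in m (Fraction coefficients)
#
# A(m) and C(m) are odd polynomials vanishing at m = 0, so p(m) = A/(A - C)
# is a power series in u = m**2.  Degree 7 in m (three orders in u beyond p*)
# is carried because the leading u-coefficient can vanish exactly on
# tricritical boundaries (it does at q = 5, r = w = q, z = 1, where the
# quartic term decides the type).

_DEG = 7
_HALF = Fraction(1, 2)
_ZERO = Fraction(0)
_X = (_HALF, _HALF) + (_ZERO,) * (_DEG - 1)     # x = (1+m)/2
_V = (_HALF, -_HALF) + (_ZERO,) * (_DEG - 1)    # v = (1-m)/2


def _mul(a, b):
    return tuple(sum(a[i] * b[k - i] for i in range(k + 1)) for k in range(_DEG + 1))


def _mirror(a):
    # m -> -m
    return tuple(-c if i % 2 else c for i, c in enumerate(a))


def _add(a, b):
    return tuple(ai + bi for ai, bi in zip(a, b))


def _scale(c, a):
    return tuple(c * ai for ai in a)


@lru_cache(maxsize=None)
def _tail_series(q: int, k: int):
    """Truncated series of P(Bin(q, x) >= k) with x = (1+m)/2, exact."""
    xp = [(Fraction(1),) + (_ZERO,) * _DEG]
    for _ in range(q):
        xp.append(_mul(xp[-1], _X))
    vp = [_mirror(t) for t in xp]
    out = (_ZERO,) * (_DEG + 1)
    for i in range(k, q + 1):
        out = _add(out, _scale(math.comb(q, i), _mul(xp[i], vp[q - i])))
    return out


@lru_cache(maxsize=None)
def _conformity_series(q: int, r: int):
    """Odd coefficients (a1, a3, a5, a7) of A(m) = alpha_plus - alpha_minus."""
    u = _tail_series(q, r)
    a = _add(_mul(_V, u), _scale(Fraction(-1), _mul(_X, _mirror(u))))
    assert all(a[i] == 0 for i in range(0, _DEG + 1, 2))
    return a[1::2]


@lru_cache(maxsize=None)
def _anticonformity_series(q: int, w: int):
    """Odd coefficients (b1, b3, b5, b7) of B(m) = beta_plus - beta_minus."""
    u = _tail_series(q, w)
    b = _add(_mul(_V, _mirror(u)), _scale(Fraction(-1), _mul(_X, u)))
    assert all(b[i] == 0 for i in range(0, _DEG + 1, 2))
    return b[1::2]


def series_coefficients(q: int, r: int, w: int, z):
    """Exact odd-series coefficients ((a1, a3, a5, a7), (c1, c3, c5, c7)).

    ``C = (1-z)*B + z*G`` with ``G(m) = gamma_plus - gamma_minus = -m/2``.
    ``z`` is converted to an exact ``Fraction``.
    """
    zf = Fraction(z) if not isinstance(z, Fraction) else z
    if not 0 <= zf <= 1:
        raise ValueError(f"z must lie in [0, 1], got {z!r}")
    a = _conformity_series(q, r)
    b = _anticonformity_series(q, w)
    c = tuple((1 - zf) * bk for bk in b)
    c = (c[0] - zf * _HALF,) + c[1:]
    return a, c


def p_series(q: int, r: int, w: int, z) -> tuple[Fraction, Fraction, Fraction, Fraction]:
    """Exact coefficients (p*, p2, p4, p6) of p(m) = p* + p2 m^2 + p4 m^4 + ...

    Obtained by long division of the odd series A by D = A - C in the
    variable u = m**2.
    """
    a, c = series_coefficients(q, r, w, z)
    d = tuple(ak - ck for ak, ck in zip(a, c))
    if d[0] == 0:
        raise DegenerateStationaryError("a1 == c1: p(m) has no finite limit at m=0")
    out = []
    num = list(a)
    for k in range(4):
        qk = num[k] / d[0]
        out.append(qk)
        for j in range(k, 4):
            num[j] -= qk * d[j - k]
    return tuple(out)


# ---------------------------------------------------------------------------
# Stationary relation p(m) and derived quantities


def _A_C(m, q: int, r: int, w: int, z: float):
    rr = infinite_rates(m, q, r, w)
    A = rr.alpha_plus - rr.alpha_minus
    C = (1.0 - z) * (rr.beta_plus - rr.beta_minus) + z * (rr.gamma_plus - rr.gamma_minus)
    return A, C


def stationary_p(m: float, q: int, r: int, w: int, z: float) -> float:
    """Nonconformity level p at which magnetization m is stationary.

    Solves the linear stationarity condition for ``p``; valid for ``m != 0``
    (at ``m = 0`` every ``p`` is stationary).  The returned root may fall
    outside ``[0, 1]``, in which case no physical stationary ``p`` exists at
    this ``m``.
    """
    if m == 0:
        raise ValueError("m must be nonzero: the m=0 branch is stationary for every p")
    A, C = _A_C(float(m), q, r, w, z)
    denom = A - C
    if abs(denom) < 1e-300:
        raise DegenerateStationaryError(f"A - C vanishes at m={m}: no unique stationary p")
    return A / denom


def _stationary_p_grid(ms: np.ndarray, q: int, r: int, w: int, z: float) -> np.ndarray:
    A, C = _A_C(ms, q, r, w, z)
    denom = A - C
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(np.abs(denom) > 0, A / np.where(denom == 0, np.nan, denom), np.nan)
    return p


@dataclass(frozen=True)
class StationaryCurve:
    """Physical (p in [0,1]) points of the stationary relation p(m), m > 0."""

    m: np.ndarray
    p: np.ndarray
    q: int
    r: int
    w: int
    z: float


def stationary_curve(q: int, r: int, w: int, z: float, n_points: int = 1000) -> StationaryCurve:
    ms = np.linspace(0.0, 1.0, n_points + 1)[1:]
    ps = _stationary_p_grid(ms, q, r, w, z)
    keep = np.isfinite(ps) & (ps >= 0.0) & (ps <= 1.0)
    return StationaryCurve(ms[keep], ps[keep], q, r, w, z)


def critical_p(q: int, r: int, w: int, z: float, exact: bool = False):
    """m -> 0 limit of p(m): the lower spinodal p* = a1/(a1 - c1)."""
    (a1, *_), (c1, *_) = series_coefficients(q, r, w, z)
    if a1 == c1:
        raise DegenerateStationaryError("a1 == c1: p(m) has no finite limit at m=0")
    ps = a1 / (a1 - c1)
    return ps if exact else float(ps)


def p2_coefficient(q: int, r: int, w: int, z: float) -> Fraction:
    """Exact quadratic coefficient of p(m) = p* + p2*m**2 + O(m**4)."""
    return p_series(q, r, w, z)[1]


def _leading_curvature(q: int, r: int, w: int, z) -> Fraction:
    """First nonzero coefficient among (p2, p4, p6); 0 if all three vanish."""
    for coeff in p_series(q, r, w, z)[1:]:
        if coeff != 0:
            return coeff
    return Fraction(0)


@dataclass(frozen=True)
class PhaseClassification:
    """Transition type plus the spinodal pair (p_star = lower, p_upper = upper)."""

    transition_type: str          # "continuous" | "discontinuous"
    p_star: float
    p_upper: float
    p2: float

    @property
    def spinodal_gap(self) -> float:
        return self.p_upper - self.p_star


def _golden_max(f, lo: float, hi: float, tol: float = 1e-8) -> float:
    """Golden-section maximizer; returns the abscissa of the maximum."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return 0.5 * (a + b)


def _p_upper(q: int, r: int, w: int, z: float, n_grid: int = 2001) -> float:
    """Maximum of the physical stationary p(m) over m in (0, 1]."""
    ms = np.linspace(0.0, 1.0, n_grid + 1)[1:]
    ps = _stationary_p_grid(ms, q, r, w, z)
    ok = np.isfinite(ps) & (ps >= 0.0) & (ps <= 1.0)
    if not ok.any():
        raise NoTransitionError("no physical stationary branch found on (0, 1]")
    psm = np.where(ok, ps, -np.inf)
    i = int(np.argmax(psm))
    lo = ms[max(i - 1, 0)]
    hi = ms[min(i + 1, len(ms) - 1)]

    def f(m):
        try:
            val = stationary_p(m, q, r, w, z)
        except DegenerateStationaryError:
            return -math.inf
        return val if 0.0 <= val <= 1.0 else -math.inf

    m_best = _golden_max(f, lo, hi)
    return max(f(m_best), float(psm[i]))


def classify_transition(q: int, r: int, w: int, z: float) -> PhaseClassification:
    """Classify the order-disorder transition via the sign of p2.

    The leading curvature is the first nonzero coefficient among
    (p2, p4, p6): negative (maximum of p(m) at m=0) means continuous, with
    both spinodals equal to p*; positive means discontinuous, with p_upper
    the interior maximum of p(m).
    """
    (a1, *_), (c1, *_) = series_coefficients(q, r, w, z)
    if a1 <= 0:
        raise NoTransitionError(
            f"a1 = {a1} <= 0: conformity does not order the m=0 state, "
            "no order-disorder transition"
        )
    p_star = critical_p(q, r, w, z)
    if not 0.0 < p_star < 1.0:
        raise NoTransitionError(f"p* = {p_star} outside (0, 1): no transition in the physical range")
    curv = _leading_curvature(q, r, w, z)
    if curv == 0:
        raise TricriticalBoundaryError(
            f"p2 = p4 = p6 = 0 at (q={q}, r={r}, w={w}, z={z}): at tricritical boundary"
        )
    if curv < 0:
        return PhaseClassification("continuous", p_star, p_star, float(p2_coefficient(q, r, w, z)))
    return PhaseClassification("discontinuous", p_star, _p_upper(q, r, w, z),
                               float(p2_coefficient(q, r, w, z)))


def is_discontinuous(q: int, r: int, w: int, z) -> bool:
    """True iff a discontinuous order-disorder transition occurs at these parameters.

    Requires an ordering linear coefficient (a1 > 0), a physical critical
    point p* in (0, 1), and a positive leading curvature of p(m) at m = 0 —
    all decided in exact rational arithmetic.
    """
    (a1, *_), (c1, *_) = series_coefficients(q, r, w, z)
    d1 = a1 - c1
    if a1 <= 0 or d1 == 0:
        return False
    p_star = a1 / d1
    if not 0 < p_star < 1:
        return False
    return _leading_curvature(q, r, w, z) > 0


def spinodals(q: int, r: int, w: int, z: float) -> tuple[float, float]:
    """(p_lower, p_upper): stability limits of the disordered / ordered phase."""
    cls = classify_transition(q, r, w, z)
    return cls.p_star, cls.p_upper


# ---------------------------------------------------------------------------
# Effective force / potential and deterministic dynamics


@dataclass(frozen=True)
class PotentialProfile:
    m: np.ndarray
    F: np.ndarray   # effective force lambda_plus - lambda_minus
    V: np.ndarray   # potential, -integral of F, anchored V(0) = 0


def effective_force(m, q: int, r: int, w: int, p: float, z: float):
    """Drift F(m) = lambda_plus - lambda_minus; scalar or ndarray m."""
    rr = infinite_rates(m, q, r, w)
    tr = total_rates(rr, p, z)
    return tr.lambda_plus - tr.lambda_minus


def potential_profile(m_grid, q: int, r: int, w: int, p: float, z: float) -> PotentialProfile:
    """Effective force and potential on a symmetric grid over [-1, 1].

    V is obtained by trapezoidal quadrature of -F and anchored at V(0) = 0;
    local minima of V are the stable roots of F.
    """
    m = np.asarray(m_grid, dtype=float)
    if m.ndim != 1 or len(m) < 3:
        raise ValueError("m_grid must be a 1-d grid with at least 3 points")
    if not np.allclose(m, -m[::-1], atol=1e-12):
        raise ValueError("m_grid must be symmetric about 0")
    F = effective_force(m, q, r, w, p, z)
    from scipy.integrate import cumulative_trapezoid

    V = np.concatenate([[0.0], cumulative_trapezoid(-F, m)])
    V = V - np.interp(0.0, m, V)
    return PotentialProfile(m, F, V)


def meanfield_trajectory(
    m0: float, q: int, r: int, w: int, p: float, z: float,
    t_max: float, dt: float = 0.01,
) -> np.ndarray:
    """Deterministic evolution dm/dt = 2*F(m) (time in Monte Carlo steps).

    One MCS is N elementary updates, each shifting m by ±2/N with
    probabilities lambda_plus / lambda_minus, so the expected drift per MCS
    is 2*(lambda_plus - lambda_minus).  Fixed-step RK4; returns an array of
    (t, m) rows.
    """
    if abs(m0) > 1:
        raise ValueError(f"|m0| must be <= 1, got {m0!r}")
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt!r}")

    def rhs(m):
        m = min(1.0, max(-1.0, m))
        return 2.0 * effective_force(m, q, r, w, p, z)

    n_steps = int(round(t_max / dt))
    out = np.empty((n_steps + 1, 2))
    t, m = 0.0, float(m0)
    out[0] = (t, m)
    for i in range(1, n_steps + 1):
        k1 = rhs(m)
        k2 = rhs(m + 0.5 * dt * k1)
        k3 = rhs(m + 0.5 * dt * k2)
        k4 = rhs(m + dt * k3)
        m = m + dt * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
        m = min(1.0, max(-1.0, m))
        t = i * dt
        out[i] = (t, m)
    return out


# ---------------------------------------------------------------------------
# Critical surfaces in (z, r, q)


def critical_z(q: int, r: int, w: int, dz: float = 0.02, tol: float = 1e-6) -> float:
    """Boundary z* between continuous (z < z*) and discontinuous (z > z*) regimes.

    Returns 1.0 when the transition is continuous (or absent) for every z in
    [0, 1] and 0.0 when it is discontinuous for every z.  A coarse scan at
    spacing ``dz`` must find a single boundary, which is then bisected to
    ``tol``; multiple sign changes raise :class:`MultipleSignChangesError`.
    """
    n = int(round(1 / dz))
    zs = [Fraction(k, n) for k in range(n + 1)]
    flags = [is_discontinuous(q, r, w, z) for z in zs]
    if not any(flags):
        return 1.0
    if all(flags):
        return 0.0
    changes = [i for i in range(n) if flags[i] != flags[i + 1]]
    if len(changes) > 1:
        raise MultipleSignChangesError(
            f"coarse z-scan found {len(changes)} boundaries at (q={q}, r={r}, w={w}); "
            "refusing to bisect"
        )
    i = changes[0]
    lo, hi = float(zs[i]), float(zs[i + 1])
    lo_disc = flags[i]
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if is_discontinuous(q, r, w, mid) == lo_disc:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _has_discontinuity_over_z(q: int, r: int, w: int, dz: float = 0.02) -> bool:
    n = int(round(1 / dz))
    return any(is_discontinuous(q, r, w, Fraction(k, n)) for k in range(n + 1))


def critical_r_scan(q: int, dz: float = 0.02) -> dict[int, dict[int, bool]]:
    """Per-(r, w) map of whether any z in [0, 1] yields a discontinuous transition.

    Majority thresholds only: r runs over (q/2, q], w over 1..q.
    """
    return {
        r: {w: _has_discontinuity_over_z(q, r, w, dz) for w in range(1, q + 1)}
        for r in range(q // 2 + 1, q + 1)
    }


def critical_r(q: int, w_policy: str = "scan_all", w: Optional[int] = None,
               require: str = "all", dz: float = 0.02) -> int:
    """Smallest majority conformity threshold r at which discontinuity becomes possible.

    r is scanned over the majority range (q/2, q] — r* answers "what share of
    the panel must oppose the target", so sub-majority thresholds are outside
    its definition (isolated discontinuous pockets do exist at small r, e.g.
    q=15, r=6).  For each candidate r the z-range [0, 1] is scanned; with
    ``w_policy="scan_all"`` the anticonformity threshold w runs over 1..q and
    ``require`` chooses whether *every* (default) or *any* w must admit a
    discontinuous transition.  The two requirements coincide for q = 10 and
    q = 15; at q = 50 a narrow pocket of discontinuity near w = q/2 makes
    "any" return 29 while "all" returns 30.  ``w_policy="fixed"`` tests the
    single given w.
    """
    if q < 2:
        raise ValueError(f"q must be >= 2, got {q}")
    if w_policy == "fixed":
        if w is None:
            raise ValueError("w_policy='fixed' requires w")
        ws = [w]
    elif w_policy == "scan_all":
        ws = list(range(1, q + 1))
    else:
        raise ValueError(f"unknown w_policy {w_policy!r}")
    agg = any if require == "any" else all
    for r in range(q // 2 + 1, q + 1):
        if agg(_has_discontinuity_over_z(q, r, wi, dz) for wi in ws):
            return r
    raise NoTransitionError(f"no discontinuous transition found for any majority r <= q = {q}")


def tricritical_q(a_r: float, a_w: float, z: float, q_max: int = 50) -> Optional[int]:
    """Smallest panel size q in [2, q_max] with a discontinuous transition.

    Thresholds follow the ceiling convention r = ceil(a_r*q), w = ceil(a_w*q).
    Returns None when every q in range classifies continuous.
    """
    from .model_core import threshold_count

    for q in range(2, q_max + 1):
        if is_discontinuous(q, threshold_count(a_r, q), threshold_count(a_w, q), z):
            return q
    return None
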