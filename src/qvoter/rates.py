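"""Exact per-step transition probabilities for the aggregated state.

Six response-resolved rates are tracked: conformity-driven up/down flips
(``alpha_plus``/``alpha_minus``), anticonformity-driven (``beta_plus``/
``beta_minus``) and independence-driven (``gamma_plus``/``gamma_minus``).
They are combined with the response-kind probabilities ``(1-p, p(1-z), pz)``
into the aggregated one-step rates ``lambda_plus``/``lambda_minus``/
``lambda_zero``.

The finite-N forms are hypergeometric (a panel of ``q`` agents drawn without
replacement from the ``N-1`` non-target agents) and are evaluated in exact
rational arithmetic; the infinite-N forms are binomial tails in
``x = (1+m)/2`` and ``v = (1-m)/2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

__all__ = [
    "ResponseRates",
    "TransitionRates",
    "binom_tail",
    "infinite_rates",
    "finite_rates",
    "finite_rates_exact",
    "total_rates",
]


@dataclass(frozen=True)
class ResponseRates:
    """The six response-resolved flip probabilities at one state."""

    alpha_plus: float
    alpha_minus: float
    beta_plus: float
    beta_minus: float
    gamma_plus: float
    gamma_minus: float

    FIELDS = ("alpha_plus", "alpha_minus", "beta_plus", "beta_minus",
              "gamma_plus", "gamma_minus")

    def as_tuple(self) -> tuple[float, ...]:
        return (self.alpha_plus, self.alpha_minus, self.beta_plus,
                self.beta_minus, self.gamma_plus, self.gamma_minus)


@dataclass(frozen=True)
class TransitionRates:
    """Aggregated probabilities of an up-flip, a down-flip, or no change."""

    lambda_plus: float
    lambda_minus: float
    lambda_zero: float


def binom_tail(k: int, q: int, s):
    """P(Bin(q, s) >= k), by direct summation of the q+1 pmf terms.

    ``s`` may be a scalar or an ndarray; the result matches its shape.
    Exact-rational inputs (``Fraction``) are summed exactly.
    """
    if k <= 0:
        return np.ones_like(s) if isinstance(s, np.ndarray) else type(s)(1) if isinstance(s, Fraction) else 1.0
    if k > q:
        return np.zeros_like(s) if isinstance(s, np.ndarray) else type(s)(0) if isinstance(s, Fraction) else 0.0
    one = Fraction(1) if isinstance(s, Fraction) else 1.0
    total = 0 * s
    for i in range(k, q + 1):
        total = total + math.comb(q, i) * s ** i * (one - s) ** (q - i)
    return total


def infinite_rates(m, q: int, r: int, w: int) -> ResponseRates:
    """Response rates in the infinite-population (mean-field) limit.

    With ``x = (1+m)/2`` (up fraction) and ``v = (1-m)/2``:

    * ``alpha_plus  = v * P(Bin(q, x) >= r)`` — a down target meets >= r ups,
    * ``alpha_minus = x * P(Bin(q, v) >= r)``,
    * ``beta_plus   = v * P(Bin(q, v) >= w)`` — a down target meets >= w downs,
    * ``beta_minus  = x * P(Bin(q, x) >= w)``,
    * ``gamma_plus  = v/2``, ``gamma_minus = x/2``.

    ``m`` may be a float or an ndarray (all six fields then hold arrays).
    """
    m_arr = np.asarray(m, dtype=float)
    if np.any(np.abs(m_arr) > 1 + 1e-12):
        raise ValueError(f"magnetization must lie in [-1, 1], got {m!r}")
    x = (1.0 + m_arr) / 2.0
    v = (1.0 - m_arr) / 2.0
    rr = ResponseRates(
        alpha_plus=v * binom_tail(r, q, x),
        alpha_minus=x * binom_tail(r, q, v),
        beta_plus=v * binom_tail(w, q, v),
        beta_minus=x * binom_tail(w, q, x),
        gamma_plus=v / 2.0,
        gamma_minus=x / 2.0,
    )
    if np.isscalar(m) or (isinstance(m, np.ndarray) and m.ndim == 0):
        rr = ResponseRates(*(float(f) for f in rr.as_tuple()))
    return rr


def _hyperg_tail(k: int, q: int, good: int, bad: int) -> Fraction:
    """P(#good in a size-q draw without replacement >= k), exact.

    The urn holds ``good + bad`` items; requires ``good + bad >= q``.
    """
    total = good + bad
    denom = math.comb(total, q)
    num = sum(math.comb(good, i) * math.comb(bad, q - i) for i in range(k, q + 1))
    return Fraction(num, denom)


def finite_rates_exact(n_up: int, N: int, q: int, r: int, w: int) -> dict[str, Fraction]:
    """Exact-rational finite-N response rates; see :func:`finite_rates`."""
    if not 0 <= n_up <= N:
        raise ValueError(f"n_up={n_up} out of range [0, {N}]")
    if q > N - 1:
        raise ValueError(f"q={q} exceeds N-1={N - 1}: cannot draw the panel without replacement")
    n_down = N - n_up
    # Panel populations exclude the target agent.
    return {
        "alpha_plus": Fraction(n_down, N) * _hyperg_tail(r, q, n_up, n_down - 1) if n_down else Fraction(0),
        "alpha_minus": Fraction(n_up, N) * _hyperg_tail(r, q, n_down, n_up - 1) if n_up else Fraction(0),
        "beta_plus": Fraction(n_down, N) * _hyperg_tail(w, q, n_down - 1, n_up) if n_down else Fraction(0),
        "beta_minus": Fraction(n_up, N) * _hyperg_tail(w, q, n_up - 1, n_down) if n_up else Fraction(0),
        "gamma_plus": Fraction(n_down, 2 * N),
        "gamma_minus": Fraction(n_up, 2 * N),
    }


def finite_rates(n_up: int, N: int, q: int, r: int, w: int) -> ResponseRates:
    """Response rates for a finite population of N agents.

    The target is uniform over the N agents; the panel of ``q`` is drawn
    uniformly without replacement from the remaining ``N - 1``.  E.g.
    ``alpha_plus = (N_down/N) * P(H >= r)`` with ``H`` hypergeometric over the
    ``n_up`` up and ``n_down - 1`` down non-target agents.  Converges to
    :func:`infinite_rates` at fixed ``m = 2*n_up/N - 1`` as ``N`` grows.
    """
    exact = finite_rates_exact(n_up, N, q, r, w)
    return ResponseRates(**{k: float(val) for k, val in exact.items()})


def total_rates(rr: ResponseRates, p: float, z: float) -> TransitionRates:
    """Aggregate response rates with kind probabilities (1-p, p(1-z), pz)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p!r}")
    if not 0.0 <= z <= 1.0:
        raise ValueError(f"z must lie in [0, 1], got {z!r}")
    lam_plus = (1.0 - p) * rr.alpha_plus + p * (1.0 - z) * rr.beta_plus + p * z * rr.gamma_plus
    lam_minus = (1.0 - p) * rr.alpha_minus + p * (1.0 - z) * rr.beta_minus + p * z * rr.gamma_minus
    return TransitionRates(lam_plus, lam_minus, 1.0 - lam_plus - lam_minus)
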