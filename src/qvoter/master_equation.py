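"""Exact finite-N treatment: the birth-death Markov chain on n_up.

On the complete graph the aggregate count ``n_up`` of up-opinions is a
sufficient state description, and one elementary update moves it by at most
one.  The chain is reversible, so its stationary distribution has the
product form ``pi(n+1)/pi(n) = lambda_plus(n)/lambda_minus(n+1)``, computed
in log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model_core import ModelParams, magnetization
from .rates import finite_rates, total_rates

__all__ = [
    "ReducibleChainError",
    "ChainSpec",
    "StateDistribution",
    "build_chain",
    "stationary_distribution",
    "evolve_distribution",
    "absorption_probabilities",
]


class ReducibleChainError(ValueError):
    """The chain has absorbing states; no unique stationary distribution."""

    def __init__(self, absorbing: list[int]):
        self.absorbing = absorbing
        super().__init__(
            f"no unique stationary distribution: chain is reducible, "
            f"absorbing/unreachable boundary at states {absorbing}"
        )


@dataclass(frozen=True)
class ChainSpec:
    """Per-state one-step rates of the birth-death chain on n_up in 0..N."""

    N: int
    params: ModelParams
    lambda_plus: np.ndarray    # length N+1; lambda_plus[N] == 0
    lambda_minus: np.ndarray   # lambda_minus[0] == 0
    lambda_zero: np.ndarray

    @property
    def m_values(self) -> np.ndarray:
        return (2 * np.arange(self.N + 1) - self.N) / self.N

    def transition_matrix(self) -> np.ndarray:
        """Dense (N+1)x(N+1) one-elementary-step stochastic matrix P[i, j]."""
        n = self.N + 1
        P = np.zeros((n, n))
        idx = np.arange(n)
        P[idx, idx] = self.lambda_zero
        P[idx[:-1], idx[:-1] + 1] = self.lambda_plus[:-1]
        P[idx[1:], idx[1:] - 1] = self.lambda_minus[1:]
        return P


@dataclass
class StateDistribution:
    """Probability vector over n_up = 0..N, with a time stamp in MCS."""

    probs: np.ndarray
    time_mcs: float = 0.0

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if np.any(self.probs < -1e-15):
            raise ValueError("probabilities must be nonnegative")
        total = self.probs.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1, got {total}")

    @property
    def N(self) -> int:
        return len(self.probs) - 1

    def mean_abs_m(self) -> float:
        m = (2 * np.arange(self.N + 1) - self.N) / self.N
        return float(np.abs(m) @ self.probs)


def build_chain(params: ModelParams) -> ChainSpec:
    """Tabulate the aggregated rates lambda±(n), lambda0(n) for n = 0..N."""
    if not params.is_finite:
        raise ValueError("build_chain requires finite N")
    N = params.N
    lp = np.empty(N + 1)
    lm = np.empty(N + 1)
    for n in range(N + 1):
        rr = finite_rates(n, N, params.q, params.r, params.w)
        tr = total_rates(rr, params.p, params.z)
        lp[n], lm[n] = tr.lambda_plus, tr.lambda_minus
    return ChainSpec(N, params, lp, lm, 1.0 - lp - lm)


def _check_irreducible(chain: ChainSpec):
    lp, lm, N = chain.lambda_plus, chain.lambda_minus, chain.N
    blocked = ([n for n in range(N) if lp[n] == 0.0]
               + [n for n in range(1, N + 1) if lm[n] == 0.0])
    if blocked:
        absorbing = [n for n in range(N + 1)
                     if (n == N or lp[n] == 0.0) and (n == 0 or lm[n] == 0.0)]
        raise ReducibleChainError(absorbing or sorted(set(blocked)))


def stationary_distribution(chain: ChainSpec) -> StateDistribution:
    """Exact stationary distribution via the detailed-balance product form.

    ``log pi(n+1) = log pi(n) + log lambda_plus(n) - log lambda_minus(n+1)``,
    normalized with a log-sum-exp.  Raises :class:`ReducibleChainError` when a
    flip channel is closed (e.g. pure conformity, consensus absorbing).
    """
    _check_irreducible(chain)
    N = chain.N
    log_pi = np.zeros(N + 1)
    for n in range(N):
        log_pi[n + 1] = log_pi[n] + math.log(chain.lambda_plus[n]) - math.log(chain.lambda_minus[n + 1])
    log_pi -= log_pi.max()
    pi = np.exp(log_pi)
    pi /= pi.sum()
    return StateDistribution(pi, time_mcs=math.inf)


def evolve_distribution(chain: ChainSpec, P0: StateDistribution, t_mcs: float) -> StateDistribution:
    """Push a distribution forward by t_mcs Monte Carlo steps (N·t elementary steps)."""
    if t_mcs < 0:
        raise ValueError(f"t must be >= 0, got {t_mcs}")
    n_steps = int(round(t_mcs * chain.N))
    probs = P0.probs.copy()
    lp, lm, lz = chain.lambda_plus, chain.lambda_minus, chain.lambda_zero
    for _ in range(n_steps):
        new = probs * lz
        new[1:] += probs[:-1] * lp[:-1]
        new[:-1] += probs[1:] * lm[1:]
        probs = new / new.sum()   # renormalize away accumulated rounding
    return StateDistribution(probs, time_mcs=P0.time_mcs + n_steps / chain.N)


def absorption_probabilities(chain: ChainSpec) -> np.ndarray:
    """P(absorb at n = N | start at n) for a chain absorbing at both ends.

    First-step analysis of the gambler's-ruin type: with
    ``rho(n) = lambda_minus(n)/lambda_plus(n)`` the hitting probability is
    ``h(n) = S(n)/S(N)`` where ``S(n) = sum_{k<n} prod_{j<=k} rho(j)``.
    Only meaningful when the interior flip channels are open and the
    boundaries are absorbing (e.g. p = 0).
    """
    N = chain.N
    if chain.lambda_plus[0] != 0.0 or chain.lambda_minus[N] != 0.0:
        raise ValueError("boundaries are not absorbing")
    interior_blocked = [n for n in range(1, N) if chain.lambda_plus[n] == 0.0 or chain.lambda_minus[n] == 0.0]
    if interior_blocked:
        raise ValueError(f"interior states {interior_blocked} block transitions; first-step analysis invalid")
    log_rho = np.array([
        math.log(chain.lambda_minus[n]) - math.log(chain.lambda_plus[n]) for n in range(1, N)
    ])
    log_terms = np.concatenate([[0.0], np.cumsum(log_rho)])  # prod over j<=k, k=0..N-1 (empty=1)
    mx = log_terms.max()
    terms = np.exp(log_terms - mx)
    S = np.concatenate([[0.0], np.cumsum(terms)])
    return S / S[-1]
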