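"""Agent-based stochastic simulation on the complete graph.

Random sequential updating: each elementary step picks a uniform target,
draws a response kind with probabilities (1-p, p(1-z), pz), and — for
conformity or anticonformity — a panel of q distinct non-target agents
without replacement.  N elementary steps make one Monte Carlo step (MCS).

Two engines sample the identical micro-process:

* ``"fast"`` (default) — a numba-compiled kernel over the explicit opinion
  array, single RNG stream seeded from the config seed;
* ``"reference"`` — pure Python built on :func:`step`, with independent
  named substreams (target / kind / panel / coin) spawned from the seed.

Neither engine consults the analytic rates module, so simulations provide an
independent check of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from .model_core import Configuration, ModelParams, ResponseKind, apply_response

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "step",
    "run_simulation",
    "estimate_order_parameter",
]


@dataclass(frozen=True)
class SimulationConfig:
    params: ModelParams
    m0: float
    duration_mcs: int
    seed: int
    burn_in_mcs: Optional[int] = None   # default: 20% of duration
    thinning_mcs: int = 1
    engine: str = "fast"

    def __post_init__(self):
        if not self.params.is_finite:
            raise ValueError("simulation requires finite N")
        N = self.params.N
        n_up = (self.m0 + 1.0) * N / 2.0
        if abs(n_up - round(n_up)) > 1e-9 or not -1.0 <= self.m0 <= 1.0:
            raise ValueError(
                f"m0={self.m0} is not realizable for N={N}: N*m0 must have the parity of N "
                f"(m = (2*n_up - N)/N for integer n_up)"
            )
        burn = self.burn_in
        if not 0 <= burn < self.duration_mcs:
            raise ValueError(f"need duration > burn_in >= 0, got {self.duration_mcs} and {burn}")
        if self.thinning_mcs < 1:
            raise ValueError("thinning interval must be >= 1 MCS")
        if self.engine not in ("fast", "reference"):
            raise ValueError(f"unknown engine {self.engine!r}")

    @property
    def burn_in(self) -> int:
        return self.burn_in_mcs if self.burn_in_mcs is not None else self.duration_mcs // 5

    @property
    def n_up0(self) -> int:
        return int(round((self.m0 + 1.0) * self.params.N / 2.0))


@dataclass
class Trajectory:
    """Sampled (t, m) series after burn-in, plus the full config echo."""

    times_mcs: np.ndarray
    m: np.ndarray
    config: SimulationConfig

    @property
    def n_up(self) -> np.ndarray:
        N = self.config.params.N
        return np.rint((self.m * N + N) / 2.0).astype(np.int64)


def _substreams(seed: int):
    ss = np.random.SeedSequence(seed)
    names = ("target", "kind", "panel", "coin")
    return dict(zip(names, (np.random.default_rng(s) for s in ss.spawn(len(names)))))


def step(config: Configuration, params: ModelParams, rng,
         rng_kind=None, rng_panel=None, rng_coin=None) -> Configuration:
    """One elementary update, in place; returns the configuration.

    ``rng`` draws the target; the optional extra generators draw the response
    kind, the panel and the independence coin (all default to ``rng``).
    """
    rng_kind = rng_kind or rng
    rng_panel = rng_panel or rng
    rng_coin = rng_coin or rng
    N = config.N
    tgt = int(rng.integers(N))
    u = rng_kind.random()
    if u < 1.0 - params.p:
        kind = ResponseKind.CONFORMITY
    elif u < 1.0 - params.p * params.z:
        kind = ResponseKind.ANTICONFORMITY
    else:
        kind = ResponseKind.INDEPENDENCE
    if kind is ResponseKind.INDEPENDENCE:
        panel = ()
        coin = rng_coin.random()
    else:
        others = np.delete(np.arange(N), tgt)
        idx = rng_panel.choice(others, size=params.q, replace=False)
        panel = tuple(config.opinions[i] for i in idx)
        coin = 0.0
    config.opinions[tgt] = apply_response(
        config.opinions[tgt], panel, kind, params.r, params.w, coin
    )
    return config


@njit(cache=False)
def _kernel(opinions, q, r, w, p, z, n_mcs, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    N = opinions.size
    panel = np.empty(q, dtype=np.int64)
    m_series = np.empty(n_mcs + 1)
    n_up = 0
    for i in range(N):
        if opinions[i] == 1:
            n_up += 1
    m_series[0] = (2.0 * n_up - N) / N
    for t in range(n_mcs):
        for _ in range(N):
            tgt = np.random.randint(0, N)
            s = opinions[tgt]
            u = np.random.random()
            if u >= 1.0 - p * z:  # independence
                new = 1 if np.random.random() < 0.5 else -1
            else:
                k = 0
                while k < q:  # q distinct non-target agents, by rejection
                    j = np.random.randint(0, N)
                    if j == tgt:
                        continue
                    dup = False
                    for l in range(k):
                        if panel[l] == j:
                            dup = True
                            break
                    if dup:
                        continue
                    panel[k] = j
                    k += 1
                n_opp = 0
                for l in range(q):
                    if opinions[panel[l]] != s:
                        n_opp += 1
                if u < 1.0 - p:  # conformity
                    new = -s if n_opp >= r else s
                else:            # anticonformity
                    new = -s if q - n_opp >= w else s
            if new != s:
                opinions[tgt] = new
                n_up += new
        m_series[t + 1] = (2.0 * n_up - N) / N
    return m_series


def run_simulation(config: SimulationConfig) -> Trajectory:
    """Run the simulation; deterministic given the seed.

    The magnetization is recorded once per MCS; samples after the burn-in are
    kept at the thinning interval.
    """
    params = config.params
    N = params.N
    if config.engine == "fast":
        opinions = np.empty(N, dtype=np.int8)
        opinions[: config.n_up0] = 1
        opinions[config.n_up0:] = -1
        # Shuffle so panels are not biased by the block layout (exchangeable
        # anyway on the complete graph, but cheap and safer).
        np.random.default_rng(config.seed).shuffle(opinions)
        m_series = _kernel(
            opinions, params.q, params.r, params.w, float(params.p), float(params.z),
            int(config.duration_mcs), int(config.seed) % (2**32),
        )
    else:
        streams = _substreams(config.seed)
        conf = Configuration.from_counts(config.n_up0, N)
        m_series = np.empty(config.duration_mcs + 1)
        m_series[0] = conf.m
        for t in range(config.duration_mcs):
            for _ in range(N):
                step(conf, params, streams["target"], streams["kind"],
                     streams["panel"], streams["coin"])
            m_series[t + 1] = conf.m
    times = np.arange(config.duration_mcs + 1, dtype=float)
    keep = times >= config.burn_in
    times, m_series = times[keep], m_series[keep]
    thin = slice(None, None, config.thinning_mcs)
    return Trajectory(times[thin], m_series[thin], config)


def estimate_order_parameter(trajectory: Trajectory, burn_in_mcs: Optional[float] = None,
                             n_batches: int = 20) -> tuple[float, float]:
    """Batch-means estimate of <|m|> with an autocorrelation-aware standard error.

    Samples are split into ``n_batches`` contiguous batches (>= 20); the
    standard error is the standard deviation of batch means over sqrt(B).
    """
    m = trajectory.m
    if burn_in_mcs is not None:
        m = m[trajectory.times_mcs >= burn_in_mcs]
    if n_batches < 20:
        raise ValueError("need at least 20 batches for a stable error estimate")
    if len(m) < n_batches:
        raise ValueError(f"too few post-burn-in samples ({len(m)}) for {n_batches} batches")
    abs_m = np.abs(m)
    usable = (len(abs_m) // n_batches) * n_batches
    batches = abs_m[:usable].reshape(n_batches, -1).mean(axis=1)
    mean = float(abs_m.mean())
    se = float(batches.std(ddof=1) / np.sqrt(n_batches))
    return mean, se
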