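"""Core parameter and state types plus the microscopic single-agent update rules.

Opinions are spins ``+1``/``-1``.  A randomly chosen target agent responds to a
panel of ``q`` peers in one of three ways: *conformity* (adopt the opposing
opinion if at least ``r`` panelists hold it), *anticonformity* (flip away from
a group of at least ``w`` panelists sharing the target's current opinion), or
*independence* (re-draw the opinion at random with flip probability ``f = 1/2``).
A target that already agrees with the panel simply keeps its opinion
(uniformity/congruence).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = [
    "ParameterError",
    "ResponseKind",
    "ModelParams",
    "Configuration",
    "magnetization",
    "threshold_count",
    "apply_response",
]


class ParameterError(ValueError):
    """Invalid model parameter; carries the offending field name."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


class ResponseKind(enum.Enum):
    """The three state-changing social responses.

    Uniformity/congruence (already agreeing with the group) is implicit:
    it is the "no change" outcome of a conformity or anticonformity draw
    whose threshold is not met.
    """

    CONFORMITY = "conformity"
    ANTICONFORMITY = "anticonformity"
    INDEPENDENCE = "independence"


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set of the model.

    Parameters
    ----------
    q : int
        Size of the influence panel (positive).
    r : int
        Conformity threshold: at least ``r`` of the ``q`` panelists must hold
        the opinion opposite to the target's for conformity to act.
    w : int
        Anticonformity threshold: at least ``w`` panelists must share the
        target's current opinion for anticonformity to act.
    p : float
        Probability of nonconformity, in [0, 1].
    z : float
        Conditional probability of independence given nonconformity, in [0, 1];
        anticonformity has conditional probability ``1 - z``.
    N : int or None
        Population size for finite systems; ``None`` marks the infinite
        (mean-field) system.
    f : float
        Independence flip probability, fixed at 1/2.
    """

    q: int
    r: int
    w: int
    p: float
    z: float
    N: Optional[int] = None
    f: float = 0.5

    def __post_init__(self):
        if not isinstance(self.q, int) or self.q < 1:
            raise ParameterError("q", f"panel size must be a positive integer, got {self.q!r}")
        if not isinstance(self.r, int) or not 1 <= self.r <= self.q:
            raise ParameterError("r", f"conformity threshold must satisfy 1 <= r <= q={self.q}, got {self.r!r}")
        if not isinstance(self.w, int) or not 1 <= self.w <= self.q:
            raise ParameterError("w", f"anticonformity threshold must satisfy 1 <= w <= q={self.q}, got {self.w!r}")
        if not 0.0 <= self.p <= 1.0:
            raise ParameterError("p", f"nonconformity probability must lie in [0, 1], got {self.p!r}")
        if not 0.0 <= self.z <= 1.0:
            raise ParameterError("z", f"independence fraction must lie in [0, 1], got {self.z!r}")
        if self.N is not None:
            if not isinstance(self.N, int) or self.N < 1:
                raise ParameterError("N", f"population size must be a positive integer or None, got {self.N!r}")
            if self.q > self.N - 1:
                raise ParameterError(
                    "q",
                    f"panel is drawn without replacement from the other agents, so q <= N-1 "
                    f"is required (q={self.q}, N={self.N})",
                )
        if self.f != 0.5:
            raise ParameterError("f", f"independence flip probability is fixed at 1/2, got {self.f!r}")

    @property
    def is_finite(self) -> bool:
        return self.N is not None

    def response_probabilities(self) -> dict[ResponseKind, float]:
        """Probabilities (1-p, p(1-z), pz) of the three response kinds."""
        return {
            ResponseKind.CONFORMITY: 1.0 - self.p,
            ResponseKind.ANTICONFORMITY: self.p * (1.0 - self.z),
            ResponseKind.INDEPENDENCE: self.p * self.z,
        }


@dataclass
class Configuration:
    """A microscopic state: one ±1 opinion per agent."""

    opinions: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.opinions = list(self.opinions)
        bad = [s for s in self.opinions if s not in (+1, -1)]
        if bad:
            raise ValueError(f"opinions must be +1 or -1, got {bad[0]!r}")

    @classmethod
    def from_counts(cls, n_up: int, N: int) -> "Configuration":
        if not 0 <= n_up <= N:
            raise ValueError(f"n_up={n_up} out of range [0, {N}]")
        return cls([+1] * n_up + [-1] * (N - n_up))

    @property
    def N(self) -> int:
        return len(self.opinions)

    @property
    def n_up(self) -> int:
        return sum(1 for s in self.opinions if s == +1)

    @property
    def n_down(self) -> int:
        return self.N - self.n_up

    @property
    def m(self) -> float:
        return magnetization(self.n_up, self.N)


def magnetization(n_up: int, N: int) -> float:
    """Order parameter m = (N_up - N_down)/N = (2*n_up - N)/N."""
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    if not 0 <= n_up <= N:
        raise ValueError(f"n_up={n_up} out of range [0, {N}]")
    return (2 * n_up - N) / N


def threshold_count(a: float, q: int) -> int:
    """Integer threshold ceil(a*q) for a fractional majority a of a panel of q.

    Raises on ``a <= 0`` or ``a > 1``; the result always lies in ``[1, q]``.
    """
    if q < 1:
        raise ValueError(f"q must be >= 1, got {q}")
    if not 0.0 < a <= 1.0:
        raise ValueError(f"threshold fraction must lie in (0, 1], got {a!r}")
    return math.ceil(a * q)


def apply_response(
    target_opinion: int,
    panel: Sequence[int],
    kind: ResponseKind,
    r: int,
    w: int,
    u: float,
) -> int:
    """Resolve one elementary social response; returns the target's new opinion.

    conformity
        Flip to the opinion opposite the target's if at least ``r`` panelists
        hold it; otherwise keep the current opinion (uniformity/congruence).
        Only the opposing opinion is tested, so the rule is single-valued even
        for ``r <= q/2``; a half-half split with ``r = q/2`` flips the target.
    anticonformity
        Flip if at least ``w`` panelists share the target's *current* opinion.
    independence
        Ignore the panel; return ``+1`` if ``u < 1/2`` else ``-1``.
    """
    if target_opinion not in (+1, -1):
        raise ValueError(f"target_opinion must be +1 or -1, got {target_opinion!r}")
    if kind is ResponseKind.INDEPENDENCE:
        return +1 if u < 0.5 else -1
    n_opposite = sum(1 for s in panel if s == -target_opinion)
    if kind is ResponseKind.CONFORMITY:
        return -target_opinion if n_opposite >= r else target_opinion
    if kind is ResponseKind.ANTICONFORMITY:
        n_same = len(panel) - n_opposite
        return -target_opinion if n_same >= w else target_opinion
    raise ValueError(f"unknown response kind: {kind!r}")
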