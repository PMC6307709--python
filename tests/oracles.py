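"""Independent test oracles.

Everything here is deliberately written from first principles (enumeration,
dense linear algebra, closed forms) and never calls the code paths it checks.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


def enumerate_finite_rates(n_up: int, N: int, q: int, r: int, w: int) -> dict[str, Fraction]:
    """Brute-force rates by enumerating every (target, panel) draw of labeled agents.

    Opinions: agents 0..n_up-1 are up, the rest down.  The target is uniform;
    the panel is every q-combination of the other agents, equally likely.
    """
    opinions = [+1] * n_up + [-1] * (N - n_up)
    out = {k: Fraction(0) for k in ("alpha_plus", "alpha_minus", "beta_plus",
                                    "beta_minus", "gamma_plus", "gamma_minus")}
    n_panels = math.comb(N - 1, q)
    for tgt in range(N):
        s = opinions[tgt]
        # independence: flip probability 1/2 regardless of panel
        if s == -1:
            out["gamma_plus"] += Fraction(1, 2 * N)
        else:
            out["gamma_minus"] += Fraction(1, 2 * N)
        others = [i for i in range(N) if i != tgt]
        for panel in itertools.combinations(others, q):
            weight = Fraction(1, N * n_panels)
            n_opp = sum(1 for i in panel if opinions[i] == -s)
            if n_opp >= r:  # conformity flips
                out["alpha_plus" if s == -1 else "alpha_minus"] += weight
            if q - n_opp >= w:  # anticonformity flips
                out["beta_plus" if s == -1 else "beta_minus"] += weight
    return out


def stationary_by_eigenvector(transition_matrix: np.ndarray) -> np.ndarray:
    """Dominant left eigenvector of the one-step matrix, normalized."""
    evals, evecs = np.linalg.eig(transition_matrix.T)
    i = int(np.argmin(np.abs(evals - 1.0)))
    pi = np.real(evecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def p_of_m_brute(m: float, q: int, r: int, w: int, z: float) -> float:
    """Stationary p(m) from raw binomial sums, written independently."""
    x, v = (1 + m) / 2, (1 - m) / 2

    def tail(k, s):
        return sum(math.comb(q, i) * s**i * (1 - s) ** (q - i) for i in range(k, q + 1))

    A = v * tail(r, x) - x * tail(r, v)
    B = v * tail(w, v) - x * tail(w, x)
    C = (1 - z) * B - z * m / 2
    return A / (A - C)


def richardson_p2(q: int, r: int, w: int, z: float, eps: float = 1e-4) -> float:
    """Quadratic coefficient of p(m) by finite differences + Richardson step.

    p(m) is even around its removable singularity at m = 0, so
    (p(h) - p(h/2)) / (h^2 - h^2/4) estimates p2 with O(h^2) error; one
    Richardson extrapolation in h removes the leading term.
    """

    def est(h):
        return (p_of_m_brute(h, q, r, w, z) - p_of_m_brute(h / 2, q, r, w, z)) / (0.75 * h**2)

    e1, e2 = est(eps), est(eps / 2)
    return (4 * e2 - e1) / 3
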