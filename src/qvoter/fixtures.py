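"""Deterministic fixture bundle: small exact oracles emitted as CSV.

The rate tables are computed here by direct enumeration of panel draws —
*not* via :mod:`qvoter.rates` — so the bundle doubles as an independent
reference for the analytic formulas.
"""

from __future__ import annotations

import csv
import json
import math
from fractions import Fraction
from pathlib import Path

from . import __version__
from .model_core import ModelParams
from .montecarlo import SimulationConfig, run_simulation

__all__ = ["enumerate_rates", "generate_fixtures"]


def enumerate_rates(n_up: int, N: int, q: int, r: int, w: int) -> dict[str, Fraction]:
    """Exact response rates by counting panel combinations, no formulas.

    The target is uniform over agents; the panel is a uniform q-subset of the
    other N-1 agents.  Tail probabilities are accumulated by enumerating the
    possible up-counts of the subset.
    """
    n_down = N - n_up

    def tail_count(k_min: int, ups: int, downs: int) -> Fraction:
        total = math.comb(ups + downs, q)
        hits = sum(math.comb(ups, k) * math.comb(downs, q - k) for k in range(k_min, q + 1))
        return Fraction(hits, total)

    out = {
        "alpha_plus": Fraction(0), "alpha_minus": Fraction(0),
        "beta_plus": Fraction(0), "beta_minus": Fraction(0),
        "gamma_plus": Fraction(n_down, 2 * N), "gamma_minus": Fraction(n_up, 2 * N),
    }
    if n_down:
        out["alpha_plus"] = Fraction(n_down, N) * tail_count(r, n_up, n_down - 1)
        out["beta_plus"] = Fraction(n_down, N) * tail_count(w, n_down - 1, n_up)
    if n_up:
        out["alpha_minus"] = Fraction(n_up, N) * tail_count(r, n_down, n_up - 1)
        out["beta_minus"] = Fraction(n_up, N) * tail_count(w, n_up - 1, n_down)
    return out


def generate_fixtures(seed: int, out_dir: str | Path) -> list[Path]:
    """Write the fixture bundle; returns the written paths (deterministic)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    rates_path = out / "finite_rates_exact.csv"
    with rates_path.open("w", newline="") as fh:
        wr = csv.writer(fh, lineterminator="\n")
        wr.writerow(["N", "q", "r", "w", "n_up", "alpha_plus", "alpha_minus",
                     "beta_plus", "beta_minus", "gamma_plus", "gamma_minus"])
        for N in range(2, 9):
            for q in range(1, N):
                for r in range(1, q + 1):
                    for w in range(1, q + 1):
                        for n_up in range(N + 1):
                            rr = enumerate_rates(n_up, N, q, r, w)
                            wr.writerow([N, q, r, w, n_up] + [
                                format(float(rr[k]), ".17g")
                                for k in ("alpha_plus", "alpha_minus", "beta_plus",
                                          "beta_minus", "gamma_plus", "gamma_minus")])
    written.append(rates_path)

    curve_path = out / "stationary_curve_q3_closed_form.csv"
    with curve_path.open("w", newline="") as fh:
        wr = csv.writer(fh, lineterminator="\n")
        wr.writerow(["m", "p_z1", "p_z0"])
        for k in range(1, 100):
            m = k / 100
            wr.writerow([format(m, ".12g"),
                         format((1 - m**2) / (3 - m**2), ".12g"),
                         format((1 - m**2) / (3 + m**2), ".12g")])
    written.append(curve_path)

    traj_path = out / "reference_trajectory.csv"
    cfg = SimulationConfig(
        params=ModelParams(q=3, r=3, w=3, p=0.1, z=1.0, N=50),
        m0=1.0, duration_mcs=200, burn_in_mcs=0, seed=seed,
    )
    traj = run_simulation(cfg)
    with traj_path.open("w", newline="") as fh:
        wr = csv.writer(fh, lineterminator="\n")
        wr.writerow(["t_mcs", "m"])
        for t, m in zip(traj.times_mcs, traj.m):
            wr.writerow([format(t, ".12g"), format(m, ".12g")])
    written.append(traj_path)

    manifest = out / "fixtures.manifest.json"
    manifest.write_text(json.dumps({
        "seed": seed, "version": __version__,
        "files": [p.name for p in written],
    }, indent=2) + "\n")
    written.append(manifest)
    return written
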