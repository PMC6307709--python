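# qvoter

Threshold q-voter opinion dynamics on the complete graph with all four
Willis–Nail social responses: **conformity** (adopt the opinion of at least
`r` of `q` sampled peers when it opposes your own), **anticonformity** (flip
away from at least `w` peers who share your opinion), **independence**
(random re-draw with flip probability 1/2) and uniformity/congruence (no
change).  A target responds with probabilities `1-p`, `p(1-z)`, `pz`
respectively.

Three engines cross-validate each other:

| engine | module | what it computes |
|---|---|---|
| mean-field | `qvoter.meanfield` | exact stationary relation `p(m)`, effective force/potential, transition type, spinodals, critical points `p*`, `z*`, `r*`, tricritical `q*` |
| master equation | `qvoter.master_equation` | exact finite-`N` birth–death chain on the up-count: stationary distribution (detailed balance), time evolution, absorption probabilities |
| Monte Carlo | `qvoter.montecarlo` | agent-based random-sequential-update simulation (numba kernel + pure-Python reference engine with named RNG substreams) |

Transition classification is done in exact rational arithmetic: the odd
polynomials `A(m)` (conformity drive) and `C(m)` (nonconformity drive) are
expanded to degree 7, `p(m) = A/(A-C)` is divided as a series in `m²`, and
the sign of the first nonzero curvature coefficient decides
continuous (negative) vs discontinuous (positive).  Carrying terms beyond
`m²` matters: at `q=5, r=w=5, z=1` the quadratic coefficient vanishes
exactly and the quartic term (correctly) classifies the transition as
continuous.

## CLI

```sh
qvoter rates --m 0 --q 2 --r 2 --w 2 --p 0 --z 0            # one-row CSV of α±, β±, γ±, λ±, λ0
qvoter stationary-curve --q 6 --r 6 --w 6 --z 1 -o curve.csv
qvoter phase-diagram --q-min 2 --q-max 20 --r-frac 0.75 --w-frac 0.75 --z 0.5
qvoter critical p --q 3 --r 3 --w 3 --z 1                   # p* = 1/3
qvoter critical z --q 6 --r 6 --w 6                         # z* boundary
qvoter critical r --q 10                                    # r* = 8
qvoter critical tricritical --r-frac 1 --w-frac 1 --z 1     # q* = 6
qvoter master --mode stationary --N 50 --q 3 --r 2 --w 2 --p 0.3 --z 0.5
qvoter simulate --N 200 --q 3 --r 3 --w 3 --p 0.1 --z 1 --m0 1 \
    --duration 10000 --seed 42 -o traj.csv --histogram hist.csv
qvoter fixtures --seed 0 --out-dir fixtures                 # oracle fixture bundle
```

Thresholds may be given as integers (`--r 8`) or as panel fractions
(`--r-frac 0.75`, resolved as `ceil(a*q)`).  Any subcommand accepts
`--config file.yaml` whose keys match the parameter names; explicit flags
override the file.  File outputs get a `<name>.manifest.json` with the
resolved parameters, seed and package version, sufficient to reproduce them
bit-identically.

## Scope

Complete graph only; homogeneous agents; independence flip probability fixed
at f = 1/2.  Heterogeneous agents/zealots, other topologies, and binodal
lines are out of scope.
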