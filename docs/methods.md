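# Methods

`fibronet` couples a lumped difference-equation model of mechanosensitive
matrix remodeling to an agent-based simulation on a prestressed 2D spring
network. This note records the model, its assumptions, the parameters that
matter, and the numerical and design choices made where the design was
genuinely open.

## The single-element model

A patch of tissue is a Hookean spring of cross-sectional area `A`, Young's
modulus `E` and rest length `L0`, with spring constant `K = E·A/L0`. `E` and
the *perceived* `L0` are uniform (a cell senses only a cell-length of fiber),
so stiffness varies solely through `A`. A population of fibroblast-like
agents of density `D` (agents per spring) senses two signals on the spring it
occupies, each a saturating Hill function:

- stiffness signal `a_K = (A/A_t)^β / ((A/A_t)^β + 1)` — half-saturates at
  the threshold area `A_t`; steep (`β = 3`) so that a fibrotic regime exists
  at all;
- stretch signal `a_ε = (ε/ε_s)^γ / ((ε/ε_s)^γ + 1)` — half-saturates at the
  homeostatic strain `ε_s`; gentle (`γ = 1`).

Total activation is the weighted difference from the homeostatic operating
point,

    a = w1·a_ε + w2·a_K − c,        c = w1/2 + w2·(A0/A_t)^β/((A0/A_t)^β+1),

so `a = 0` exactly at `(ε, A) = (ε_s, A0)`. `c ≈ 0.5` at the defaults
(`0.500999`). In code `c` is evaluated through the same Hill routines used
for `a_ε` and `a_K`, which makes the homeostatic zero exact in floating
point rather than merely approximate — the fixed-point acceptance check is
bitwise.

Per iteration `j` the element updates in this order:

1. strain under constant external force: `ε_j = ε_s·A0/A_j` (the force is
   frozen at its pre-injury value, so `ε·A` is invariant);
2. signals `a_ε`, `a_K` from `(ε_j, A_j)`;
3. activation with memory `r`: `a_{j+1} = (1−r)·a_j + r·(w1·a_ε + w2·a_K − c)`;
4. matrix: `A_{j+1} = A_j + P·D_j·a_{j+1}` (deposition for `a>0`, digestion
   for `a<0`; `A ≤ 0` means rupture);
5. density: `D_{j+1} = D_j + p1·(n/s) + p3(a)·D·(1−D/D_max) − p2(a)·D`,
   clamped to `[0, D_max]`.

The rationale for the order is the narrative of a crossing: the agent feels
the spring, updates its state, then modifies the spring; the population
turns over last.

### Death and division closures

Only `p1` (spontaneous appearance per node) is a free constant. The other
two probabilities are closed so that the two biological fixed points exist:

- `p2(a) = p2_0 · clip(1 − a/a_fib, 0, 1)` with `p2_0 = p1·(n/s)/D0`:
  baseline death balances the influx exactly at `(a=0, D=D0)`; death is
  *suppressed* linearly with activation (activated myofibroblasts resist
  apoptosis), vanishing at the fibrotic maximum `a_fib = w2 − c` so that
  `D → D_max` in the fibrotic state; death is *elevated* for negative
  activation (digesting agents die more).
- `p3(a) = p3_max · clip(a, 0, a_fib)/a_fib`: division ramps with positive
  activation; the `1/a_fib` normalization diverges as `w2` approaches the
  critical weight (where `a_fib → 0`) — the model is undefined there, and
  for `a_fib ≤ 0` (sub-critical stiffness weight) division is impossible and
  death stays at baseline.
- the logistic factor `(1 − D/D_max)` caps proliferation at the carrying
  capacity; the saturation is stated by the biology, the logistic form is
  our mechanism of choice.

A constant `p2` was considered and rejected: with constant death the
fibrotic density fixed point sits far below `D_max`, contradicting the
intended "apoptosis-resistant myofibroblast" end state. In the density
update the influx `p1·(n/s)` is written as `p2_0·D0` (the same number) so
that the homeostatic balance cancels bitwise. The lumped model uses
`n/s = 2/3`, the interior-vertex ratio of a degree-3 network; on a network
the live counts are used.

### Strain closure

Several discrete renderings of the per-step strain update are possible; we
adopt the closed form of a Hookean spring under constant external force,
`ε = ε_s·A0/A`, which satisfies `ε(A0) = ε_s`, drives `ε → 0` as `A → ∞`,
and makes `ε·A` an exact invariant (tested to float tolerance).

### Outcomes, thresholds and the critical weight

A trajectory is classified:

- **healing** — converged to `(A0, a≈0)` (`|A−A0| < 0.01·A0`, `|a| < 1e-3`),
  or still moving strictly monotonically toward `A0` with the matching
  activation sign (severe sub-critical injuries decay more slowly than the
  2000-iteration run);
- **fibrotic** — runaway growth past `10·max(A_t, A_init)`, or a sustained
  strict increase with `a > 0` beyond `10·A_t`;
- **unstable** — non-finite density; **undecided** otherwise.

The thresholds are chosen to be well separated from both fixed points at the
default parameters. `find_fibrotic_threshold` bisects the injury multiplier
on `[1, 100·A_t/A0]` to `1e-3`. Unbounded growth requires the asymptotic
activation `a_∞ = w2·1 + w1·0 − c` to be positive (stiffness signal
saturated, stretch signal extinguished); when `a_∞ ≤ 0` the threshold is
`+∞`. This computed guard — not a hard-coded constant — is what
`find_critical_weight` bisects against, landing on
`w2* = w1 / (2·(1 − (A0/A_t)^β/((A0/A_t)^β+1))) ≈ 0.5005·w1`, i.e. `0.5` to
one-decimal precision.

One honest subtlety: under the constant-force strain closure the element map
also admits *saturated* elevated fixed points (`A* ≈ 40–100`) in a narrow
weight band just below the runaway condition (`w2 ≈ 0.484–0.5005`). These
states stiffen without running away. The threshold analysis deliberately
targets runaway fibrosis — the state with `A` growing without limit,
`ε → 0`, `D → D_max` — because that is the bifurcation of interest; the
saturated states are reachable only from injuries already an order of
magnitude past `A_t`.

## The spring network

- **Geometry.** Bridson Poisson-disk sampling (`k = 30` candidates, minimum
  separation `r`) over a square of side `s`, then the Voronoi diagram of the
  points; finite edges become springs, infinite ridges are extended and
  clipped at the square, and cut points become boundary nodes. The default
  `s = 15, r = 1` yields roughly 400–550 springs; tests and the scaled-down
  experiments use `s = 12` (~260–300 springs). The network size is a
  documented knob — nothing in the physics fixes it. A regular honeycomb
  (`hexagonal_network`) is the deterministic fixture.
- **Prestress.** Rest lengths are set to `L/(1+ε0)` so every spring carries
  strain `ε0 = 1` (inflated parenchyma). Because uniform strain is not an
  equilibrium of a non-uniform network, the interior is relaxed with the
  boundary pinned *before* the boundary reaction forces are frozen; the
  delivered configuration is then an equilibrium everywhere and the frozen
  forces sum to zero. On the honeycomb the relaxation is a no-op and the
  uniform strain survives exactly. Boundary forces are constant for the
  whole run — the network is free to contract as it stiffens.
- **Equilibrium.** The state minimizes `Σ ½K(L−L0)² − Σ f_ext·x`. The
  default engine is a damped Newton iteration on the exact sparse tangent
  stiffness matrix (per-spring 2×2 blocks), warm-started from the previous
  iteration's coordinates; it reaches the force-residual tolerance
  (`1e-6·E·Ā`) in a handful of steps. A random-displacement annealing
  schedule with shrinking amplitude is retained as a fidelity cross-check
  (the two agree in final energy to `1e-4` relative on fixtures). Springs
  are Hookean in compression too — no buckling model.
- **Rigid modes.** Rupture can strand a connected component whose frozen
  boundary forces no longer balance; no static equilibrium then exists. The
  solver projects the net force and net torque out of the applied load per
  component (statics in the comoving frame) — the only self-consistent
  completion of constant-force boundary conditions under topology change.
- **Rupture.** Springs digested to `A ≤ 0` are removed, then springs
  isolated on both ends, then naked nodes; agents stranded on removed nodes
  die. Pruning is idempotent and spring count never increases.
- **Stiffness assay.** Five accumulating 2% isotropic stretches of the
  boundary about the live-node centroid, interior re-equilibrated with the
  boundary pinned, total spring energy recorded after each; a second-order
  polynomial in cumulative strain (zero point included) is fit and its
  quadratic coefficient is the stiffness, normalized per run by its
  iteration-0 value. Isotropic (vs uniaxial) stretch and pinned (vs free)
  boundary during the assay are declared choices. The assay runs on a copy
  every `assay_stride = 50` iterations (it is the costly step); metric
  curves are step functions in between.

## Agents on the network

Each iteration: every agent picks one incident spring uniformly at random
(migration is unbiased — no durotaxis, by design), traverses it, folds that
spring's `a_K` and `a_ε` into its activation memory, and deposits `P·a` on
the spring. Density enters through crossing counts, so the expectation
recovers the mean-field `ΔA = P·D·a` (tested). All agents sense the
*pre-sweep* state — the strains of the previous equilibrium and the areas
before this sweep's deposition — consistent with the static-strain
approximation of breathing; draws occur in ascending agent-id order from a
single seeded stream, so runs are bit-reproducible. Compressed springs
deliver no stretch signal (the Hill function is defined for tensile strain).
Turnover then applies death before division (a dying agent does not divide),
daughters start undifferentiated (`a = 0`) on the parent's node, and
spontaneous appearance is suppressed at carrying capacity (one-step
overshoot bounded by `p1·n/s`). Event order per iteration: migrate/remodel →
prune → turnover → re-equilibrate.

Agents with `a ≈ 0` are fibroblast-like, agents near `a_fib`
myofibroblast-like; the activation histogram and the per-node accumulated
activation (a proxy for α-smooth-muscle-actin build-up) are the
differentiation readouts.

## Network-level outcome

A run is **healing** when its final normalized stiffness lies in
`[0.8, 1.2]` with quiescent agents (mean `|a| < 0.05`), **fibrotic** when
stiffness exceeds 2, or is still strictly rising across the last three
assays having already left the band upward. These bands are declared, not
derived. Replicate studies (default 9) use consecutive seeds; injury
selection is uniformly random over springs (a clustered-patch option exists,
off by default). Runs may stop early once normalized stiffness passes a
caller-set factor — by then the runaway outcome is decided.

## What the simulations do and do not show

The generator *is* the study system: all inputs are procedural, there is no
external data. Passing tests show that the implemented rules reproduce the
intended dynamical structure — exact homeostasis, the 0.5 critical weight,
threshold monotonicity, softening-injury recovery, network-level
bifurcation under moderate injury, ablation asymmetry, and mean-field
consistency of the stochastic population process. They do not show anything
about real lung tissue beyond that structure: springs are linear with
uniform modulus, the network is 2D without airways, static strain stands in
for cyclic stretch, a single agent type stands in for the cellular milieu,
and iteration time is only loosely related to physiological time.

Problem sizes used by the test suite: single-element analyses run the full
2000 iterations; network experiments use ~300-spring domains with 400–500
iterations where only a trend is asserted and the full 2000 iterations where
the outcome itself is the assertion (bifurcation study, with early stopping
once decided). The bifurcation study fixes `w2 = 2.25`, placing the ×5
injury about 10% below the single-element threshold — the regime where
network structure, not the lumped dynamics, decides the outcome.

## Known limitations

- Near the critical weight the runaway is asymptotically slow; within a
  finite run such trajectories classify "undecided", so the sharp
  healing/fibrotic split has a narrow undecided band around the threshold.
- The annealing engine is a fidelity check, not a production solver; its
  schedule (amplitude decay 0.85–0.97 per sweep) is a declared default.
- Voronoi networks keep the prestress strain only approximately (median
  within ~1% of ε0, spread ±50% after interior relaxation); the honeycomb
  fixture keeps it exactly.
- `%`-ruptured uses the initial spring count as denominator and counts
  isolated-spring removals as ruptured.
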