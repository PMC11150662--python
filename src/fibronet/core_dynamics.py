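"""Lumped single-element dynamics of mechanosensitive tissue remodeling.

A single Hookean element under a constant external force stands in for a
patch of lung parenchyma. A population of fibroblast-like agents reads the
element's stiffness (through its cross-sectional area ``A``) and its strain
``eps``, integrates the two signals into a signed activation ``a``, and
deposits (``a > 0``) or digests (``a < 0``) matrix, closing the feedback
loop. The coupled map in (A, eps, a, D) has a homeostatic fixed point at
(A0, eps_s, 0, D0); a sufficiently strong stiffening insult flips the
negative (healing) feedback into a positive (fibrotic) one once the
stiffness signal overpowers the strain signal.

All quantities are dimensionless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from functools import cached_property
from typing import Sequence

__all__ = [
    "ModelParams",
    "ElementState",
    "Trajectory",
    "Outcome",
    "stiffness_activation",
    "strain_activation",
    "steady_state_constant",
    "total_activation",
    "update_activation",
    "update_area",
    "constant_force_strain",
    "update_density",
    "death_probability",
    "division_probability",
    "simulate_element",
    "classify_outcome",
    "find_fibrotic_threshold",
    "find_critical_weight",
    "phase_diagram",
]


class Outcome(str, Enum):
    HEALING = "healing"
    FIBROTIC = "fibrotic"
    UNSTABLE = "unstable"
    UNDECIDED = "undecided"


@dataclass(frozen=True)
class ModelParams:
    """All model constants; single source of truth for every module.

    Defaults are the model's standard operating point: unit initial
    area and strain, fibrotic threshold area ``At`` ten times the initial
    area, a steep (beta=3) stiffness Hill function and a gentle (gamma=1)
    strain Hill function, agent memory r=0.5.

    Derived quantities:

    * ``c`` — steady-state constant making total activation vanish at
      homeostasis (cached; always coherent with ``steady_state_constant``).
    * ``a_fib`` — maximal fibrotic activation ``w2 - c`` (stiffness signal
      saturated, strain signal extinguished); sets the scale of the
      division-probability ramp and of death suppression.
    * ``p2_0`` — homeostatic death probability ``p1*(n/s)/D0`` balancing the
      spontaneous-appearance influx.
    """

    w1: float = 1.0          # strain signal weight
    w2: float = 1.0          # stiffness signal weight (1-3 in the study)
    A0: float = 1.0          # initial cross-sectional area
    At: float = 10.0         # fibrotic-threshold area
    eps0: float = 1.0        # initial (prestress) strain
    eps_s: float = 1.0       # target homeostatic strain
    gamma: float = 1.0       # strain Hill steepness
    beta: float = 3.0        # stiffness Hill steepness
    r: float = 0.5           # agent activation memory, 0 = frozen, 1 = memoryless
    P: float = 0.2           # matrix production/digestion rate constant
    p1: float = 0.01         # per-node spontaneous agent appearance probability
    p3_max: float = 0.02     # division probability at full fibrotic activation
    D0: float = 0.3          # initial agent density (agents per spring)
    Dmax: float = 3.0        # carrying capacity (agents per spring)
    E: float = 1.0           # Young's modulus (uniform; stiffness varies via A)
    ns_ratio: float = 2.0 / 3.0   # lumped nodes/springs ratio for the element model
    n_iterations: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.w1 < 0 or self.w2 < 0:
            raise ValueError("signal weights must be non-negative")
        if self.A0 <= 0 or self.At <= self.A0:
            raise ValueError("require 0 < A0 < At")
        if self.eps_s <= 0:
            raise ValueError("target strain must be positive")
        if self.gamma <= 0 or self.beta <= 0:
            raise ValueError("Hill steepness must be positive")
        if not 0.0 <= self.r <= 1.0:
            raise ValueError("agent memory r must lie in [0, 1]")
        if self.P <= 0:
            raise ValueError("production constant must be positive")
        for name in ("p1", "p3_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        if self.D0 < 0 or self.Dmax < self.D0:
            raise ValueError("require 0 <= D0 <= Dmax")
        if self.E <= 0:
            raise ValueError("Young's modulus must be positive")
        if self.ns_ratio <= 0:
            raise ValueError("nodes/springs ratio must be positive")

    @cached_property
    def c(self) -> float:
        return steady_state_constant(self)

    @cached_property
    def a_fib(self) -> float:
        """Maximum fibrotic activation: stiffness Hill saturated, strain lost."""
        return self.w2 * 1.0 + self.w1 * 0.0 - self.c

    @property
    def p2_0(self) -> float:
        """Homeostatic death probability (balances the appearance influx)."""
        return self.p1 * self.ns_ratio / self.D0

    def with_ns_ratio(self, n_nodes: int, n_springs: int) -> "ModelParams":
        return replace(self, ns_ratio=n_nodes / n_springs)


@dataclass(frozen=True)
class ElementState:
    A: float      # cross-sectional area
    eps: float    # strain
    a: float      # agent activation (signed)
    D: float      # agent density (agents/spring)


@dataclass
class Trajectory:
    """One ElementState per iteration (length n_iterations+1 unless truncated)."""

    states: list[ElementState]
    outcome: Outcome = Outcome.UNDECIDED
    truncated: bool = False    # area overflow cut the run short

    def __len__(self) -> int:
        return len(self.states)

    @property
    def final(self) -> ElementState:
        return self.states[-1]

    def series(self, attr: str) -> list[float]:
        return [getattr(s, attr) for s in self.states]


# ---------------------------------------------------------------------------
# activation signals
# ---------------------------------------------------------------------------

def stiffness_activation(A: float, params: ModelParams) -> float:
    """Hill response to spring stiffness, ``(A/At)^beta / ((A/At)^beta + 1)``.

    Self-limited in [0, 1): agents probe the spring constant K = E*A/L0 but,
    with E and the perceived L0 uniform, the signal reduces to the area.
    Half-saturates at A = At, the fibrotic threshold.
    """
    if A < 0:
        raise ValueError(f"negative cross-sectional area: {A}")
    x = (A / params.At) ** params.beta
    if math.isinf(x):
        return 1.0
    return x / (x + 1.0)


def strain_activation(eps: float, params: ModelParams) -> float:
    """Hill response to spring strain, half-saturating at the target eps_s."""
    if eps < 0:
        raise ValueError(f"negative strain: {eps}")
    x = (eps / params.eps_s) ** params.gamma
    if math.isinf(x):
        return 1.0
    return x / (x + 1.0)


def steady_state_constant(params: ModelParams) -> float:
    """Offset ``c`` making total activation exactly zero at homeostasis.

    c = w1*H(eps_s) + w2*H(A0) with the same Hill evaluations used by
    ``total_activation``, so the homeostatic zero is exact in floating point.
    Equals w1/2 + w2*(A0/At)^beta/((A0/At)^beta+1); ~0.501 at defaults.
    """
    return (params.w1 * strain_activation(params.eps_s, params)
            + params.w2 * stiffness_activation(params.A0, params))


def total_activation(a_eps: float, a_K: float, params: ModelParams) -> float:
    """Weighted sum of the two signals minus the homeostatic offset."""
    return params.w1 * a_eps + params.w2 * a_K - params.c


def update_activation(a: float, a_eps: float, a_K: float, params: ModelParams) -> float:
    """First-order activation memory: blend the old value with the new signal."""
    return a * (1.0 - params.r) + params.r * total_activation(a_eps, a_K, params)


# ---------------------------------------------------------------------------
# matrix and density updates
# ---------------------------------------------------------------------------

def update_area(A: float, D: float, a: float, params: ModelParams) -> float:
    """Mean-field matrix update ``A + P*D*a``.

    Not clamped: a non-positive result signals rupture to the caller.
    """
    return A + params.P * D * a


def constant_force_strain(A: float, params: ModelParams, force: float | None = None) -> float:
    """Strain of a Hookean element under a constant external force.

    With K proportional to A and the force fixed at its homeostatic value,
    eps*A is invariant: eps = eps_s*A0/A. ``force`` (in units of eps*A)
    overrides the homeostatic eps_s*A0 product.
    """
    if A <= 0:
        raise ValueError("element ruptured: A <= 0")
    f = params.eps_s * params.A0 if force is None else force
    return f / A


def death_probability(a: float, params: ModelParams) -> float:
    """Per-agent death probability.

    Homeostatic baseline p2_0 = p1*(n/s)/D0; suppressed linearly toward zero
    as activation approaches a_fib (activated myofibroblasts resist
    apoptosis) and raised above baseline for negative activation. When
    a_fib <= 0 (stiffness weight at or below the critical value) no fibrotic
    density response exists and the baseline applies throughout.
    """
    base = params.p2_0
    af = params.a_fib
    if af <= 0.0:
        return min(base, 1.0)
    return min(max(base * (1.0 - a / af), 0.0), 1.0)


def division_probability(a: float, params: ModelParams) -> float:
    """Per-agent division probability: p3_max * clip(a, 0, a_fib)/a_fib.

    The 1/a_fib normalization makes the model singular (divide-by-zero) at
    the critical stiffness weight (a_fib -> 0 there); for a_fib <= 0 division
    is impossible.
    """
    af = params.a_fib
    if af <= 0.0:
        return 0.0
    return params.p3_max * min(max(a, 0.0), af) / af


def update_density(D: float, a: float, n_nodes: int, n_springs: int,
                   params: ModelParams) -> float:
    """Mean-field agent density map, clamped to [0, Dmax].

    Influx p1*(n/s), logistic proliferation p3(a)*D*(1-D/Dmax), death
    p2(a)*D. Written so that D=D0 at a=0 and D=Dmax at a=a_fib are exact
    fixed points.
    """
    p = params.with_ns_ratio(n_nodes, n_springs)
    return _update_density(D, a, p)


def _update_density(D: float, a: float, params: ModelParams) -> float:
    p2_0 = params.p2_0
    # influx p1*(n/s) == p2_0*D0 by definition of p2_0; this association makes
    # the homeostatic balance cancel bitwise
    influx = p2_0 * params.D0
    growth = division_probability(a, params) * D * (1.0 - D / params.Dmax)
    delta = influx + growth - death_probability(a, params) * D
    return min(max(D + delta, 0.0), params.Dmax)


# ---------------------------------------------------------------------------
# the coupled map
# ---------------------------------------------------------------------------

_OVERFLOW = 1e12


def simulate_element(params: ModelParams, injury_multiplier: float, *,
                     initial: tuple[float, float] | None = None,
                     n_iterations: int | None = None) -> Trajectory:
    """Iterate the coupled (A, eps, a, D) map from a single insult.

    The insult multiplies the homeostatic area at iteration 0; the external
    force is held at the value it carried through the pre-injury state, so
    strain responds instantly (eps = force/A). ``initial`` optionally seeds
    the run at an arbitrary (A, eps) point, in which case the constant force
    is eps*A of that point (used by the phase diagram). Deterministic.
    """
    if injury_multiplier <= 0:
        raise ValueError("injury multiplier must be positive")
    n = params.n_iterations if n_iterations is None else n_iterations
    if initial is None:
        A = params.A0 * injury_multiplier
        force = params.eps_s * params.A0
    else:
        A, eps_init = initial
        if A <= 0 or eps_init <= 0:
            raise ValueError("initial state must have positive area and strain")
        force = eps_init * A
    a = 0.0
    D = params.D0
    states = [ElementState(A, force / A, a, D)]
    truncated = False
    for _ in range(n):
        eps = constant_force_strain(A, params, force)
        a_eps = strain_activation(eps, params)
        a_K = stiffness_activation(A, params)
        a = update_activation(a, a_eps, a_K, params)
        A = update_area(A, D, a, params)
        D = _update_density(D, a, params)
        if A <= 0:
            truncated = True  # fully digested: element ruptured
            break
        states.append(ElementState(A, force / A, a, D))
        if A > _OVERFLOW:
            truncated = True
            break
    traj = Trajectory(states, truncated=truncated)
    traj.outcome = classify_outcome(traj, params)
    return traj


def _strictly_monotone(xs: Sequence[float], sign: int) -> bool:
    return all(sign * (b - a) > 0 for a, b in zip(xs, xs[1:]))


def classify_outcome(traj: Trajectory, params: ModelParams,
                     tol_A: float | None = None, tol_a: float = 1e-3) -> Outcome:
    """Label a trajectory healing / fibrotic / unstable / undecided.

    Healing: converged back to (A0, a=0) within tolerance, or still moving
    monotonically toward A0 with the matching activation sign (severe but
    sub-critical injuries decay slower than the run length). Fibrotic:
    runaway growth past 10x the larger of At and the injured area, or a
    sustained strict increase with positive activation already an order of
    magnitude beyond the fibrotic threshold. Unstable: density left the
    finite range.
    """
    if not traj.states:
        raise ValueError("cannot classify an empty trajectory")
    if tol_A is None:
        tol_A = 0.01 * params.A0
    final = traj.final
    A0 = params.A0
    if traj.truncated:
        return Outcome.FIBROTIC if final.A > A0 else Outcome.UNSTABLE
    if abs(final.A - A0) < tol_A and abs(final.a) < tol_a:
        return Outcome.HEALING
    A_series = traj.series("A")
    A_init = A_series[0]
    cap = 10.0 * max(params.At, A_init)
    if max(A_series) >= cap:
        return Outcome.FIBROTIC
    if not math.isfinite(final.D):
        return Outcome.UNSTABLE
    tail = A_series[-max(2, len(A_series) // 10):]
    if (_strictly_monotone(tail, +1) and final.a > 0
            and final.A > 10.0 * params.At):
        return Outcome.FIBROTIC
    # healing in progress: moving monotonically toward homeostasis
    if final.A > A0 and _strictly_monotone(tail, -1) and final.a < 0:
        return Outcome.HEALING
    if final.A < A0 and _strictly_monotone(tail, +1) and final.a > 0:
        return Outcome.HEALING
    return Outcome.UNDECIDED


# ---------------------------------------------------------------------------
# threshold and bifurcation analysis
# ---------------------------------------------------------------------------

def _asymptotic_activation(params: ModelParams) -> float:
    """Limit of total activation under constant force as A -> infinity.

    The stiffness Hill saturates to 1 while the strain signal vanishes, so
    a_inf = w2 - c. Unbounded (runaway) fibrotic growth is possible iff
    a_inf > 0; this is the model's critical-weight condition.
    """
    return total_activation(0.0, 1.0, params)


def _is_fibrotic(params: ModelParams, multiplier: float) -> bool:
    return simulate_element(params, multiplier).outcome is Outcome.FIBROTIC


def multiplier_grid(params: ModelParams, ratio: float = 1.1,
                    m_max: float | None = None) -> list[float]:
    """Geometric injury-multiplier grid from 1 to 100*At/A0."""
    if m_max is None:
        m_max = 100.0 * params.At / params.A0
    grid = [1.0]
    while grid[-1] * ratio < m_max:
        grid.append(grid[-1] * ratio)
    grid.append(m_max)
    return grid


def find_fibrotic_threshold(params: ModelParams, tol: float = 1e-3,
                            m_max: float | None = None) -> float:
    """Critical injury multiplier above which the element turns fibrotic.

    Returns +inf when no runaway response exists, i.e. when the asymptotic
    activation w2 - c is non-positive (equivalently w2 <~ 0.5*w1): the
    stiffness signal can then never overpower the strain signal. Otherwise
    bisection over [1, 100*At/A0] to the requested tolerance.
    """
    if m_max is None:
        m_max = 100.0 * params.At / params.A0
    if _asymptotic_activation(params) <= 0.0:
        return math.inf
    if not _is_fibrotic(params, m_max):
        # runaway exists asymptotically but is not reachable in the scan range
        for m in reversed(multiplier_grid(params, m_max=m_max)):
            if _is_fibrotic(params, m):
                m_max = m
                break
        else:
            return math.inf
    lo, hi = 1.0, m_max
    lo_out = simulate_element(params, lo).outcome
    if lo_out is Outcome.FIBROTIC:
        raise RuntimeError("no healing bracket: homeostasis classified fibrotic")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _is_fibrotic(params, mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def find_critical_weight(params: ModelParams, tol: float = 1e-4,
                         lo: float = 0.25, hi: float = 1.0) -> float:
    """Infimum stiffness weight (w1 held fixed) admitting a fibrotic response.

    Bisects the predicate "find_fibrotic_threshold is finite" in w2; lands on
    the runaway condition w2 = w1 / (2*(1 - H(A0/At))), ~0.5005*w1 at the
    default parameters, i.e. 0.5 at one-decimal precision.
    """
    def admits_fibrosis(w2: float) -> bool:
        return math.isfinite(find_fibrotic_threshold(replace(params, w2=w2)))

    lo_scaled = lo * params.w1
    hi_scaled = hi * params.w1
    if admits_fibrosis(lo_scaled):
        raise RuntimeError("lower bracket already fibrotic; widen the bracket")
    while not admits_fibrosis(hi_scaled):
        hi_scaled *= 2.0
        if hi_scaled > 100.0 * params.w1:
            raise RuntimeError("no fibrotic weight found in bracket")
    while hi_scaled - lo_scaled > tol:
        mid = 0.5 * (lo_scaled + hi_scaled)
        if admits_fibrosis(mid):
            hi_scaled = mid
        else:
            lo_scaled = mid
    return 0.5 * (lo_scaled + hi_scaled)


def phase_diagram(eps_values: Sequence[float], A_values: Sequence[float],
                  params: ModelParams,
                  n_iterations: int | None = None) -> list[list[str]]:
    """Outcome label for each (eps, A) initial state; grid[i][j] = (eps_i, A_j).

    Each point seeds the element map with the constant force eps*A of that
    state. Cells whose 4-neighbourhood mixes healing and fibrotic labels are
    relabelled "mixed" (the bifurcation boundary band).
    """
    labels = [[simulate_element(params, 1.0, initial=(A, e),
                                n_iterations=n_iterations).outcome.value
               for A in A_values] for e in eps_values]
    ni, nj = len(eps_values), len(A_values)
    out = [row[:] for row in labels]
    for i in range(ni):
        for j in range(nj):
            neigh = {labels[i][j]}
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                if 0 <= i + di < ni and 0 <= j + dj < nj:
                    neigh.add(labels[i + di][j + dj])
            if Outcome.HEALING.value in neigh and Outcome.FIBROTIC.value in neigh:
                out[i][j] = "mixed"
    return out
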