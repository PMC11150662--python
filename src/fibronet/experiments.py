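"""Injury protocols, the full simulation driver, replicates and run metrics.

A run couples the pieces: generate a prestressed Voronoi network held by its
boundary reaction forces, seed agents at the homeostatic density, inflict a
single insult (multiply the area of a random fraction of springs), then
iterate migration/remodeling -> rupture pruning -> population turnover ->
re-equilibration. Network function is tracked by the strain-energy stiffness
assay (normalized to its pre-injury value), the percentage of ruptured
springs, the agent density, the activation distribution, and the convex-hull
area of the tissue (fibrotic networks contract).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

from . import abm
from .core_dynamics import ModelParams, Outcome
from .mechanics_solver import equilibrate, prune_ruptured, stiffness_assay
from .network_geometry import (DomainSpec, SpringNetwork, apply_prestress,
                               build_voronoi_network, compute_boundary_forces,
                               poisson_disk_sample)

__all__ = [
    "InjurySpec",
    "RunMetrics",
    "generate_prestressed_network",
    "apply_injury",
    "run_simulation",
    "replicate_study",
    "ablation",
    "classify_network_outcome",
]

HISTOGRAM_BINS = np.linspace(-1.0, 3.0, 41)


@dataclass(frozen=True)
class InjurySpec:
    """Single tissue insult: multiply A of a random fraction of springs."""

    fraction: float = 0.0        # fraction of live springs injured
    multiplier: float = 1.0      # area factor; <1 softening, >1 stiffening
    selection_seed: int = 0
    clustered: bool = False      # grow one contiguous patch instead of uniform picks

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("injury fraction must lie in [0, 1]")
        if self.multiplier <= 0:
            raise ValueError("injury multiplier must be positive")


@dataclass
class RunMetrics:
    """Per-iteration records of one simulation run."""

    iteration: np.ndarray = None
    normalized_stiffness: np.ndarray = None   # step function between assays
    pct_ruptured: np.ndarray = None           # vs initial spring count
    density: np.ndarray = None
    mean_abs_activation: np.ndarray = None
    network_area: np.ndarray = None
    assay_iterations: list = field(default_factory=list)
    assay_values: list = field(default_factory=list)      # normalized
    histograms: dict = field(default_factory=dict)        # iteration -> counts
    histogram_bins: np.ndarray = None
    activation_accum: np.ndarray = None       # per-node accumulated activation
    outcome: Outcome = Outcome.UNDECIDED
    snapshots: dict = field(default_factory=dict)         # iteration -> SpringNetwork

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy per-iteration table (iteration, metric, value)."""
        wide = pd.DataFrame({
            "iteration": self.iteration,
            "normalized_stiffness": self.normalized_stiffness,
            "pct_ruptured": self.pct_ruptured,
            "density": self.density,
            "mean_abs_activation": self.mean_abs_activation,
            "network_area": self.network_area,
        })
        return wide.melt(id_vars="iteration", var_name="metric", value_name="value")


def generate_prestressed_network(domain: DomainSpec, params: ModelParams
                                 ) -> SpringNetwork:
    """Voronoi network prestressed to eps0 and frozen under its reaction forces.

    The interior is relaxed with the boundary pinned before the boundary
    reaction forces are frozen, so the delivered configuration is an
    equilibrium everywhere: re-equilibrating it moves nothing. (Interior
    relaxation perturbs the strains away from the exactly uniform eps0; the
    hexagonal fixture keeps them exact by symmetry.)
    """
    pts = poisson_disk_sample(domain)
    net = build_voronoi_network(pts, domain, A0=params.A0, E=params.E)
    apply_prestress(net, params.eps0)
    equilibrate(net, pin_boundary=True)
    compute_boundary_forces(net)
    return net


def apply_injury(net: SpringNetwork, spec: InjurySpec,
                 re_equilibrate: bool = True) -> SpringNetwork:
    """Multiply A of the selected springs and (by default) re-equilibrate.

    Selection is uniformly random over live springs; with ``clustered`` the
    same number of springs is grown breadth-first from a random seed spring
    (injuries in real tissue are spatially correlated; off by default).
    """
    count = int(round(spec.fraction * net.n_live_springs))
    if count == 0:
        return net
    rng = np.random.default_rng(spec.selection_seed)
    live = np.flatnonzero(net.spring_alive)
    if not spec.clustered:
        chosen = rng.choice(live, size=count, replace=False)
    else:
        adj = net.adjacency()
        start = int(rng.choice(live))
        seen = {start}
        frontier = [start]
        while frontier and len(seen) < count:
            s = frontier.pop(0)
            for node in net.springs[s]:
                for s2, _ in adj[node]:
                    if s2 not in seen:
                        seen.add(s2)
                        frontier.append(s2)
                        if len(seen) >= count:
                            break
        chosen = np.fromiter(seen, dtype=np.intp)
    net.A[chosen] *= spec.multiplier
    if re_equilibrate:
        equilibrate(net)
    return net


def _network_area(net: SpringNetwork) -> float:
    pts = net.nodes[net.node_alive]
    if len(pts) < 3:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)   # 2D: volume is the area
    except Exception:
        return 0.0


def run_simulation(params: ModelParams, domain: DomainSpec | None = None,
                   injury: InjurySpec | None = None,
                   n_iterations: int | None = None, seed: int | None = None,
                   assay_stride: int = 50, net: SpringNetwork | None = None,
                   snapshot_iterations: tuple[int, ...] | None = None,
                   stop_when_fibrotic: float | None = None) -> RunMetrics:
    """Full agent-network simulation; deterministic for a fixed seed.

    Event order per iteration: agents migrate and remodel on the strains of
    the previous equilibrium (static-strain approximation) -> ruptured
    springs are pruned and stranded agents removed -> population turnover ->
    re-equilibration (warm start). The stiffness assay runs every
    ``assay_stride`` iterations; its curve is a step function in between.
    Terminates early if the network disintegrates, or — when
    ``stop_when_fibrotic`` is set — once the normalized stiffness exceeds
    that factor (the runaway outcome is then already decided; used to keep
    replicate studies cheap).
    """
    if domain is None:
        domain = DomainSpec()
    if injury is None:
        injury = InjurySpec()
    n = params.n_iterations if n_iterations is None else n_iterations
    master = np.random.default_rng(params.seed if seed is None else seed)
    net_seed, agent_seed, dyn_seed, injury_seed = master.integers(2 ** 31, size=4)

    if net is None:
        net = generate_prestressed_network(replace(domain, seed=int(net_seed)), params)
    else:
        net = net.copy()
    if snapshot_iterations is None:
        snapshot_iterations = (0, n // 2, n)

    m = RunMetrics()
    m.histogram_bins = HISTOGRAM_BINS
    m.activation_accum = np.zeros(len(net.nodes))
    n_initial = net.n_springs_initial

    stiff0, _ = stiffness_assay(net)
    rng = np.random.default_rng(int(dyn_seed))
    pop = abm.init_agents(net, params.D0, np.random.default_rng(int(agent_seed)))

    if injury.fraction > 0:
        injury = replace(injury, selection_seed=int(injury_seed))
        apply_injury(net, injury)
    strains = net.strains()

    it = np.arange(n + 1)
    norm_stiff = np.empty(n + 1)
    pct_rupt = np.empty(n + 1)
    dens = np.empty(n + 1)
    mean_a = np.empty(n + 1)
    area = np.empty(n + 1)

    current_stiffness = 1.0
    m.assay_iterations.append(0)
    m.assay_values.append(1.0)

    def record(j: int) -> None:
        norm_stiff[j] = current_stiffness
        pct_rupt[j] = 100.0 * (1.0 - net.n_live_springs / n_initial)
        dens[j] = pop.density(net)
        mean_a[j] = float(np.abs(pop.a).mean()) if len(pop) else 0.0
        area[j] = _network_area(net)
        if j in snapshot_iterations:
            m.snapshots[j] = net.copy()
            m.histograms[j] = activation_counts(pop)

    def activation_counts(p) -> np.ndarray:
        counts, _ = abm.activation_histogram(p, m.histogram_bins)
        return counts

    record(0)
    last = n
    for j in range(1, n + 1):
        abm.step_migration(pop, net, strains, rng, params, m.activation_accum)
        _, removed, dead_nodes = prune_ruptured(net)
        if dead_nodes:
            stranded = np.isin(pop.node, dead_nodes)
            if stranded.any():
                pop.events["stranded"] += int(stranded.sum())
                pop._remove(stranded)
        if net.n_live_springs == 0:
            last = j
            record(j)
            break
        abm.step_birth_death_division(pop, net, rng, params)
        equilibrate(net)
        strains = net.strains()
        if j % assay_stride == 0 or j == n:
            coeff, _ = stiffness_assay(net)
            current_stiffness = coeff / stiff0
            m.assay_iterations.append(j)
            m.assay_values.append(current_stiffness)
        record(j)
        if (stop_when_fibrotic is not None
                and current_stiffness > stop_when_fibrotic):
            last = j
            break

    sl = slice(0, last + 1)
    m.iteration = it[sl]
    m.normalized_stiffness = norm_stiff[sl]
    m.pct_ruptured = pct_rupt[sl]
    m.density = dens[sl]
    m.mean_abs_activation = mean_a[sl]
    m.network_area = area[sl]
    if last not in m.histograms:
        m.histograms[last] = activation_counts(pop)
        m.snapshots[last] = net.copy()
    m.outcome = classify_network_outcome(m)
    return m


def classify_network_outcome(m: RunMetrics,
                             healing_band: tuple[float, float] = (0.8, 1.2),
                             activation_tol: float = 0.05,
                             fibrotic_stiffness: float = 2.0) -> Outcome:
    """Label a network run from its stiffness trajectory and final activation.

    Healing: final normalized stiffness inside the band with quiescent
    agents. Fibrotic: stiffness beyond the hard threshold, or still rising
    across the last three assays having already left the band upward.
    """
    stiff = m.assay_values
    final = stiff[-1]
    if final > fibrotic_stiffness:
        return Outcome.FIBROTIC
    if len(stiff) >= 3:
        tail = stiff[-3:]
        if all(b > a for a, b in zip(tail, tail[1:])) and final > healing_band[1]:
            return Outcome.FIBROTIC
    if healing_band[0] <= final <= healing_band[1] \
            and m.mean_abs_activation[-1] < activation_tol:
        return Outcome.HEALING
    return Outcome.UNDECIDED


def replicate_study(params: ModelParams, domain: DomainSpec | None = None,
                    injury: InjurySpec | None = None, n_replicates: int = 9,
                    n_iterations: int | None = None, base_seed: int = 0,
                    assay_stride: int = 50,
                    stop_when_fibrotic: float | None = None) -> list[RunMetrics]:
    """Independent replicates (fresh network, agents and injury pattern each).

    Returns the full per-replicate metric distribution — the raw material for
    final-stiffness / %-ruptured / density box plots across conditions.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    return [run_simulation(params, domain, injury, n_iterations,
                           seed=base_seed + k, assay_stride=assay_stride,
                           stop_when_fibrotic=stop_when_fibrotic)
            for k in range(n_replicates)]


def ablation(params: ModelParams, mode: str, domain: DomainSpec | None = None,
             injury: InjurySpec | None = None, n_iterations: int | None = None,
             seed: int = 0, assay_stride: int = 50) -> RunMetrics:
    """Knock out one mechanosensing pathway and run the standard experiment.

    mode="no_strain" removes stretch sensitivity (w1=0): the healing signal
    is lost and stiffening injuries cannot resolve. mode="no_stiffness"
    removes stiffness sensitivity (w2=0): the positive feedback is lost and
    fibrosis cannot develop. The homeostatic offset c is recomputed.
    """
    if mode == "no_strain":
        p = replace(params, w1=0.0)
    elif mode == "no_stiffness":
        p = replace(params, w2=0.0)
    else:
        raise ValueError(f"unknown ablation mode: {mode!r}")
    return run_simulation(p, domain, injury, n_iterations, seed=seed,
                          assay_stride=assay_stride)
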