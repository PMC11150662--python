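"""Discrete fibroblast-like agents migrating on the spring network.

Agents perform an unbiased random walk on the network graph (one spring per
iteration; durotaxis deliberately omitted). Crossing a spring, an agent
reads the spring's stiffness and strain, folds them into its activation
memory, and deposits or digests matrix on that spring by P*a per crossing —
density enters through the number of discrete crossings, so the mean-field
area update A + P*D*a is recovered in expectation. Population turnover
(spontaneous appearance, death, division) matches the mean-field density
map in expectation; agents with activation near zero are fibroblast-like,
near the fibrotic maximum myofibroblast-like.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_dynamics import ModelParams
from .network_geometry import SpringNetwork

__all__ = [
    "AgentPopulation",
    "init_agents",
    "step_migration",
    "step_birth_death_division",
    "activation_histogram",
    "local_activation_map",
]


@dataclass
class AgentPopulation:
    """Array-of-fields agent collection; iteration order is ascending id."""

    node: np.ndarray                  # (n,) current node index per agent
    a: np.ndarray                     # (n,) activation
    ids: np.ndarray                   # (n,) persistent ids
    next_id: int
    events: dict = field(default_factory=lambda: {
        "births": 0, "deaths": 0, "divisions": 0, "stranded": 0})

    def __len__(self) -> int:
        return len(self.node)

    def density(self, net: SpringNetwork) -> float:
        m = net.n_live_springs
        return len(self) / m if m else 0.0

    def to_dataframe(self):
        """Agent table (id, node, a) — optional per-iteration dump."""
        import pandas as pd
        return pd.DataFrame({"id": self.ids, "node": self.node, "a": self.a})

    def _remove(self, mask: np.ndarray) -> None:
        keep = ~mask
        self.node = self.node[keep]
        self.a = self.a[keep]
        self.ids = self.ids[keep]

    def _append(self, nodes: np.ndarray, a: float = 0.0) -> None:
        k = len(nodes)
        if k == 0:
            return
        self.node = np.concatenate([self.node, nodes])
        self.a = np.concatenate([self.a, np.full(k, a)])
        self.ids = np.concatenate(
            [self.ids, np.arange(self.next_id, self.next_id + k)])
        self.next_id += k


def init_agents(net: SpringNetwork, D0: float, seed: int | np.random.Generator = 0
                ) -> AgentPopulation:
    """Place round(D0 * live springs) zero-activation agents on random nodes."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(D0 * net.n_live_springs))
    live_nodes = np.flatnonzero(net.node_alive)
    nodes = rng.choice(live_nodes, size=n) if n else np.empty(0, dtype=np.intp)
    return AgentPopulation(node=nodes.astype(np.intp), a=np.zeros(n),
                           ids=np.arange(n), next_id=n)


def step_migration(pop: AgentPopulation, net: SpringNetwork, strains: np.ndarray,
                   rng: np.random.Generator, params: ModelParams,
                   activation_accum: np.ndarray | None = None) -> AgentPopulation:
    """One migration/mechanosensing/remodeling sweep over all agents.

    Each agent picks a uniformly random incident spring, traverses it,
    updates its activation from that spring's stiffness and strain, and adds
    P*a to the spring's area. All agents sense the pre-sweep state (the
    strains of the previous equilibrium, the areas before this sweep's
    deposition), consistent with the static-strain approximation; draws are
    made in ascending id order from a single RNG stream, so the sweep is bit
    reproducible. Compressed springs (negative strain) deliver no stretch
    signal. Agents whose node has lost all springs are removed as stranded.
    ``activation_accum`` (per-node) accumulates visiting activations for the
    local-activation map.
    """
    if len(pop) == 0:
        return pop
    # flat adjacency: incident (spring, partner) pairs grouped by node
    live = np.flatnonzero(net.spring_alive)
    si, sj = net.springs[live, 0], net.springs[live, 1]
    ends = np.concatenate([si, sj])
    partners = np.concatenate([sj, si])
    spring_of = np.concatenate([live, live])
    order = np.argsort(ends, kind="stable")
    ends_sorted = ends[order]
    deg = np.bincount(ends_sorted, minlength=len(net.nodes))
    offset = np.concatenate([[0], np.cumsum(deg)])

    node = pop.node
    stranded = deg[node] == 0
    if stranded.any():
        pop.events["stranded"] += int(stranded.sum())
        pop._remove(stranded)
        node = pop.node
        if len(pop) == 0:
            return pop

    # one uniform incident-spring draw per agent (ascending id order)
    pick = offset[node] + rng.integers(deg[node])
    s = spring_of[order][pick]
    dest = partners[order][pick]

    # every agent senses the pre-step state (the strains of the previous
    # equilibrium and the areas before this sweep's deposition)
    A_seen = net.A[s]
    x = (np.maximum(A_seen, 0.0) / params.At) ** params.beta
    a_K = x / (x + 1.0)
    eps = np.maximum(strains[s], 0.0)   # compression delivers no stretch signal
    y = (eps / params.eps_s) ** params.gamma
    a_eps = y / (y + 1.0)
    a_new = (pop.a * (1.0 - params.r)
             + params.r * (params.w1 * a_eps + params.w2 * a_K - params.c))
    pop.a = a_new
    np.add.at(net.A, s, params.P * a_new)
    pop.node = dest.astype(np.intp)
    if activation_accum is not None:
        np.add.at(activation_accum, dest, a_new)
    return pop


def step_birth_death_division(pop: AgentPopulation, net: SpringNetwork,
                              rng: np.random.Generator, params: ModelParams
                              ) -> AgentPopulation:
    """Stochastic population turnover matching the mean-field density map.

    Death is evaluated before division (a dying agent does not divide);
    division carries the logistic capacity factor (1 - D/Dmax) with the
    density measured at phase start; daughters start undifferentiated (a=0)
    on the parent's node. Spontaneous appearance (probability p1 per live
    node) is suppressed once the population is at carrying capacity, so the
    density overshoots Dmax by at most p1*n/s in a single step.
    """
    n_springs = net.n_live_springs
    if n_springs == 0:
        pop._remove(np.ones(len(pop), dtype=bool))
        return pop
    params = params.with_ns_ratio(net.n_live_nodes, n_springs)
    D = pop.density(net)

    if len(pop):
        af = params.a_fib
        base = params.p2_0
        if af > 0:
            p_death = np.clip(base * (1.0 - pop.a / af), 0.0, 1.0)
            p_div = params.p3_max * np.clip(pop.a, 0.0, af) / af
        else:
            p_death = np.full(len(pop), min(base, 1.0))
            p_div = np.zeros(len(pop))
        dying = rng.random(len(pop)) < p_death
        capacity = max(1.0 - D / params.Dmax, 0.0)
        p_div = p_div * capacity
        dividing = (rng.random(len(pop)) < p_div) & ~dying
        if dying.any():
            pop.events["deaths"] += int(dying.sum())
        daughters = pop.node[dividing].copy()
        pop._remove(dying)
        if len(daughters):
            pop.events["divisions"] += len(daughters)
            pop._append(daughters)

    if pop.density(net) < params.Dmax:
        live_nodes = np.flatnonzero(net.node_alive)
        born = live_nodes[rng.random(len(live_nodes)) < params.p1]
        if len(born):
            pop.events["births"] += len(born)
            pop._append(born.astype(np.intp))
    return pop


def activation_histogram(pop: AgentPopulation, bins) -> tuple[np.ndarray, np.ndarray]:
    """Counts of agents per activation bin (fibroblast vs myofibroblast split)."""
    return np.histogram(pop.a, bins=bins)


def local_activation_map(visits, n_nodes: int) -> np.ndarray:
    """Accumulated activation per node from an iterable of (node, a) visits.

    Proxy for local alpha-smooth-muscle-actin build-up: each agent visit adds
    its current activation to the visited node's tally. The simulation driver
    maintains this incrementally via ``step_migration``'s accumulator; this
    function reduces an explicit visit log the same way.
    """
    acc = np.zeros(n_nodes)
    for node, a in visits:
        acc[node] += a
    return acc
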