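"""Agents on the network: migration, mechanosensing, deposition, turnover."""

from dataclasses import replace

import numpy as np
import pytest

from fibronet import (ModelParams, hexagonal_network, apply_prestress,
                      compute_boundary_forces, init_agents,
                      activation_histogram, local_activation_map,
                      step_birth_death_division, step_migration)
from fibronet.core_dynamics import update_density


@pytest.fixture
def hex_net_3():
    net = hexagonal_network(3)
    apply_prestress(net, 1.0)
    compute_boundary_forces(net)
    return net


class TestInitAgents:
    def test_count_matches_density(self, hex_net_3):
        pop = init_agents(hex_net_3, 0.3, seed=0)
        assert len(pop) == round(0.3 * hex_net_3.n_live_springs)
        assert np.all(pop.a == 0.0)
        assert hex_net_3.node_alive[pop.node].all()

    def test_zero_density_empty(self, hex_net_3):
        assert len(init_agents(hex_net_3, 0.0, seed=0)) == 0


class TestMigration:
    def test_homeostatic_crossing_is_neutral(self, hex_net_3, params):
        """On a uniformly homeostatic network an a=0 agent stays at a=0 and
        deposits nothing (exact fixed point of the crossing rule)."""
        pop = init_agents(hex_net_3, 0.5, seed=1)
        A_before = hex_net_3.A.copy()
        strains = hex_net_3.strains()
        rng = np.random.default_rng(2)
        for _ in range(5):
            step_migration(pop, hex_net_3, strains, rng, params)
        assert np.all(pop.a == 0.0)
        assert np.array_equal(hex_net_3.A, A_before)

    def test_activated_agent_deposits(self, hex_net_3, params):
        """Positive activation thickens every spring crossed; negative digests."""
        for a0, sign in ((1.0, +1), (-0.45, -1)):
            net = hex_net_3.copy()
            pop = init_agents(net, 0.2, seed=3)
            pop.a[:] = a0
            A_before = net.A.copy()
            # strains/stiffness at homeostasis contribute zero fresh signal,
            # so the memory keeps the imposed activation's sign this step
            step_migration(pop, net, net.strains(), np.random.default_rng(4), params)
            delta = net.A - A_before
            assert sign * delta.sum() > 0
            assert np.all(sign * delta >= 0)

    def test_stranded_agents_removed(self, params):
        net = hexagonal_network(1)
        apply_prestress(net, 1.0)
        pop = init_agents(net, 1.0, seed=5)
        net.spring_alive[:] = False
        step_migration(pop, net, net.strains(), np.random.default_rng(0), params)
        assert len(pop) == 0
        assert pop.events["stranded"] > 0

    def test_bit_reproducible(self, hex_net_3, params):
        def run():
            net = hex_net_3.copy()
            pop = init_agents(net, 0.4, seed=9)
            rng = np.random.default_rng(10)
            for _ in range(30):
                step_migration(pop, net, net.strains(), rng, params)
                step_birth_death_division(pop, net, rng, params)
            return pop.node.copy(), pop.a.copy(), net.A.copy()
        n1, a1, A1 = run()
        n2, a2, A2 = run()
        assert np.array_equal(n1, n2) and np.array_equal(a1, a2) \
            and np.array_equal(A1, A2)


class TestTurnover:
    def test_no_events_when_probabilities_zero(self, hex_net_3):
        p = ModelParams(p1=0.0, p3_max=0.0)
        pop = init_agents(hex_net_3, 0.3, seed=0)
        n0 = len(pop)
        step_birth_death_division(pop, hex_net_3, np.random.default_rng(1), p)
        assert len(pop) == n0

    @pytest.mark.parametrize("a_level", ["homeostatic", "fibrotic"])
    def test_mean_field_agreement(self, hex_net_3, params, a_level):
        """Expected one-step density change matches the mean-field map."""
        n_nodes, n_springs = hex_net_3.n_live_nodes, hex_net_3.n_live_springs
        if a_level == "homeostatic":
            a, D_target = 0.0, params.D0
        else:
            a = params.with_ns_ratio(n_nodes, n_springs).a_fib
            D_target = params.Dmax
        n_agents = int(round(D_target * n_springs))
        D = n_agents / n_springs          # realized (rounded) start density
        expected = update_density(D, a, n_nodes, n_springs, params) - D
        rng = np.random.default_rng(12)
        deltas = []
        for _ in range(3000):
            pop = init_agents(hex_net_3, 0.0, seed=rng)
            pop._append(rng.choice(np.flatnonzero(hex_net_3.node_alive),
                                   size=n_agents).astype(np.intp))
            pop.a[:] = a
            step_birth_death_division(pop, hex_net_3, rng, params)
            deltas.append(len(pop) / n_springs - D)
        mc = np.mean(deltas)
        se = np.std(deltas) / np.sqrt(len(deltas))
        assert abs(mc - expected) < 4 * se + 1e-4

    def test_capacity_caps_overshoot(self, hex_net_3, params):
        """At carrying capacity only spontaneous influx can add agents."""
        n_springs = hex_net_3.n_live_springs
        pop = init_agents(hex_net_3, 0.0, seed=0)
        rng = np.random.default_rng(3)
        pop._append(rng.choice(np.flatnonzero(hex_net_3.node_alive),
                               size=int(params.Dmax * n_springs)).astype(np.intp))
        pop.a[:] = params.with_ns_ratio(hex_net_3.n_live_nodes, n_springs).a_fib
        step_birth_death_division(pop, hex_net_3, rng, params)
        overshoot = len(pop) / n_springs - params.Dmax
        assert overshoot <= params.p1 * hex_net_3.n_live_nodes / n_springs + 1e-12

    def test_density_homeostasis_long_run(self, params):
        """With both pathways intact and no injury, density holds near D0.

        The band is a stochastic tolerance: on this ~1000-spring lattice the
        stationary count fluctuations stay well inside +-20% of D0.
        """
        net = hexagonal_network(11)
        apply_prestress(net, 1.0)
        compute_boundary_forces(net)
        pop = init_agents(net, params.D0, seed=21)
        rng = np.random.default_rng(22)
        strains = net.strains()
        densities = []
        for _ in range(2000):
            step_migration(pop, net, strains, rng, params)
            step_birth_death_division(pop, net, rng, params)
            densities.append(pop.density(net))
        densities = np.array(densities)
        assert np.all(np.abs(densities - params.D0) <= 0.2 * params.D0 + 1e-9)


class TestHistogramAndMap:
    def test_histogram_conserves_agents(self, hex_net_3):
        pop = init_agents(hex_net_3, 0.7, seed=2)
        pop.a = np.random.default_rng(0).uniform(-0.4, 2.0, len(pop))
        counts, edges = activation_histogram(pop, np.linspace(-1, 3, 21))
        assert counts.sum() == len(pop)

    def test_homeostatic_population_is_single_mode_at_zero(self, hex_net_3):
        pop = init_agents(hex_net_3, 0.5, seed=2)
        counts, edges = activation_histogram(pop, np.linspace(-1, 3, 21))
        nonzero = np.flatnonzero(counts)
        assert len(nonzero) == 1
        assert edges[nonzero[0]] <= 0.0 <= edges[nonzero[0] + 1]

    def test_agent_table_columns(self, hex_net_3):
        pop = init_agents(hex_net_3, 0.4, seed=1)
        df = pop.to_dataframe()
        assert list(df.columns) == ["id", "node", "a"]
        assert len(df) == len(pop)

    def test_local_activation_map(self):
        acc = local_activation_map([(0, 0.5), (0, 0.25), (2, -0.1)], 4)
        assert acc.tolist() == [0.75, 0.0, -0.1, 0.0]
        assert np.all(local_activation_map([], 3) == 0.0)
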