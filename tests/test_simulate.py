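"""Stage-structured demography, dispersal mechanics, and full simulations."""

import numpy as np
import pytest

from netspread import (
    DemographicParams,
    DispersalKernel,
    PopulationState,
    SpatialHabitatNetwork,
    build_lattice,
    disperse_step,
    initialize,
    mortality_and_aging_step,
    reproduce_step,
    simulate,
)

NO_DEMOGRAPHY = DemographicParams(
    stage_advance_prob=0.0, repro_prob=0.0, mortality_prob=0.0, density_ceiling=None
)


def tiny_net(n_nodes, links, lengths=None):
    links = tuple(tuple(sorted(l)) for l in links)
    lengths = lengths or tuple(15.0 for _ in links)
    return SpatialHabitatNetwork(
        n_nodes=n_nodes,
        coords=np.zeros((n_nodes, 2)),
        links=links,
        link_lengths=tuple(lengths),
        config_label="partial",
        rewire_fraction=0.5,
        topology_id=f"tiny-{n_nodes}",
    )


def adult_state(n, node, n_nodes):
    return PopulationState(
        day=0,
        age=np.full(n, 100, dtype=np.int64),
        stage=np.full(n, 4, dtype=np.int64),
        node=np.full(n, node, dtype=np.int64),
        n_nodes=n_nodes,
    )


class TestInitialize:
    def test_all_individuals_at_source(self, lattice, rng):
        state = initialize(lattice, source=0, n0=200, rng=rng)
        assert state.size == 200
        assert (state.node == 0).all()
        assert state.counts()[0] == 200

    def test_forced_stage_assignment(self, lattice, rng):
        state = initialize(lattice, 0, 4, rng, stages=np.array([1, 2, 3, 4]))
        assert sorted(state.stage) == [1, 2, 3, 4]
        # initial age is stage x juvenile threshold
        assert sorted(state.age) == [7, 14, 21, 28]

    def test_uniform_stage_split(self, lattice):
        rng = np.random.default_rng(0)
        counts = np.zeros(4)
        n_rep = 100
        for _ in range(n_rep):
            state = initialize(lattice, 0, 200, rng)
            counts += np.bincount(state.stage, minlength=5)[1:]
        per_class = counts / n_rep
        se = np.sqrt(200 * 0.25 * 0.75 / n_rep)
        assert np.all(np.abs(per_class - 50) < 3 * se)

    def test_unknown_source_rejected(self, lattice, rng):
        with pytest.raises(ValueError):
            initialize(lattice, source=99, n0=10, rng=rng)


class TestReproduce:
    def test_no_reproduction_leaves_state(self, rng):
        state = adult_state(50, 0, 3)
        out = reproduce_step(state, NO_DEMOGRAPHY, rng)
        assert out.size == 50

    def test_ceiling_blocks_recruitment(self, rng):
        params = DemographicParams(repro_prob=1.0, density_ceiling=10)
        state = adult_state(10, 0, 3)  # node already at ceiling
        out = reproduce_step(state, params, rng)
        assert out.counts()[0] == 10

    def test_compound_binomial_mean(self):
        """100 adults at p=0.1 with Poisson(5) clutches yield ~50 recruits."""
        rng = np.random.default_rng(5)
        params = DemographicParams(repro_prob=0.1, clutch_size_mean=5.0, density_ceiling=None)
        n_rep = 500
        recruits = np.empty(n_rep)
        for i in range(n_rep):
            out = reproduce_step(adult_state(100, 0, 2), params, rng)
            recruits[i] = out.size - 100
        var = 100 * (0.1 * (5 + 25) - 0.25)  # compound binomial-Poisson
        se = np.sqrt(var / n_rep)
        assert abs(recruits.mean() - 50) < 3 * se

    def test_recruits_are_newborns(self, rng):
        params = DemographicParams(repro_prob=1.0, density_ceiling=None)
        out = reproduce_step(adult_state(20, 1, 3), params, rng)
        new = out.age == 0
        assert new.sum() > 0
        assert (out.stage[new] == 1).all()
        assert (out.node[new] == 1).all()


class TestDisperse:
    def test_zero_kernel_freezes_everyone(self, rng):
        net = tiny_net(2, [(0, 1)])
        state = adult_state(100, 0, 2)
        out = disperse_step(state, net, DispersalKernel(a=0.0, b=0.0), NO_DEMOGRAPHY, rng)
        assert (out.node == 0).all()

    def test_certain_single_neighbour_move(self, rng):
        net = tiny_net(2, [(0, 1)])
        state = adult_state(5, 0, 2)
        out = disperse_step(state, net, DispersalKernel(a=1.0, b=0.0), NO_DEMOGRAPHY, rng)
        assert (out.node == 1).all()

    def test_departure_rate_two_equal_neighbours(self):
        """P(leave) = 1 - (1-0.5)^2 with two neighbours at D=0.5."""
        rng = np.random.default_rng(11)
        net = tiny_net(3, [(0, 1), (0, 2)])
        kernel = DispersalKernel(a=0.5, b=0.0)
        n_days, n_ind = 100, 100
        left = 0
        for _ in range(n_days):
            out = disperse_step(adult_state(n_ind, 0, 3), net, kernel, NO_DEMOGRAPHY, rng)
            left += int((out.node != 0).sum())
        n_tot = n_days * n_ind
        p = 0.75
        se = np.sqrt(p * (1 - p) / n_tot)
        assert abs(left / n_tot - p) < 3 * se

    def test_total_count_conserved(self, lattice):
        rng = np.random.default_rng(2)
        kernel = DispersalKernel(a=0.5, b=-0.01)
        state = PopulationState(
            day=0,
            age=rng.integers(0, 60, 500),
            stage=rng.integers(1, 5, 500),
            node=rng.integers(0, 10, 500),
            n_nodes=10,
        )
        for _ in range(20):
            state = disperse_step(state, lattice, kernel, NO_DEMOGRAPHY, rng)
            assert state.size == 500

    def test_juveniles_never_move(self, rng):
        net = tiny_net(2, [(0, 1)])
        state = PopulationState(
            day=0,
            age=np.array([0, 3, 7]),  # all at or below the 7-day threshold
            stage=np.array([1, 1, 2]),
            node=np.zeros(3, dtype=np.int64),
            n_nodes=2,
        )
        out = disperse_step(state, net, DispersalKernel(a=1.0, b=0.0), NO_DEMOGRAPHY, rng)
        assert (out.node == 0).all()

    def test_move_keeps_age_and_stage(self, rng):
        net = tiny_net(2, [(0, 1)])
        state = adult_state(10, 0, 2)
        out = disperse_step(state, net, DispersalKernel(a=1.0, b=0.0), NO_DEMOGRAPHY, rng)
        assert (out.age == 100).all()
        assert (out.stage == 4).all()


class TestMortalityAndAging:
    def test_pure_aging(self, rng):
        state = adult_state(10, 0, 2)
        out = mortality_and_aging_step(state, NO_DEMOGRAPHY, rng)
        assert (out.age == 101).all()
        assert (out.stage == 4).all()

    def test_certain_death_empties_network(self, rng):
        params = DemographicParams(mortality_prob=1.0)
        out = mortality_and_aging_step(adult_state(100, 0, 2), params, rng)
        assert out.size == 0

    def test_binomial_survival(self):
        rng = np.random.default_rng(8)
        params = DemographicParams(mortality_prob=0.05, stage_advance_prob=0.0)
        survivors = [
            mortality_and_aging_step(adult_state(1000, 0, 2), params, rng).size
            for _ in range(200)
        ]
        se = np.sqrt(1000 * 0.05 * 0.95 / 200)
        assert abs(np.mean(survivors) - 950) < 3 * se

    def test_stage_never_exceeds_max(self, rng):
        params = DemographicParams(stage_advance_prob=1.0, mortality_prob=0.0)
        out = mortality_and_aging_step(adult_state(50, 0, 2), params, rng)
        assert (out.stage == 4).all()


class TestSimulate:
    def test_single_node_occupied_at_introduction(self):
        net = SpatialHabitatNetwork(
            n_nodes=1, coords=np.zeros((1, 2)), links=(), link_lengths=(),
            config_label="lattice", rewire_fraction=0.0, topology_id="single",
        )
        res = simulate(net, DemographicParams(), DispersalKernel(a=0.1, b=0.0), duration=5, seed=0)
        assert res.occupancy_day == 0
        assert not res.censored

    def test_zero_kernel_censors(self, lattice):
        res = simulate(lattice, DemographicParams(), DispersalKernel(a=0.0, b=0.0), duration=20, seed=0)
        assert res.censored
        assert res.occupancy_day is None
        assert res.occupancy_or_horizon == 20

    def test_counts_cover_every_day(self, lattice):
        res = simulate(lattice, DemographicParams(), DispersalKernel(a=0.1, b=-0.043), duration=30, seed=4)
        assert res.counts.shape == (31, 10)
        assert (res.counts >= 0).all()

    def test_colonization_precedes_occupancy(self, lattice):
        res = simulate(lattice, DemographicParams(), DispersalKernel(a=0.1, b=-0.043), duration=200, seed=4)
        assert res.occupancy_day is not None
        assert (res.colonization_day >= 0).all()
        assert res.colonization_day.max() <= res.occupancy_day

    def test_deterministic_given_seed(self, lattice):
        a = simulate(lattice, DemographicParams(), DispersalKernel(a=0.1, b=-0.043), duration=40, seed=77)
        b = simulate(lattice, DemographicParams(), DispersalKernel(a=0.1, b=-0.043), duration=40, seed=77)
        assert np.array_equal(a.counts, b.counts)
        assert a.occupancy_day == b.occupancy_day

    def test_different_seeds_differ(self, lattice):
        a = simulate(lattice, DemographicParams(), DispersalKernel(a=0.1, b=-0.043), duration=40, seed=1)
        b = simulate(lattice, DemographicParams(), DispersalKernel(a=0.1, b=-0.043), duration=40, seed=2)
        assert not np.array_equal(a.counts, b.counts)

    def test_stop_when_occupied_truncates(self, lattice):
        res = simulate(
            lattice, DemographicParams(), DispersalKernel(a=0.1, b=-0.043),
            duration=200, seed=4, stop_when_occupied=True,
        )
        assert res.counts.shape[0] == res.occupancy_day + 1
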