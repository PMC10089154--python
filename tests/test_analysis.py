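"""Occupancy-time definition, speedup ratios, regression, and sweeps."""

import numpy as np
import pandas as pd
import pytest

from netspread import (
    DemographicParams,
    DispersalKernel,
    build_lattice,
    occupancy_vs_connectivity,
    rewire,
    run_occupancy_experiment,
    simulate,
    speedup_ratios,
    sweep_b,
    time_to_full_occupancy,
)
from netspread.simulate import SimulationResult


def result_from_counts(counts):
    counts = np.asarray(counts)
    return SimulationResult(
        counts=counts,
        colonization_day=np.zeros(counts.shape[1], dtype=int),
        occupancy_day=None,
        censored=True,
        duration=counts.shape[0] - 1,
        seed=0,
        topology_id="synthetic",
    )


class TestTimeToFullOccupancy:
    def test_occupied_from_day_zero(self):
        assert time_to_full_occupancy(result_from_counts(np.ones((5, 3)))) == 0

    def test_last_node_sets_the_day(self):
        counts = np.ones((50, 3))
        counts[:42, 2] = 0
        assert time_to_full_occupancy(result_from_counts(counts)) == 42

    def test_simultaneity_required_after_local_extinction(self):
        """A node that empties after colonization delays full occupancy until
        every node is simultaneously occupied (brute-force constructed table)."""
        counts = np.ones((70, 3))
        counts[:30, 1] = 0     # node 1 colonized on day 30
        counts[20:60, 2] = 0   # node 2 colonized day 0, dips, back on day 60
        assert time_to_full_occupancy(result_from_counts(counts)) == 60

    def test_never_full_is_none(self):
        counts = np.ones((10, 2))
        counts[:, 1] = 0
        assert time_to_full_occupancy(result_from_counts(counts)) is None


def occupancy_table(days_by_config, lambda2_by_config=None):
    rows = []
    lambda2_by_config = lambda2_by_config or {"lattice": 3.0, "partial": 2.0, "random": 1.0}
    for cfg, days in days_by_config.items():
        for i, d in enumerate(days):
            rows.append(
                {
                    "topology_id": f"{cfg}-{i % 3}",
                    "config_label": cfg,
                    "rewire_fraction": {"lattice": 0.0, "partial": 0.2, "random": 1.0}[cfg],
                    "replicate": i,
                    "occupancy_day": float(d),
                    "censored": False,
                    "lambda2": lambda2_by_config[cfg] + 0.01 * (i % 3),
                }
            )
    return pd.DataFrame(rows)


class TestSpeedupRatios:
    def test_identical_distributions_give_unity(self):
        tab = occupancy_table({c: [20] * 30 for c in ("lattice", "partial", "random")})
        r = speedup_ratios(tab, n_boot=100)
        assert r.random_vs_lattice == pytest.approx(1.0)
        assert r.random_vs_partial == pytest.approx(1.0)

    def test_ratio_is_mean_quotient(self):
        tab = occupancy_table(
            {"lattice": [10] * 20, "partial": [15] * 20, "random": [51] * 20}
        )
        r = speedup_ratios(tab, n_boot=100)
        assert r.random_vs_lattice == pytest.approx(5.1)
        assert r.random_vs_partial == pytest.approx(3.4)

    def test_missing_config_rejected(self):
        tab = occupancy_table({"lattice": [10] * 5, "random": [20] * 5})
        with pytest.raises(ValueError):
            speedup_ratios(tab)

    def test_bootstrap_ci_shrinks_with_replicates(self):
        rng = np.random.default_rng(0)
        small = occupancy_table(
            {c: rng.normal(40, 10, 12) for c in ("lattice", "partial", "random")}
        )
        big = occupancy_table(
            {c: rng.normal(40, 10, 200) for c in ("lattice", "partial", "random")}
        )
        r_small = speedup_ratios(small, n_boot=400, seed=1)
        r_big = speedup_ratios(big, n_boot=400, seed=1)
        width = lambda ci: ci[1] - ci[0]
        assert width(r_big.ci_random_vs_lattice) < width(r_small.ci_random_vs_lattice)


class TestOccupancyVsConnectivity:
    def test_noiseless_line_recovered(self):
        lam = {"lattice": 3.0, "partial": 2.0, "random": 1.0}
        tab = occupancy_table(
            {c: [100 - 30 * lam[c]] * 9 for c in lam}, lambda2_by_config=lam
        )
        # remove the within-config lambda2 jitter so the line is exact
        tab["lambda2"] = tab["config_label"].map(lam)
        tab["topology_id"] = tab["config_label"] + "-" + (tab["replicate"] % 3).astype(str)
        tab["occupancy_day"] = 100 - 30 * tab["lambda2"]
        reg = occupancy_vs_connectivity(tab)
        assert reg.slope == pytest.approx(-30.0)
        assert reg.r_squared == pytest.approx(1.0)

    def test_shuffled_response_uncorrelated(self):
        rng = np.random.default_rng(4)
        tab = occupancy_table(
            {c: rng.normal(50, 5, 30) for c in ("lattice", "partial", "random")}
        )
        tab["lambda2"] = rng.permutation(np.linspace(0.5, 3.0, len(tab)))
        tab["topology_id"] = np.arange(len(tab)).astype(str)
        reg = occupancy_vs_connectivity(tab)
        assert reg.r_squared < 0.15

    def test_constant_lambda2_rejected(self):
        tab = occupancy_table({c: [10, 20, 30] for c in ("lattice", "partial", "random")})
        tab["lambda2"] = 1.0
        with pytest.raises(ValueError):
            occupancy_vs_connectivity(tab)

    def test_agrees_with_reference_least_squares(self):
        """OLS and ANOVA match hand-rolled normal-equation results to 1e-8."""
        rng = np.random.default_rng(9)
        lam = {"lattice": 3.0, "partial": 2.0, "random": 1.0}
        tab = occupancy_table(
            {c: rng.normal(100 - 30 * lam[c], 4, 12) for c in lam}, lambda2_by_config=lam
        )
        reg = occupancy_vs_connectivity(tab)
        per = tab.groupby(["topology_id", "config_label"], as_index=False).agg(
            occupancy_day=("occupancy_day", "mean"), lambda2=("lambda2", "first")
        )
        x, y = per["lambda2"].to_numpy(), per["occupancy_day"].to_numpy()
        slope_ref, intercept_ref = np.polyfit(x, y, 1)
        resid = y - (slope_ref * x + intercept_ref)
        r2_ref = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert reg.slope == pytest.approx(slope_ref, abs=1e-8)
        assert reg.r_squared == pytest.approx(r2_ref, abs=1e-8)
        group_means = per.groupby("config_label")["occupancy_day"].transform("mean")
        ss_between = ((group_means - y.mean()) ** 2).sum()
        anova_r2_ref = ss_between / ((y - y.mean()) ** 2).sum()
        assert reg.anova_r_squared == pytest.approx(anova_r2_ref, abs=1e-8)


@pytest.fixture(scope="module")
def small_nets():
    rng = np.random.default_rng(3)
    lattice = build_lattice(10)
    return [lattice, rewire(lattice, 0.2, rng), rewire(lattice, 1.0, rng)]


class TestSweeps:
    def test_grid_covers_every_cell(self, small_nets):
        out = sweep_b(small_nets, [-0.05, -0.01], reps=2, mode="distance_dependent", seed=0)
        assert set(out["b"]) == {-0.05, -0.01}
        assert set(out["config_label"]) == {"lattice", "partial", "random"}
        assert (out.groupby("b")["fastest"].sum() == 1).all()

    def test_distance_independent_speed_monotone_in_probability(self):
        """With a common link probability, a larger probability never slows
        spread (checked across three kernel averages on the lattice)."""
        lattice = build_lattice(10)
        params = DemographicParams()
        means = []
        for b in (-0.1, -0.043, -0.01):
            kernel = DispersalKernel(a=0.1, b=b, mode="distance_independent")
            days = [
                simulate(
                    lattice, params, kernel, duration=200,
                    seed=np.random.SeedSequence([17, rep, abs(hash(b)) % 1000]),
                    stop_when_occupied=True,
                ).occupancy_or_horizon
                for rep in range(30)
            ]
            means.append(np.mean(days))
        assert means[0] > means[1] > means[2]


class TestRunOccupancyExperiment:
    def test_table_schema_and_determinism(self, topologies):
        kernel = DispersalKernel(a=0.1, b=-0.043)
        params = DemographicParams()
        tab1 = run_occupancy_experiment(topologies[:3], params, kernel, replicates=2, seed=5)
        tab2 = run_occupancy_experiment(topologies[:3], params, kernel, replicates=2, seed=5)
        pd.testing.assert_frame_equal(tab1, tab2)
        assert len(tab1) == 6
        assert (tab1["occupancy_day"] <= 200).all()
        assert (tab1["lambda2"] > 0).all()
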