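"""Molecular-clock timing: piecewise clock, acceptance sampling, TD dating."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonetrace.chronology import (
    ClockModel,
    accept_draw,
    anchor_path,
    piecewise_age,
    td_onset_age,
    td_sbs1_regression,
    time_clusters,
)
from clonetrace.errors import ConfigurationError, DataError
from clonetrace.synthetic import SimulationConfig, simulate_clone_tree
from clonetrace.trees import Clone, CloneTree

from _oracles import acceptance_region_by_scan


def chain_tree(sbs1_counts, private_leaf=False):
    """Linear chain T -> S1 -> ... with given branch SBS1 counts."""
    clones = []
    prev = None
    for i, n in enumerate(sbs1_counts):
        cid = "T" if i == 0 else f"S{i}"
        ccf = {"a": 1.0, "b": 1.0}
        if i > 0:
            ccf = {"a": max(0.05, 1.0 - 0.15 * i), "b": 0.0} if private_leaf else {
                "a": max(0.05, 1.0 - 0.1 * i), "b": max(0.05, 1.0 - 0.1 * i)}
        clones.append(Clone(cid, prev, ccf, n_snv=4 * n, n_sbs1=n))
        prev = cid
    return CloneTree(clones)


class TestAnchorPath:
    def test_root_only(self):
        tree = CloneTree([Clone("T", None, {"a": 1.0}, n_sbs1=10)])
        path, cum = anchor_path(tree)
        assert path == ["T"] and cum.tolist() == [10]

    def test_max_sbs1_leaf_wins(self):
        tree = CloneTree(
            [
                Clone("T", None, {"a": 1.0, "b": 1.0}, n_sbs1=100, n_snv=400),
                Clone("A", "T", {"a": 0.5, "b": 0.1}, n_sbs1=20, n_snv=100),
                Clone("B", "T", {"a": 0.1, "b": 0.5}, n_sbs1=60, n_snv=100),
            ]
        )
        path, cum = anchor_path(tree)
        assert path == ["T", "B"] and cum.tolist() == [100, 160]

    def test_sbs1_tie_broken_by_snv_total(self):
        tree = CloneTree(
            [
                Clone("T", None, {"a": 1.0, "b": 1.0}, n_sbs1=100, n_snv=400),
                Clone("A", "T", {"a": 0.5, "b": 0.1}, n_sbs1=50, n_snv=300),
                Clone("B", "T", {"a": 0.1, "b": 0.5}, n_sbs1=50, n_snv=100),
            ]
        )
        path, _ = anchor_path(tree)
        assert path == ["T", "A"]


class TestPiecewiseAge:
    def test_boundary_values(self):
        assert piecewise_age(0, 100, 60, 50, 5) == 0.0
        assert piecewise_age(100, 100, 60, 50, 5) == pytest.approx(60.0)

    def test_hand_evaluated_rates(self):
        # N=100, T=60, t_a=50, k=5 -> r = 100/(50 + 5*10) = 1
        assert piecewise_age(40, 100, 60, 50, 5) == pytest.approx(40.0)
        assert piecewise_age(80, 100, 60, 50, 5) == pytest.approx(56.0)

    def test_zero_anchor_total_is_an_error(self):
        with pytest.raises(DataError):
            piecewise_age(0, 0, 60, 50, 5)

    @settings(derandomize=True, max_examples=60)
    @given(
        t_a=st.floats(0.0, 60.0),
        k=st.floats(1.0, 10.0),
        n=st.floats(0.0, 199.0),
    )
    def test_strictly_increasing_and_continuous(self, t_a, k, n):
        age_lo = piecewise_age(n, 200, 60, t_a, k)
        age_hi = piecewise_age(n + 1, 200, 60, t_a, k)
        assert age_hi > age_lo
        # continuity at the change point: approaching from both sides
        r = 200 / (t_a + k * (60 - t_a))
        edge = r * t_a
        if 0 < edge < 200:
            below = piecewise_age(edge - 1e-7, 200, 60, t_a, k)
            above = piecewise_age(edge + 1e-7, 200, 60, t_a, k)
            assert above - below < 1e-4

    def test_anchor_identity_for_any_change_point(self):
        for t_a in np.linspace(0, 60, 13):
            assert piecewise_age(150, 150, 60, t_a, 5) == pytest.approx(60.0)


class TestAcceptDraw:
    def test_zero_change_point_always_accepted(self):
        tree = chain_tree([100, 30, 20], private_leaf=True)
        clock = ClockModel(age_rp=60)
        assert accept_draw(0.0, tree, clock)

    def test_grid_matches_direct_scan_oracle(self):
        tree, _ = simulate_clone_tree(SimulationConfig(seed=21, n_clusters=6))
        clock = ClockModel(age_rp=60.0)
        grid = np.linspace(45.0, 60.0, 1000)
        expected = acceptance_region_by_scan(tree, clock, grid)
        got = np.array([accept_draw(t, tree, clock) for t in grid])
        assert np.array_equal(got, expected)

    def test_private_cluster_low_on_trunk_restricts_acceptance(self):
        # private branch starting at 50/150 of the anchor cannot fall
        # entirely inside a late acceleration era
        tree = CloneTree(
            [
                Clone("T", None, {"a": 1.0, "b": 1.0}, n_sbs1=50, n_snv=100),
                Clone("A", "T", {"a": 0.6, "b": 0.6}, n_sbs1=80, n_snv=200),
                Clone("P", "T", {"a": 0.2, "b": 0.0}, n_sbs1=20, n_snv=50),
            ]
        )
        clock = ClockModel(age_rp=60)
        assert not accept_draw(59.0, tree, clock)
        assert accept_draw(20.0, tree, clock)


class TestTimeClusters:
    def test_constant_rate_limit_equals_linear_clock(self):
        tree = chain_tree([100, 40, 60])
        clock = ClockModel(age_rp=60.0, accel_factor=1.0, n_draws=500, seed=1)
        timing = time_clusters(tree, clock)
        table = timing.table.set_index("cluster")
        for cid in tree.clones:
            n = tree.cumulative(cid, "n_sbs1")
            expected = 60.0 * n / 200.0
            assert table.loc[cid, "median_age"] == pytest.approx(expected, rel=1e-12)
            assert table.loc[cid, "ci_low"] == pytest.approx(expected, rel=1e-12)
            assert table.loc[cid, "ci_high"] == pytest.approx(expected, rel=1e-12)
            assert table.loc[cid, "ci_high"] - table.loc[cid, "ci_low"] < 1e-9

    def test_child_age_not_below_parent_age(self):
        tree, _ = simulate_clone_tree(SimulationConfig(seed=13, n_clusters=7))
        clock = ClockModel(age_rp=60.0, n_draws=2000, seed=2)
        timing = time_clusters(tree, clock)
        table = timing.table.set_index("cluster")
        for cid, clone in tree.clones.items():
            if clone.parent is not None:
                assert table.loc[cid, "median_age"] >= table.loc[clone.parent, "median_age"]

    def test_deterministic_under_seed(self):
        tree = chain_tree([100, 40, 60])
        clock = ClockModel(age_rp=60.0, n_draws=1000, seed=9)
        a = time_clusters(tree, clock).table
        b = time_clusters(tree, clock).table
        assert a.equals(b)

    def test_all_ages_bounded_by_age_at_sampling(self):
        tree, _ = simulate_clone_tree(SimulationConfig(seed=14, n_clusters=6))
        timing = time_clusters(tree, ClockModel(age_rp=60.0, n_draws=1000, seed=3))
        assert (timing.table["ci_high"] <= 60.0 + 1e-9).all()
        assert (timing.table["ci_low"] <= timing.table["median_age"]).all()
        assert (timing.table["median_age"] <= timing.table["ci_high"]).all()

    def test_zero_accepted_draws_is_an_error(self):
        # a private cluster branching off almost at the root: no late
        # change point can make its mutations fully accelerated
        tree = CloneTree(
            [
                Clone("T", None, {"a": 1.0, "b": 1.0}, n_sbs1=10, n_snv=40),
                Clone("A", "T", {"a": 0.7, "b": 0.7}, n_sbs1=140, n_snv=500),
                Clone("P", "T", {"a": 0.3, "b": 0.0}, n_sbs1=10, n_snv=30),
            ]
        )
        with pytest.raises(DataError, match="wider window"):
            time_clusters(tree, ClockModel(age_rp=60.0, n_draws=500, seed=4))

    def test_invalid_clock_is_a_config_error(self):
        with pytest.raises(ConfigurationError):
            ClockModel(age_rp=10.0, window_years=15.0).validate()

    def test_calibration_cis_cover_true_ages(self):
        """95% CIs from accepted draws cover the simulated truth."""
        covered = total = 0
        for seed in range(10):
            config = SimulationConfig(seed=700 + seed, n_clusters=6)
            tree, truth = simulate_clone_tree(config)
            clock = ClockModel(age_rp=config.age_rp, n_draws=4000, seed=seed,
                               count_resampling=True)
            try:
                timing = time_clusters(tree, clock)
            except DataError:
                continue
            table = timing.table.set_index("cluster")
            for cid in tree.clones:
                total += 1
                lo, hi = table.loc[cid, "ci_low"], table.loc[cid, "ci_high"]
                true_age = truth.emergence_age[cid] if len(tree) > 1 else 0.0
                covered += (lo <= true_age <= hi)
        assert total >= 30
        assert covered / total >= 0.85


class TestTdRegression:
    def test_exact_line_recovers_slope_two(self):
        x = np.array([100, 120, 150, 180, 200])
        fit = td_sbs1_regression(x, 2 * x)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)
        assert fit.pvalue < 1e-6

    def test_constant_tds_have_zero_slope(self):
        fit = td_sbs1_regression([100, 120, 150, 180], [40, 40, 40, 40])
        assert fit.slope == 0.0

    def test_too_few_points_is_an_error(self):
        with pytest.raises(DataError):
            td_sbs1_regression([1, 2], [2, 4])

    def test_poisson_noise_recovery_within_band(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(100):
            x = np.sort(rng.integers(120, 260, size=8))
            y = rng.poisson(2.0 * x)
            fit = td_sbs1_regression(x, y)
            hits += 1.6 <= fit.slope <= 2.4
        assert hits >= 90


class TestTdOnset:
    def make_tree(self, n_truncal=100, d_truncal=50):
        return chain_tree([n_truncal, 50, 50]), None

    def test_hand_evaluated_onset_coordinate(self):
        tree = chain_tree([100, 50, 50])
        tree.clones["T"].n_td = 50
        clock = ClockModel(age_rp=60.0, n_draws=500, seed=1)
        timing = time_clusters(tree, clock)
        onset = td_onset_age(tree, timing, slope=2.0, clock=clock)
        assert onset.onset_sbs1 == pytest.approx(75.0)
        assert onset.fraction_truncal == pytest.approx(0.75)
        assert onset.ci_low <= onset.median_age <= onset.ci_high

    def test_tds_from_first_mutation(self):
        tree = chain_tree([100, 50, 50])
        tree.clones["T"].n_td = 200  # slope 2 * N_T
        clock = ClockModel(age_rp=60.0, n_draws=500, seed=1)
        timing = time_clusters(tree, clock)
        onset = td_onset_age(tree, timing, slope=2.0, clock=clock)
        assert onset.fraction_truncal == 0.0
        assert onset.median_age == pytest.approx(0.0)

    def test_no_truncal_tds_puts_onset_at_trunk_end(self):
        tree = chain_tree([100, 50, 50])
        tree.clones["T"].n_td = 0
        clock = ClockModel(age_rp=60.0, n_draws=500, seed=1)
        timing = time_clusters(tree, clock)
        onset = td_onset_age(tree, timing, slope=2.0, clock=clock)
        assert onset.fraction_truncal == 1.0

    def test_nonpositive_slope_is_an_error(self):
        tree = chain_tree([100, 50, 50])
        clock = ClockModel(age_rp=60.0, n_draws=100, seed=1)
        timing = time_clusters(tree, clock)
        with pytest.raises(DataError):
            td_onset_age(tree, timing, slope=0.0, clock=clock)

    def test_fraction_always_in_unit_interval(self):
        rng = np.random.default_rng(2)
        clock = ClockModel(age_rp=60.0, n_draws=200, seed=1)
        for _ in range(20):
            tree = chain_tree([int(rng.integers(50, 200)), 40, 40])
            tree.clones["T"].n_td = int(rng.integers(0, 600))
            timing = time_clusters(tree, clock)
            onset = td_onset_age(tree, timing, slope=2.0, clock=clock)
            assert 0.0 <= onset.fraction_truncal <= 1.0
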