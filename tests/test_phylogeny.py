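"""Tree building, cluster curation, event assignment, jawbreakers."""

import numpy as np
import pandas as pd
import pytest

from clonetrace.errors import DataError
from clonetrace.phylogeny import (
    assign_event_to_cluster,
    build_tree,
    classify_tandem_duplications,
    drop_low_ccf_clusters,
    jawbreaker_layers,
    merge_close_clusters,
)
from clonetrace.synthetic import SimulationConfig, simulate_clone_tree
from clonetrace.trees import Clone, CloneTree

from _oracles import cluster_frame, enumerate_canonical_tree


def frame(rows):
    return pd.DataFrame(rows)


class TestBuildTree:
    def test_single_truncal_cluster(self):
        tree = build_tree(frame([{"cluster": "T", "n_mutations": 10, "ccf_a": 1.0}]))
        assert tree.root == "T" and len(tree) == 1

    def test_mutually_exclusive_subclones_attach_to_trunk(self):
        tree = build_tree(
            frame(
                [
                    {"cluster": "T", "n_mutations": 100, "ccf_a": 1.0, "ccf_b": 1.0},
                    {"cluster": "A", "n_mutations": 50, "ccf_a": 0.8, "ccf_b": 0.1},
                    {"cluster": "B", "n_mutations": 40, "ccf_a": 0.1, "ccf_b": 0.8},
                ]
            )
        )
        assert tree.clones["A"].parent == "T"
        assert tree.clones["B"].parent == "T"

    def test_no_truncal_cluster_is_an_error(self):
        with pytest.raises(DataError, match="no truncal cluster"):
            build_tree(frame([{"cluster": "A", "n_mutations": 5, "ccf_a": 0.5}]))

    def test_unplaceable_cluster_is_an_error(self):
        # A and B are forced siblings (mutual dominance fails) but
        # together overfill the trunk in sample a: pigeonhole violation
        with pytest.raises(DataError, match="cannot be placed|no sum-rule"):
            build_tree(
                frame(
                    [
                        {"cluster": "T", "n_mutations": 9,
                         "ccf_a": 1.0, "ccf_b": 1.0, "ccf_c": 1.0},
                        {"cluster": "A", "n_mutations": 5,
                         "ccf_a": 0.7, "ccf_b": 0.2, "ccf_c": 0.0},
                        {"cluster": "B", "n_mutations": 4,
                         "ccf_a": 0.7, "ccf_b": 0.0, "ccf_c": 0.2},
                    ]
                ),
                tolerance=0.01,
            )

    def test_output_satisfies_sum_rule_post_hoc(self):
        for seed in range(5):
            tree, _ = simulate_clone_tree(SimulationConfig(seed=seed, n_clusters=6))
            rebuilt = build_tree(cluster_frame(tree), tolerance=0.05)
            rebuilt.validate(tolerance=0.05)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n_clusters = int(rng.integers(2, 8))
        tree, _ = simulate_clone_tree(
            SimulationConfig(seed=4000 + seed, n_clusters=n_clusters, n_samples=5)
        )
        clusters = cluster_frame(tree)
        built = build_tree(clusters, tolerance=0.1)
        got = {c.id: c.parent for c in built.clones.values() if c.parent is not None}
        want = enumerate_canonical_tree(clusters, tolerance=0.1)
        assert got == want


class TestMergeClusters:
    def test_identical_vectors_merge(self):
        merged = merge_close_clusters(
            frame(
                [
                    {"cluster": "A", "n_mutations": 10, "ccf_a": 0.5, "ccf_b": 0.5},
                    {"cluster": "B", "n_mutations": 30, "ccf_a": 0.5, "ccf_b": 0.5},
                ]
            ),
            ccf_distance=0.1,
        )
        assert len(merged) == 1
        assert merged.at[0, "n_mutations"] == 40

    def test_two_discordant_samples_do_not_merge(self):
        merged = merge_close_clusters(
            frame(
                [
                    {"cluster": "A", "n_mutations": 10, "ccf_a": 0.5, "ccf_b": 0.5, "ccf_c": 0.5},
                    {"cluster": "B", "n_mutations": 10, "ccf_a": 0.9, "ccf_b": 0.9, "ccf_c": 0.5},
                ]
            ),
            ccf_distance=0.1,
            max_discordant_samples=1,
        )
        assert len(merged) == 2

    def test_merged_ccfs_are_count_weighted(self):
        merged = merge_close_clusters(
            frame(
                [
                    {"cluster": "A", "n_mutations": 10, "ccf_a": 0.40},
                    {"cluster": "B", "n_mutations": 30, "ccf_a": 0.48},
                ]
            ),
            ccf_distance=0.1,
        )
        assert merged.at[0, "ccf_a"] == pytest.approx(0.46)

    def test_three_mutually_close_clusters_reach_one_fixpoint(self):
        rows = [
            {"cluster": "A", "n_mutations": 10, "ccf_a": 0.50, "ccf_b": 0.30},
            {"cluster": "B", "n_mutations": 10, "ccf_a": 0.55, "ccf_b": 0.33},
            {"cluster": "C", "n_mutations": 10, "ccf_a": 0.58, "ccf_b": 0.36},
        ]
        for order in ([0, 1, 2], [2, 0, 1], [1, 2, 0]):
            merged = merge_close_clusters(
                frame([rows[i] for i in order]), ccf_distance=0.1
            )
            assert len(merged) == 1
            assert merged.at[0, "n_mutations"] == 30
            assert merged.at[0, "ccf_a"] == pytest.approx((0.50 + 0.55 + 0.58) / 3)


class TestDropLowCcf:
    def test_one_high_sample_retains(self):
        kept, dropped = drop_low_ccf_clusters(
            frame([{"cluster": "A", "ccf_a": 0.6, "ccf_b": 0.1}])
        )
        assert dropped == [] and len(kept) == 1

    def test_all_low_drops(self):
        kept, dropped = drop_low_ccf_clusters(
            frame([{"cluster": "A", "ccf_a": 0.3, "ccf_b": 0.2}])
        )
        assert dropped == ["A"] and len(kept) == 0

    def test_gp5_low_ccf_subclones_are_exactly_the_dropped_set(self, gp5):
        clusters = cluster_frame(gp5.tree)
        _, dropped = drop_low_ccf_clusters(clusters)
        # the GP5 subclones that never reach CCF 0.5 in any sample
        assert set(dropped) == {"Aa", "Ab", "Aba", "Baa", "Bc"}


class TestEventAssignment:
    @pytest.fixture()
    def tree(self):
        return CloneTree(
            [
                Clone("T", None, {"a": 1.0, "b": 1.0}, n_snv=100),
                Clone("A", "T", {"a": 0.4, "b": 0.6}, n_snv=50),
                Clone("Aa", "A", {"a": 0.4, "b": 0.6}, n_snv=25),
            ]
        )

    def test_exact_match_has_zero_distance(self, tree):
        cluster, distance = assign_event_to_cluster({"a": 1.0, "b": 1.0}, tree)
        assert cluster == "T" and distance == 0.0

    def test_hand_evaluated_nearest(self, tree):
        cluster, distance = assign_event_to_cluster({"a": 0.5, "b": 0.5}, tree)
        assert cluster == "A"
        assert distance == pytest.approx(np.hypot(0.1, 0.1))

    def test_tie_broken_toward_ancestor(self, tree):
        # A and Aa share identical CCFs; the parent wins the tie
        cluster, _ = assign_event_to_cluster({"a": 0.4, "b": 0.6}, tree)
        assert cluster == "A"

    def test_missing_samples_excluded_pairwise(self, tree):
        cluster, _ = assign_event_to_cluster({"a": 0.4, "b": float("nan")}, tree)
        assert cluster == "A"

    def test_all_missing_returns_unassigned(self, tree):
        cluster, distance = assign_event_to_cluster({"a": float("nan")}, tree)
        assert cluster is None and np.isnan(distance)

    def test_noisy_events_return_generating_cluster(self):
        tree = CloneTree(
            [
                Clone("T", None, {"a": 1.0, "b": 1.0}),
                Clone("A", "T", {"a": 0.7, "b": 0.1}),
                Clone("B", "T", {"a": 0.1, "b": 0.7}),
            ]
        )
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(500):
            target = "A" if rng.uniform() < 0.5 else "B"
            ev = {
                s: tree.ccf(target, s) + rng.normal(0, 0.02)
                for s in tree.samples
            }
            cluster, _ = assign_event_to_cluster(ev, tree)
            hits += cluster == target
        assert hits / 500 >= 0.95


class TestTandemDuplications:
    def test_span_and_type_rules(self):
        svs = pd.DataFrame(
            [
                {"chrom1": "chr1", "pos1": 100, "chrom2": "chr1", "pos2": 200_100, "svtype": "DUP"},
                {"chrom1": "chr1", "pos1": 100, "chrom2": "chr1", "pos2": 6_000_100, "svtype": "DUP"},
                {"chrom1": "chr2", "pos1": 100, "chrom2": "chr2", "pos2": 5_100, "svtype": "DEL"},
                {"chrom1": "chr3", "pos1": 100, "chrom2": "chr4", "pos2": 5_100, "svtype": "DUP"},
            ]
        )
        tds = classify_tandem_duplications(svs)
        assert len(tds) == 1
        assert tds.iloc[0]["span"] == 200_000

    def test_counts_seven_of_ten(self):
        rng = np.random.default_rng(1)
        rows = []
        for i in range(10):
            span = int(rng.integers(10_000, 4_000_000)) if i < 7 else int(6e6 + i)
            rows.append(
                {"chrom1": "chr5", "pos1": 1000, "chrom2": "chr5",
                 "pos2": 1000 + span, "svtype": "DUP"}
            )
        assert len(classify_tandem_duplications(pd.DataFrame(rows))) == 7

    def test_malformed_record_skipped_with_warning(self, caplog):
        svs = pd.DataFrame(
            [
                {"chrom1": "chr1", "pos1": "oops", "chrom2": "chr1", "pos2": 2000, "svtype": "DUP"},
                {"chrom1": "chr1", "pos1": 1000, "chrom2": "chr1", "pos2": 2000, "svtype": "DUP"},
            ]
        )
        with caplog.at_level("WARNING"):
            tds = classify_tandem_duplications(svs)
        assert len(tds) == 1
        assert any("malformed" in rec.message for rec in caplog.records)


class TestJawbreaker:
    def test_truncal_only_sample(self):
        tree = CloneTree([Clone("T", None, {"a": 1.0})])
        assert jawbreaker_layers(tree, "a") == {"T": 1.0}

    def test_hand_evaluated_layers(self):
        tree = CloneTree(
            [
                Clone("T", None, {"a": 1.0}),
                Clone("A", "T", {"a": 0.6}),
                Clone("Aa", "A", {"a": 0.2}),
            ]
        )
        layers = jawbreaker_layers(tree, "a")
        assert layers == pytest.approx({"T": 0.4, "A": 0.4, "Aa": 0.2})

    def test_saturated_parent_has_zero_surface(self):
        tree = CloneTree(
            [
                Clone("T", None, {"a": 1.0}),
                Clone("A", "T", {"a": 0.5}),
                Clone("B", "T", {"a": 0.5}),
            ]
        )
        assert jawbreaker_layers(tree, "a")["T"] == 0.0

    def test_surfaces_nonnegative_and_conserve_mass(self):
        for seed in range(5):
            tree, _ = simulate_clone_tree(SimulationConfig(seed=seed, n_clusters=7))
            for s in tree.samples:
                layers = jawbreaker_layers(tree, s)
                assert all(v >= 0 for v in layers.values())
                assert sum(layers.values()) == pytest.approx(tree.ccf(tree.root, s), abs=1e-9)
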