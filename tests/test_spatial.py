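"""Anatomic tracing on the bundled cases and constructed scenarios."""

import pandas as pd

from clonetrace.spatial import (
    classify_metastatic,
    count_seeding_events,
    descent_closure_report,
    infer_origin,
    seeding_clusters,
    trace_report,
    trace_routes,
)
from clonetrace.trees import Clone, CloneTree

from _oracles import seeding_set_by_construction


class TestClassifyMetastatic:
    def test_gp5_capable_set_is_the_metastatic_branch(self, gp5):
        capable = classify_metastatic(gp5.tree, gp5.anatomy)
        assert set(capable["cluster"]) == {"B", "Ba", "Baa", "Bb", "Bb1", "Bb2"}

    def test_capable_clusters_list_their_seeder_samples(self, gp5):
        capable = classify_metastatic(gp5.tree, gp5.anatomy).set_index("cluster")
        assert capable.loc["Bb1", "seeder_samples"] == ["6-LCA1"]
        assert capable.loc["Bb2", "seeder_samples"] == ["1-RApexCA"]

    def test_below_threshold_met_presence_not_capable(self):
        tree = CloneTree(
            [
                Clone("T", None, {"p": 1.0, "ln": 1.0}),
                Clone("A", "T", {"p": 0.5, "ln": 0.005}),
            ]
        )
        anatomy = pd.DataFrame(
            {"sample": ["p", "ln"], "site_class": ["prostate", "lymph_node"],
             "laterality": ["L", "L"]}
        )
        assert len(classify_metastatic(tree, anatomy)) == 0

    def test_no_extraprostatic_samples_yields_empty_set(self, caplog):
        tree = CloneTree([Clone("T", None, {"p": 1.0}), Clone("A", "T", {"p": 0.5})])
        anatomy = pd.DataFrame(
            {"sample": ["p"], "site_class": ["prostate"], "laterality": ["L"]}
        )
        with caplog.at_level("WARNING"):
            capable = classify_metastatic(tree, anatomy)
        assert len(capable) == 0

    def test_capable_set_closed_under_detectable_descent(self, gp5, gp12):
        for case in (gp5, gp12):
            report = descent_closure_report(case.tree, case.anatomy)
            assert report["in_metastases"].all()


class TestSeedingEvents:
    def test_gp5_minimum_five_events(self, gp5):
        assert count_seeding_events(gp5.tree, gp5.anatomy) == 5
        assert count_seeding_events(gp5.tree, gp5.anatomy, sites=("lymph_node",)) == 5

    def test_gp12_minimum_eight_events(self, gp12):
        assert count_seeding_events(gp12.tree, gp12.anatomy) == 8
        assert count_seeding_events(gp12.tree, gp12.anatomy, sites=("lymph_node",)) == 8

    def test_matches_direct_set_construction_oracle(self, gp5, gp12):
        for case in (gp5, gp12):
            got = seeding_clusters(case.tree, case.anatomy, 0.01)
            want = seeding_set_by_construction(
                case.tree, case.anatomy, 0.01,
                ("seminal_vesicle", "lymph_node"),
            )
            assert got == want

    def test_monotone_in_presence_threshold(self, gp12):
        counts = [
            count_seeding_events(gp12.tree, gp12.anatomy, presence_threshold=t)
            for t in (0.005, 0.01, 0.05, 0.2, 0.5)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_no_metastatic_samples_counts_zero(self):
        tree = CloneTree([Clone("T", None, {"p": 1.0}), Clone("A", "T", {"p": 0.5})])
        anatomy = pd.DataFrame(
            {"sample": ["p"], "site_class": ["prostate"], "laterality": ["L"]}
        )
        assert count_seeding_events(tree, anatomy) == 0

    def test_count_bounded_by_clusters_detected_in_mets(self, gp5):
        detected = {
            c
            for c in gp5.tree.clones
            if any(
                gp5.tree.ccf(c, s) >= 0.01
                for s in ("LPelvicLNMet1", "LPelvicLNMet2", "RPelvicLNMet1")
            )
        }
        assert count_seeding_events(gp5.tree, gp5.anatomy) <= len(detected)


class TestOrigin:
    def test_gp5_origin_is_the_left_posterior_mid_apex_pair(self, gp5):
        origin, table = infer_origin(gp5.tree, gp5.anatomy)
        assert set(origin) == {"6-LCA1", "7-LCA2"}

    def test_gp12_origin_is_left_mid_apical(self, gp12):
        origin, _ = infer_origin(gp12.tree, gp12.anatomy)
        assert origin == ["2-LMidApicalCA"]

    def test_ranking_descends_by_truncal_fraction(self, gp12):
        _, table = infer_origin(gp12.tree, gp12.anatomy)
        fractions = table["truncal_fraction"].tolist()
        assert fractions == sorted(fractions, reverse=True)

    def test_single_sample_input_returns_it(self):
        tree = CloneTree([Clone("T", None, {"p": 1.0})])
        anatomy = pd.DataFrame(
            {"sample": ["p"], "site_class": ["prostate"], "laterality": ["L"]}
        )
        origin, _ = infer_origin(tree, anatomy)
        assert origin == ["p"]


class TestRoutes:
    def test_gp12_right_ln_dominant_cluster_sources_from_right_sv(self, gp12):
        routes = trace_routes(gp12.tree, gp12.anatomy)
        row = routes[(routes.cluster == "Cba2") & (routes.met_sample == "RPelvicLNMet1")]
        assert row.iloc[0]["sources"] == ["7-RSVBase"]
        assert row.iloc[0]["verdict"] == "ipsilateral"

    def test_no_contralateral_routes_in_either_case(self, gp5, gp12):
        for case in (gp5, gp12):
            routes = trace_routes(case.tree, case.anatomy)
            assert not (routes["verdict"] == "contralateral").any()

    def test_dominant_met_lineages_are_strictly_ipsilateral(self, gp5):
        routes = trace_routes(gp5.tree, gp5.anatomy).set_index(["cluster", "met_sample"])
        for cluster, met in [
            ("Bb1", "LPelvicLNMet1"),
            ("Bb1", "LPelvicLNMet2"),
            ("Bb2", "RPelvicLNMet1"),
            ("Ba", "LPelvicLNMet1"),
            ("Baa", "LPelvicLNMet2"),
        ]:
            assert routes.loc[(cluster, met), "verdict"] == "ipsilateral"

    def test_met_private_cluster_routes_via_ancestor(self, gp12):
        routes = trace_routes(gp12.tree, gp12.anatomy)
        row = routes[(routes.cluster == "Cba2a")].iloc[0]
        assert row["flag"] == "met-private"
        assert row["source_cluster"] == "Cba2"
        assert row["verdict"] == "ipsilateral"

    def test_bilateral_source_is_ambiguous(self):
        tree = CloneTree(
            [
                Clone("T", None, {"l": 1.0, "r": 1.0, "ln": 1.0}),
                Clone("A", "T", {"l": 0.5, "r": 0.5, "ln": 0.8}),
            ]
        )
        anatomy = pd.DataFrame(
            {
                "sample": ["l", "r", "ln"],
                "site_class": ["prostate", "prostate", "lymph_node"],
                "laterality": ["L", "R", "L"],
            }
        )
        routes = trace_routes(tree, anatomy)
        assert routes.iloc[0]["verdict"] == "ambiguous-bilateral"

    def test_contralateral_only_source_detected(self):
        tree = CloneTree(
            [
                Clone("T", None, {"r": 1.0, "ln": 1.0}),
                Clone("A", "T", {"r": 0.5, "ln": 0.8}),
            ]
        )
        anatomy = pd.DataFrame(
            {
                "sample": ["r", "ln"],
                "site_class": ["prostate", "lymph_node"],
                "laterality": ["R", "L"],
            }
        )
        routes = trace_routes(tree, anatomy)
        assert routes.iloc[0]["verdict"] == "contralateral"


class TestTraceReport:
    def test_report_bundles_both_seeding_tallies(self, gp12):
        report = trace_report(gp12.tree, gp12.anatomy)
        assert report.seeding_events_extraprostatic == 8
        assert report.seeding_events_lymph_node == 8
        payload = report.to_dict()
        assert payload["seeding_events"] == {
            "extraprostatic": 8, "lymph_node_only": 8,
        }

    def test_report_serialises_to_json(self, gp5, tmp_path):
        report = trace_report(gp5.tree, gp5.anatomy)
        out = tmp_path / "trace.json"
        report.to_json(out)
        import json

        payload = json.loads(out.read_text())
        assert payload["origin"] == ["6-LCA1", "7-LCA2"]
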