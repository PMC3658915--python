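import pytest

from metnet import (
    FluxDistribution,
    UsageError,
    build_variation_network,
    compare_networks,
    degree_report,
    filter_network_by_simulation,
    remove_vertices,
)
from metnet.compare import EXCLUSIVE_B, FLUX_CHANGE, PARTICIPANT


@pytest.fixture
def wt():
    return FluxDistribution("wild-type", {"R1": 0.0, "R2": 1.0, "R3": 1.0})


@pytest.fixture
def mutant():
    return FluxDistribution("mutant", {"R1": 2.0, "R2": 0.5, "R3": 0.5})


@pytest.fixture
def snapshots(diamond_rc, wt, mutant):
    net_a = filter_network_by_simulation(diamond_rc, wt, 1e-6)
    net_b = filter_network_by_simulation(diamond_rc, mutant, 1e-6)
    return net_a, net_b


def degrees(net):
    rows = degree_report(net).rows
    return dict(zip(rows["id"], (float(x) for x in rows["total_degree"])))


class TestCompareNetworks:
    def test_degree_comparison_after_filtering(self, diamond_rc):
        filtered = remove_vertices(diamond_rc, {"R1"})
        report = compare_networks(
            diamond_rc, filtered,
            {"degree": degrees(diamond_rc)}, {"degree": degrees(filtered)},
        )
        assert report.metrics_compared == ["degree"]
        table = report.vertex_table.set_index("id")
        only_a = set(table[table["presence"] == "only_a"].index)
        assert only_a == {"R1"}
        row_a = table.loc["A"]
        assert (row_a["value_a"], row_a["value_b"], row_a["delta"]) == (3, 1, -2)

    def test_self_comparison_all_zero(self, diamond_rc):
        report = compare_networks(
            diamond_rc, diamond_rc,
            {"degree": degrees(diamond_rc)}, {"degree": degrees(diamond_rc)},
        )
        assert (report.vertex_table["delta"] == 0).all()
        assert (report.vertex_table["presence"] == "both").all()

    def test_metric_intersection_rule(self, diamond_rc):
        report = compare_networks(
            diamond_rc, diamond_rc,
            {"degree": degrees(diamond_rc)},
            {"degree": degrees(diamond_rc), "closeness": {}},
        )
        assert report.metrics_compared == ["degree"]

    def test_no_shared_metrics_is_not_an_error(self, diamond_rc):
        report = compare_networks(diamond_rc, diamond_rc, {"x": {}}, {"y": {}})
        assert report.metrics_compared == []
        assert not report.vertex_table.empty  # structural diff still present

    def test_global_metrics_compared(self, diamond_rc):
        report = compare_networks(
            diamond_rc, diamond_rc, {"diameter": 4.0}, {"diameter": 4.0}
        )
        assert report.global_table.iloc[0].tolist() == ["diameter", 4.0, 4.0]

    def test_provenance_mismatch_flagged(self, diamond_rc):
        other = diamond_rc.copy(provenance="model:other")
        report = compare_networks(diamond_rc, other)
        assert report.provenance_warning is not None


class TestVariationNetwork:
    def test_exclusivity_only(self, diamond_rc, snapshots, wt, mutant):
        net = build_variation_network(
            diamond_rc, *snapshots, wt, mutant, use_exclusivity=True
        )
        assert set(net.vertices()) == {"R1", "A", "B", "C"}
        assert net.n_edges == 6
        assert net.vertex_metadata("R1")["tna_reason"] == EXCLUSIVE_B
        assert net.vertex_metadata("R1")["tna_delta"] == 2.0
        for m in ("A", "B", "C"):
            assert net.vertex_metadata(m)["tna_reason"] == PARTICIPANT

    def test_flux_variation_only(self, diamond_rc, snapshots, wt, mutant):
        net = build_variation_network(
            diamond_rc, *snapshots, wt, mutant,
            use_exclusivity=False, flux_threshold=0.4,
        )
        # R1 is excluded: it is not present in both snapshots
        assert set(net.vertices()) == {"R2", "R3", "A", "E", "B"}
        for r in ("R2", "R3"):
            assert net.vertex_metadata(r)["tna_reason"] == FLUX_CHANGE
            assert net.vertex_metadata(r)["tna_delta"] == -0.5

    def test_combined_criteria_union(self, diamond_rc, snapshots, wt, mutant):
        net = build_variation_network(
            diamond_rc, *snapshots, wt, mutant,
            use_exclusivity=True, flux_threshold=0.4,
        )
        assert set(net.vertices()) == {"A", "B", "C", "E", "R1", "R2", "R3"}

    def test_subgraph_of_base(self, diamond_rc, snapshots, wt, mutant):
        net = build_variation_network(
            diamond_rc, *snapshots, wt, mutant,
            use_exclusivity=True, flux_threshold=0.4,
        )
        base_edges = {(e.source, e.target, e.set_label) for e in diamond_rc.edges()}
        for e in net.edges():
            assert (e.source, e.target, e.set_label) in base_edges
            assert net.has_vertex(e.source) and net.has_vertex(e.target)

    def test_threshold_monotonicity(self, diamond_rc, snapshots, wt, mutant):
        def flux_change_set(threshold):
            net = build_variation_network(
                diamond_rc, *snapshots, wt, mutant,
                use_exclusivity=False, flux_threshold=threshold,
            )
            return {
                v for v in net.vertices()
                if net.vertex_metadata(v).get("tna_reason") == FLUX_CHANGE
            }

        assert flux_change_set(0.6) <= flux_change_set(0.4) <= flux_change_set(0.1)

    def test_strictly_exceeds(self, diamond_rc, snapshots, wt, mutant):
        net = build_variation_network(
            diamond_rc, *snapshots, wt, mutant,
            use_exclusivity=False, flux_threshold=0.5,
        )
        assert net.n_vertices == 0  # |delta| = 0.5 does not exceed 0.5

    def test_identical_conditions_give_empty_network(self, diamond_rc, wt):
        snap = filter_network_by_simulation(diamond_rc, wt, 1e-6)
        net = build_variation_network(
            diamond_rc, snap, snap, wt, wt,
            use_exclusivity=True, flux_threshold=0.1,
        )
        assert net.n_vertices == 0 and net.n_edges == 0

    def test_percentage_threshold(self, diamond_rc, snapshots, wt, mutant):
        # R2: |delta|=0.5 vs reference |flux_a|=1.0 -> 50% change
        net = build_variation_network(
            diamond_rc, *snapshots, wt, mutant,
            use_exclusivity=False, flux_threshold=40.0, percentage=True,
        )
        assert {"R2", "R3"} <= set(net.vertices())
        net60 = build_variation_network(
            diamond_rc, *snapshots, wt, mutant,
            use_exclusivity=False, flux_threshold=60.0, percentage=True,
        )
        assert net60.n_vertices == 0

    def test_both_criteria_disabled_rejected(self, diamond_rc, snapshots, wt, mutant):
        with pytest.raises(UsageError):
            build_variation_network(
                diamond_rc, *snapshots, wt, mutant, use_exclusivity=False
            )
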