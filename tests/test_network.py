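import itertools
import math
from collections import Counter

import networkx as nx
import numpy as np
import pytest

from sicklemark import (
    BiomarkerNetwork,
    CorrelationEdge,
    build_group_network,
    build_network,
    export_edge_list,
    find_triads,
    network_summary,
    spearman,
    taylor_category,
)
from sicklemark.network import UndefinedCorrelationError, read_edge_list_tsv
from tests.conftest import make_cohort


# -- independent oracle: Spearman rho and exact p from first principles --

def oracle_distribution(n):
    """Null rho distribution over all n! permutations via the
    sum-of-squared-rank-differences identity rho = 1 - 6S/(n^3 - n)."""
    rhos = Counter()
    for perm in itertools.permutations(range(1, n + 1)):
        s = sum((i + 1 - p) ** 2 for i, p in enumerate(perm))
        rhos[1 - 6 * s / (n**3 - n)] += 1
    return rhos


def oracle_p(rhos, r):
    total = sum(rhos.values())
    extreme = sum(c for v, c in rhos.items() if abs(v) >= abs(r) - 1e-12)
    return extreme / total


class TestSpearman:
    def test_perfect_monotone(self):
        r, _, n = spearman([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert r == pytest.approx(1.0) and n == 5

    def test_perfect_antitone(self):
        r, _, _ = spearman([1, 2, 3, 4, 5], [10, 8, 6, 4, 2])
        assert r == pytest.approx(-1.0)

    def test_exact_p_n4_monotone(self):
        # only 2 of the 24 rank permutations reach |rho| = 1
        _, p, _ = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert p == pytest.approx(2 / 24)

    def test_exact_p_matches_permutation_oracle(self):
        rng = np.random.default_rng(0)
        for n in (4, 5, 6):
            rhos = oracle_distribution(n)
            for _ in range(20):
                y = rng.permutation(n).astype(float)
                r, p, _ = spearman(np.arange(n, dtype=float), y)
                assert p == pytest.approx(oracle_p(rhos, r))

    def test_pairwise_deletion_of_missing_values(self):
        r, _, n = spearman(
            [1.0, 2.0, math.nan, 4.0, 5.0], [2.0, 4.0, 6.0, math.nan, 10.0]
        )
        assert n == 3 and r == pytest.approx(1.0)

    def test_too_few_pairs_error(self):
        with pytest.raises(ValueError, match="complete pairs"):
            spearman([1.0, 2.0], [3.0, 4.0])

    def test_zero_variance_error(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_r_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        r1, p1, _ = spearman(x, y)
        r2, p2, _ = spearman(np.exp(x), y**3)
        assert r1 == pytest.approx(r2) and p1 == pytest.approx(p2)


class TestTaylorCategory:
    @pytest.mark.parametrize(
        "r,expected",
        [
            (0.70, ("positive", "strong")),
            (0.50, ("positive", "moderate")),
            (0.35, ("positive", "weak")),
            (-0.10, ("negative", "weak")),
            (0.36, ("positive", "moderate")),   # closed lower bound
            (0.68, ("positive", "moderate")),   # strong is strictly above
            (-0.69, ("negative", "strong")),
            (1.0, ("positive", "strong")),
        ],
    )
    def test_boundaries(self, r, expected):
        assert taylor_category(r) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            taylor_category(1.5)


class TestBuildNetwork:
    def test_perfect_pair_gives_one_strong_edge(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(size=30)
        table = two_marker_cohort(x, 2 * x)
        net = build_group_network(table, "SCA")
        assert len(net.edges) == 1
        assert (net.edges[0].sign, net.edges[0].strength) == (
            "positive", "strong",
        )

    def test_n4_perfect_pair_not_significant(self):
        # exact p = 2/24 > 0.05, so even rho = 1 yields no edge
        x = np.array([1.0, 2.0, 3.0, 4.0])
        table = two_marker_cohort(x, 2 * x)
        net = build_group_network(table, "SCA")
        assert net.edges == []

    def test_constant_marker_skipped_with_warning(self, caplog):
        rng = np.random.default_rng(3)
        x = rng.uniform(size=10)
        table = two_marker_cohort(x, np.full(10, 7.0))
        with caplog.at_level("WARNING"):
            net = build_group_network(table, "SCA")
        assert net.edges == []
        assert any("skipping pair" in r.message for r in caplog.records)

    def test_edge_count_bounded_by_pairs(self):
        rng = np.random.default_rng(4)
        base = rng.uniform(size=40)
        cols = {f"M{i}": base + rng.normal(0, 1e-3, 40) for i in range(4)}
        table = multi_marker_cohort(cols)
        net = build_group_network(table, "SCA")
        assert len(net.edges) == 6  # all C(4,2) pairs co-monotone


class TestNetworkContainers:
    def edge(self, a, b, r=0.9):
        sign, strength = taylor_category(r)
        return CorrelationEdge((a, b), r, 0.001, 30, sign, strength)

    def test_duplicate_edges_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            BiomarkerNetwork(
                "SCA", ["A", "B"],
                [self.edge("A", "B"), self.edge("B", "A")],
            )

    def test_summary_counts_partition_edges(self):
        net = BiomarkerNetwork(
            "SCA", ["A", "B", "C"],
            [self.edge("A", "B", 0.9), self.edge("B", "C", -0.5)],
        )
        s = network_summary(net)
        assert s["edge_counts"]["positive_strong"] == 1
        assert s["edge_counts"]["negative_moderate"] == 1
        assert sum(s["edge_counts"].values()) == s["n_edges"] == 2
        assert s["n_components"] == 1

    def test_empty_network_summary(self):
        s = network_summary(BiomarkerNetwork("HD", [], []))
        assert s["n_edges"] == 0 and s["n_components"] == 0

    def test_triangle_is_one_triad(self):
        net = BiomarkerNetwork(
            "SCA", ["A", "B", "C"],
            [self.edge("A", "B"), self.edge("B", "C"), self.edge("A", "C")],
        )
        triads = find_triads(net)
        assert len(triads) == 1
        assert triads[0]["nodes"] == ("A", "B", "C")

    def test_path_has_no_triads(self):
        net = BiomarkerNetwork(
            "SCA", ["A", "B", "C"],
            [self.edge("A", "B"), self.edge("B", "C")],
        )
        assert find_triads(net) == []

    def test_complete_graph_on_four_nodes_has_four_triads(self):
        nodes = ["A", "B", "C", "D"]
        edges = [
            self.edge(a, b) for a, b in itertools.combinations(nodes, 2)
        ]
        net = BiomarkerNetwork("SCA", nodes, edges)
        assert len(find_triads(net)) == 4  # C(4,3)


class TestExport:
    def small_net(self):
        sign, strength = taylor_category(0.9)
        return BiomarkerNetwork(
            "SCA", ["A", "B"],
            [CorrelationEdge(("A", "B"), 0.9, 0.001, 30, sign, strength)],
        )

    def test_sif_line(self, tmp_path):
        path = tmp_path / "net.sif"
        export_edge_list(self.small_net(), path, format="sif")
        assert path.read_text() == "A positive_strong B\n"

    def test_tsv_round_trip(self, tmp_path):
        net = self.small_net()
        path = tmp_path / "net.tsv"
        export_edge_list(net, path, format="tsv")
        back = read_edge_list_tsv(path, group="SCA")
        assert back.edges == net.edges

    def test_graphml_loads_with_attributes(self, tmp_path):
        path = tmp_path / "net.graphml"
        export_edge_list(self.small_net(), path, format="graphml")
        g = nx.read_graphml(path)
        assert g.edges["A", "B"]["strength"] == "strong"
        assert g.edges["A", "B"]["r"] == pytest.approx(0.9)

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            export_edge_list(self.small_net(), tmp_path / "x", format="xml")


def two_marker_cohort(x, y):
    return multi_marker_cohort({"MA": x, "MB": y})


def multi_marker_cohort(cols):
    from sicklemark import (
        BiomarkerDescriptor, CohortTable, Measurement, SubjectRecord,
    )

    names = list(cols)
    n = len(cols[names[0]])
    reg = [BiomarkerDescriptor(m, "cytokine", "mfi") for m in names]
    subjects = [
        SubjectRecord(
            f"SCA{i}", "SCA",
            measurements={
                m: Measurement(float(cols[m][i])) for m in names
            },
        )
        for i in range(n)
    ]
    return CohortTable(registry=reg, subjects=subjects)
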