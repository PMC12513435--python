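import numpy as np
import pytest

from concise_networks import (
    PathCorpus,
    StateNetwork,
    TrigramCounts,
    assemble_network,
    build_first_order,
    build_second_order,
    disparity_backbone,
    export_infomap_states,
    extract_trigram_counts,
    jaccard_similarity,
    matrix_flow_overlap,
    posterior_dynamics,
    read_infomap_states,
    split_node,
    trim_state_edges,
)
from concise_networks.nmf import StateSplit


def ring_counts(n: int = 5, per: float = 10.0) -> dict[str, TrigramCounts]:
    """Trigram counts of a deterministic walk around a labeled ring."""
    labels = [f"N{i}" for i in range(n)]
    pc = PathCorpus([(tuple(labels[(s + t) % n] for t in range(4)), per) for s in range(n)])
    return extract_trigram_counts(pc)


def two_split_network():
    """Two centers with hand-set splits: i (rank 2) feeding j (rank 2)."""
    split_i = StateSplit(
        center="i",
        rank=2,
        Xin=np.array([[1.0, 0.0], [0.0, 1.0]]),
        Xout=np.array([[0.5, 0.2], [0.5, 0.8]]),  # successors (j, z)
        overlap=1.0,
        loss=0.0,
        predecessors=("u", "v"),
        successors=("j", "z"),
    )
    split_j = StateSplit(
        center="j",
        rank=2,
        Xin=np.array([[0.8, 0.2]]),  # single predecessor: i
        Xout=np.array([[1.0, 0.0], [0.0, 1.0]]),
        overlap=1.0,
        loss=0.0,
        predecessors=("i",),
        successors=("q", "w"),
    )
    return {"i": split_i, "j": split_j}


class TestAssembleNetwork:
    def test_edge_weight_is_product_of_out_and_in_probabilities(self):
        net = assemble_network(two_split_network())
        sid = {(phys, alpha): s for s, phys, alpha in net.states}
        weights = {(s, t): w for s, t, w in net.edges}
        # P(alpha_i -> j) = 0.5, P(i -> beta0_j) = 0.8 -> 0.4
        assert weights[(sid[("i", 0)], sid[("j", 0)])] == pytest.approx(0.4)
        assert weights[(sid[("i", 0)], sid[("j", 1)])] == pytest.approx(0.1)

    def test_flow_into_split_successor_sums_to_out_probability(self):
        net = assemble_network(two_split_network())
        sid = {(phys, alpha): s for s, phys, alpha in net.states}
        weights = {(s, t): w for s, t, w in net.edges}
        into_j = sum(
            weights.get((sid[("i", 0)], sid[("j", b)]), 0.0) for b in range(2)
        )
        assert into_j == pytest.approx(0.5)

    def test_out_weights_sum_to_one(self):
        net = assemble_network(two_split_network())
        out = net.out_weights()
        for sid, phys, _ in net.states:
            if phys in ("i", "j"):
                assert out[sid] == pytest.approx(1.0)

    def test_unsplit_successors_get_single_passthrough_state(self):
        net = assemble_network(two_split_network())
        for label in ("z", "q", "w", "u", "v"):
            assert len(net.physical_map[label]) == 1

    def test_unobserved_predecessor_flow_dropped_and_logged(self, caplog):
        splits = two_split_network()
        # make z a split center that never observed i as a predecessor
        splits["z"] = StateSplit(
            center="z",
            rank=1,
            Xin=np.array([[1.0]]),
            Xout=np.array([[1.0]]),
            overlap=1.0,
            loss=0.0,
            predecessors=("other",),
            successors=("q",),
        )
        with caplog.at_level("INFO"):
            net = assemble_network(splits)
        assert "no observed trigram" in caplog.text
        out = net.out_weights()
        sid = {(phys, alpha): s for s, phys, alpha in net.states}
        assert out[sid[("i", 0)]] == pytest.approx(0.5)  # mass into z dropped


class TestBuildFirstOrder:
    def test_one_state_per_physical_node(self):
        counts = ring_counts()
        net = build_first_order(counts)
        assert all(len(ids) == 1 for ids in net.physical_map.values())

    def test_out_distribution_is_first_order_mle_at_mu_zero(self):
        pc = PathCorpus([(("A", "B", "C"), 3.0), (("D", "B", "E"), 1.0)])
        counts = extract_trigram_counts(pc)
        net = build_first_order(counts, mu_policy=0.0)
        sid = {phys: ids[0] for phys, ids in net.physical_map.items()}
        weights = {(s, t): w for s, t, w in net.edges}
        assert weights[(sid["B"], sid["C"])] == pytest.approx(0.75)
        assert weights[(sid["B"], sid["E"])] == pytest.approx(0.25)

    def test_collapse_recovers_first_order_weights(self):
        """Aggregating any rank's states by physical node with entry-flow
        weights reproduces the first-order transition weights."""
        counts = ring_counts()
        fo = build_first_order(counts, mu_policy=0.0)
        so = build_second_order(counts, mu_policy=0.0)
        fo_weights = {}
        for s, t, w in fo.edges:
            fo_weights[(fo.states[s][1], fo.states[t][1])] = w
        # entry flow of state beta of center j: sum_i (n_i/sum n) Xin[i, beta]
        collapsed: dict[tuple[str, str], float] = {}
        state_meta = {sid: (phys, alpha) for sid, phys, alpha in so.states}
        entry = {}
        for center, tc in counts.items():
            n = tc.n / tc.n.sum()
            for alpha in range(len(tc.predecessors)):
                entry[(center, alpha)] = n[alpha]  # Xin = I for second order
        for s, t, w in so.edges:
            phys_s, alpha_s = state_meta[s]
            phys_t, _ = state_meta[t]
            key = (phys_s, phys_t)
            collapsed[key] = collapsed.get(key, 0.0) + entry[(phys_s, alpha_s)] * w
        for key, w in fo_weights.items():
            assert collapsed[key] == pytest.approx(w, abs=1e-9)


class TestBuildSecondOrder:
    def test_one_state_per_observed_predecessor(self):
        counts = ring_counts()
        net = build_second_order(counts)
        for center, tc in counts.items():
            assert len(net.physical_map[center]) == len(tc.predecessors)

    def test_exact_flow_overlap(self):
        counts = ring_counts()
        for center, tc in counts.items():
            dyn = posterior_dynamics(tc, "auto")
            Xhat = dyn.X @ np.eye(dyn.X.shape[1])
            assert matrix_flow_overlap(dyn.X, Xhat, dyn.n) == pytest.approx(1.0)

    def test_state_count_matches_undirected_double_cover(self):
        # union graph with E undirected edges -> 2E second-order states
        pc = PathCorpus(
            [(("A", "B", "A", "C", "A", "B"), 1.0), (("C", "B", "C", "A"), 1.0)]
        )
        counts = extract_trigram_counts(pc)
        net = build_second_order(counts)
        n_states = sum(len(tc.predecessors) for tc in counts.values())
        assert net.n_states >= n_states  # plus pass-through endpoints
        assert sum(len(net.physical_map[c]) for c in counts) == n_states


class TestTrimStateEdges:
    def test_threshold_arithmetic(self):
        # r=2, sigma=0.05 -> threshold 0.025: 0.024 removed, 0.026 kept
        split = StateSplit(
            center="j",
            rank=2,
            Xin=np.array([[0.024, 0.976], [0.026, 0.974]]),
            Xout=np.array([[0.5, 0.5], [0.5, 0.5]]),
            overlap=1.0,
            loss=0.0,
            predecessors=("a", "b"),
            successors=("x", "y"),
        )
        net = trim_state_edges({"j": split}, sigma=0.05)
        sid = {(phys, alpha): s for s, phys, alpha in net.states}
        # predecessor a's 0.024 entry dropped -> its in-split renormalizes to state 1
        # successor side unchanged (all shares 0.5 >= 0.025)
        weights = {(s, t): w for s, t, w in net.edges}
        assert (sid[("j", 0)], sid[("x", 0)]) in weights

    def test_sigma_to_zero_keeps_all_positive_edges(self):
        counts = ring_counts()
        splits = {
            c: split_node(posterior_dynamics(tc, 0.0), 1) for c, tc in counts.items()
        }
        net_plain = assemble_network(splits)
        net_trim = trim_state_edges(splits, sigma=1e-12)
        assert sorted(net_plain.edges) == pytest.approx(sorted(net_trim.edges))

    def test_rank_one_below_all_entries_unchanged(self):
        counts = ring_counts()
        splits = {
            c: split_node(posterior_dynamics(tc, 0.0), 1) for c, tc in counts.items()
        }
        net = trim_state_edges(splits, sigma=0.01)
        for s, t, w in net.edges:
            assert w > 0

    def test_out_weights_renormalized_after_trim(self):
        # successor z takes only ~1.4% of its flow from state 0 (< 0.1/2),
        # so the edge (j,0) -> z is trimmed and the column renormalized
        split = StateSplit(
            center="j",
            rank=2,
            Xin=np.array([[1.0, 0.0], [0.0, 1.0]]),
            Xout=np.array([[0.9, 0.1], [0.09, 0.2], [0.01, 0.7]]),
            overlap=1.0,
            loss=0.0,
            predecessors=("a", "b"),
            successors=("x", "y", "z"),
        )
        net = trim_state_edges({"j": split}, sigma=0.1)  # threshold 0.05
        out = net.out_weights()
        sid = {(phys, alpha): s for s, phys, alpha in net.states}
        assert out[sid[("j", 0)]] == pytest.approx(1.0)
        assert out[sid[("j", 1)]] == pytest.approx(1.0)
        weights = {(s, t): w for s, t, w in net.edges}
        assert (sid[("j", 0)], sid[("z", 0)]) not in weights
        assert weights[(sid[("j", 0)], sid[("x", 0)])] == pytest.approx(0.9 / 0.99)


class TestDisparityBackbone:
    def _star(self, weights):
        states = [(0, "hub", 0)] + [(i + 1, f"leaf{i}", 0) for i in range(len(weights))]
        edges = [(0, i + 1, w) for i, w in enumerate(weights)]
        return StateNetwork(states=states, edges=edges)

    def test_dominant_edge_survives_its_out_star(self):
        net = self._star([0.98, 0.01, 0.01])
        kept, report = disparity_backbone(net, 0.01)
        kept_weights = sorted(w for _, _, w in kept.edges)
        # scores: (1-0.98)^2 = 4e-4 < 0.01 keeps 0.98; 0.9801 fails out-star,
        # but each leaf's in-star has degree 1 -> all edges ultimately kept
        assert 0.98 in kept_weights
        assert report.edges_before == 3

    def test_degree_one_stars_keep_their_edge(self):
        net = self._star([1.0])
        kept, _ = disparity_backbone(net, 0.001)
        assert len(kept.edges) == 1

    def test_threshold_close_to_one_keeps_everything(self):
        net = self._star([0.5, 0.3, 0.2])
        kept, report = disparity_backbone(net, 0.999999)
        assert report.edges_after == report.edges_before

    def test_out_star_scores_match_closed_form(self):
        # bypass the in-star rescue by giving every leaf in-degree 2
        states = [(0, "hub", 0), (1, "hub2", 0)] + [(i + 2, f"l{i}", 0) for i in range(3)]
        edges = [(0, i + 2, w) for i, w in enumerate([0.98, 0.01, 0.01])]
        edges += [(1, i + 2, 1.0 / 3) for i in range(3)]
        net = StateNetwork(states=states, edges=edges)
        kept, _ = disparity_backbone(net, 0.01)
        hub_edges = [(s, t, w) for s, t, w in kept.edges if s == 0]
        assert [w for _, _, w in hub_edges] == [0.98]

    def _skewed_net(self, seed=0, conc=0.3):
        rng = np.random.default_rng(seed)
        states = [(i, f"n{i}", 0) for i in range(12)]
        edges = []
        for s in range(12):
            targets = rng.choice([t for t in range(12) if t != s], size=5, replace=False)
            raw = rng.dirichlet(np.ones(5) * conc)
            edges += [(s, int(t), float(w)) for t, w in zip(targets, raw) if w > 1e-9]
        return StateNetwork(states=states, edges=edges)

    def test_idempotent_on_strongly_filtered_instance(self):
        # idempotence is instance-dependent in general (renormalized p and
        # reduced star degree move scores in opposite directions); in the
        # strict-threshold regime with skewed weights it holds
        net = self._skewed_net(seed=0, conc=0.3)
        once, _ = disparity_backbone(net, 0.01)
        twice, _ = disparity_backbone(once, 0.01)
        assert sorted(once.edges) == sorted(twice.edges)

    def test_output_edges_are_a_subset_of_input(self):
        net = self._skewed_net(seed=1)
        kept, report = disparity_backbone(net, 0.05)
        assert set(kept.edges) <= set(net.edges)
        assert report.edges_after == len(kept.edges)
        assert kept.states == net.states

    def test_weak_connectivity_repair(self):
        # a weak bridge that fails the filter must be re-added
        states = [(i, f"n{i}", 0) for i in range(6)]
        edges = []
        for s, t_range in ((0, (1, 2)), (3, (4, 5))):
            for t in t_range:
                edges.append((s, t, 0.5))
        edges.append((2, 3, 1e-6))  # bridge
        edges.append((2, 0, 1.0))
        net = StateNetwork(states=states, edges=edges)
        kept, report = disparity_backbone(net, 0.5)
        g_edges = {(s, t) for s, t, _ in kept.edges}
        assert (2, 3) in g_edges
        assert report.edges_after <= report.edges_before


class TestJaccard:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ({"a", "b"}, {"a", "b"}, 1.0),
            ({"a"}, {"b"}, 0.0),
            ({"a", "b"}, {"b", "c"}, 1 / 3),
            (set(), set(), 0.0),
        ],
    )
    def test_values(self, a, b, expected):
        assert jaccard_similarity(a, b) == pytest.approx(expected)


class TestInfomapExport:
    def test_minimal_file_sections(self, tmp_path):
        net = StateNetwork(states=[(0, "A", 0)], edges=[(0, 0, 1.0)])
        f = tmp_path / "states.net"
        export_infomap_states(net, f)
        text = f.read_text()
        assert "*Vertices" in text and "*States" in text and "*Links" in text
        assert text.count("\n1 1 ") >= 1

    def test_round_trip_recovers_edges(self, tmp_path):
        counts = ring_counts()
        net = build_first_order(counts)
        f = tmp_path / "states.net"
        export_infomap_states(net, f)
        back = read_infomap_states(f)
        orig = {(net.states[s][1], net.states[t][1]): w for s, t, w in net.edges}
        rt = {(back.states[s][1], back.states[t][1]): w for s, t, w in back.edges}
        assert set(orig) == set(rt)
        for key in orig:
            assert rt[key] == pytest.approx(orig[key], rel=1e-9)

    def test_first_order_export_one_state_per_vertex(self, tmp_path):
        net = build_first_order(ring_counts())
        f = tmp_path / "fo.net"
        export_infomap_states(net, f)
        lines = f.read_text().splitlines()
        n_vertices = lines.index("*States") - lines.index("*Vertices") - 1
        n_states = lines.index("*Links") - lines.index("*States") - 1
        assert n_vertices == n_states
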