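"""OTU clustering, prevalence filter, Zi-Pi roles, and wanted-list assembly."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mdmcensus.catalog import Category
from mdmcensus.samples import AmpliconTable
from mdmcensus.wanted import (
    OTUTable,
    Role,
    _role,
    assemble_wanted_list,
    build_otu_table,
    cluster_otus,
    cross_environment_max,
    detect_modules,
    flag_underrepresented_phyla,
    node_topology,
    prevalence_filter,
)

BASE = ("ACGGTTCAAC" * 9)


def _sub(seq, positions):
    chars = list(seq)
    for pos in positions:
        chars[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chars[pos]]
    return "".join(chars)


class TestClusterOtus:
    def test_identical_sequences_one_otu(self):
        _, membership = cluster_otus({"a": BASE, "b": BASE}, {"a": 2, "b": 1})
        assert len(membership) == 1
        assert sorted(next(iter(membership.values()))) == ["a", "b"]

    def test_hamming_two_joins_three_splits(self):
        near = _sub(BASE, [0, 1])
        far = _sub(BASE, [0, 1, 2])
        _, m2 = cluster_otus({"a": BASE, "b": near}, {"a": 2, "b": 1})
        assert len(m2) == 1
        _, m3 = cluster_otus({"a": BASE, "b": far}, {"a": 2, "b": 1})
        assert len(m3) == 2

    def test_abundance_order_changes_clustering(self):
        # d(A,B)=2, d(B,C)=2, d(A,C)=4: greedy outcome depends on which
        # sequence founds the first centroid
        a, b, c = _sub(BASE, [0, 1]), BASE, _sub(BASE, [2, 3])
        seqs = {"A": a, "B": b, "C": c}
        _, m_b_first = cluster_otus(seqs, {"B": 3, "A": 2, "C": 1})
        assert len(m_b_first) == 1  # B absorbs both neighbors
        _, m_a_first = cluster_otus(seqs, {"A": 3, "C": 2, "B": 1})
        assert len(m_a_first) == 2  # A and C too far apart; B joins A

    def test_matches_brute_force_greedy_oracle(self):
        rng = np.random.default_rng(12)
        seqs, abund = {}, {}
        for i in range(30):
            if i % 3 and seqs:
                parent = seqs[f"t{rng.integers(i)}"]
                k = int(rng.integers(0, 4))
                s = _sub(parent, rng.choice(90, size=k, replace=False)) if k \
                    else parent
            else:
                s = "".join(rng.choice(list("ACGT"), size=90))
            seqs[f"t{i}"] = s
            abund[f"t{i}"] = float(rng.random())
        centroid_of, membership = cluster_otus(seqs, abund)

        # independent re-run of the greedy definition
        order = sorted(seqs, key=lambda x: (-abund[x], seqs[x], x))
        oracle: list[tuple[str, list[str]]] = []
        for asv in order:
            for entry in oracle:
                if sum(x != y for x, y in zip(seqs[asv], seqs[entry[0]])) <= 2:
                    entry[1].append(asv)
                    break
            else:
                oracle.append((asv, [asv]))
        assert sorted(map(sorted, membership.values())) == \
            sorted(sorted(m) for _, m in oracle)
        assert set(centroid_of.values()) == {c for c, _ in oracle}

    def test_mixed_lengths_fatal(self):
        with pytest.raises(ValueError, match="lengths"):
            cluster_otus({"a": "ACGT", "b": "ACGTA"}, {})


def _toy_otu_table(counts: pd.DataFrame, taxonomy=None) -> OTUTable:
    return OTUTable(
        centroid={o: o for o in counts.columns},
        membership={o: [o] for o in counts.columns},
        counts=counts,
        sequences={o: BASE for o in counts.columns},
        taxonomy=taxonomy or {},
    )


class TestPrevalenceFilter:
    def test_kept_above_both_thresholds(self):
        counts = pd.DataFrame(
            {"core": [80, 90, 100, 0, 70, 60, 50, 90, 20, 10],
             "filler": [10000] * 10}, index=[f"s{i}" for i in range(10)])
        table = _toy_otu_table(counts)
        # core: prevalence 0.9, mean abundance ~0.6% -> kept
        assert "core" in prevalence_filter(table)

    def test_exact_boundary_excluded(self):
        counts = pd.DataFrame({"x": [5, 5, 0, 0, 0], "y": [95, 95, 100, 100, 100]},
                              index=[f"s{i}" for i in range(5)])
        table = _toy_otu_table(counts)
        # prevalence of x is exactly 0.40: strict > excludes it
        assert prevalence_filter(table, 0.40, 0.001) == {"y"}
        assert "x" in prevalence_filter(table, 0.39, 0.001)

    def test_preset_nesting_loose_default_tight(self, small_world):
        table = build_otu_table(small_world.table)
        loose = prevalence_filter(table, 0.30)
        default = prevalence_filter(table, 0.40)
        tight = prevalence_filter(table, 0.50)
        assert tight <= default <= loose

    def test_planted_core_recovered_exactly(self, small_catalog):
        from mdmcensus import generate_community

        world = generate_community(
            small_catalog, n_samples=50, n_taxa=200, f_sequenced_abundance=0.5,
            seed=41, n_core=10, other_prevalence=(0.05, 0.15))
        table = build_otu_table(world.table)
        expected = {o for o, c in table.centroid.items()
                    if c in set(world.truth["core_asvs"])}
        assert prevalence_filter(table) == expected


class TestDetectModules:
    def test_two_disjoint_triangles(self):
        G = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        modules = detect_modules(G)
        assert len(set(modules.values())) == 2
        assert modules[0] == modules[1] == modules[2]

    def test_single_edge_one_module(self):
        modules = detect_modules(nx.Graph([("a", "b")]))
        assert modules["a"] == modules["b"]

    def test_empty_network(self):
        assert detect_modules(nx.Graph()) == {}

    def test_isolated_nodes_are_own_modules(self):
        G = nx.Graph([(0, 1)])
        G.add_nodes_from([7, 8])
        modules = detect_modules(G)
        assert len({modules[7], modules[8], modules[0]}) == 3

    def test_planted_two_block_graph_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        scores = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 30
            G = nx.Graph()
            G.add_nodes_from(range(2 * n))
            for i, j in itertools.combinations(range(2 * n), 2):
                same = (i < n) == (j < n)
                if rng.random() < (0.5 if same else 0.02):
                    G.add_edge(i, j)
            modules = detect_modules(G, seed=seed)
            truth = [0] * n + [1] * n
            found = [modules[i] for i in range(2 * n)]
            scores.append(adjusted_rand_score(truth, found))
        assert np.mean(scores) >= 0.9


class TestNodeTopology:
    def test_all_edges_inside_module_gives_pi_zero(self):
        G = nx.Graph([(0, 1), (1, 2), (0, 2)])
        topo = node_topology(G, {0: 0, 1: 0, 2: 0})
        assert all(t.pi == 0.0 for t in topo)

    def test_even_split_across_two_modules(self):
        G = nx.Graph([("x", f"m{i}") for i in range(2)]
                     + [("x", f"n{i}") for i in range(2)])
        modules = {"x": 0, "m0": 0, "m1": 0, "n0": 1, "n1": 1}
        topo = {t.node: t for t in node_topology(G, modules)}
        assert topo["x"].pi == pytest.approx(1 - (0.25 + 0.25))

    @pytest.mark.parametrize("zi,pi,expected", [
        (3.0, 0.5, Role.MODULE_HUB),
        (3.0, 0.7, Role.NETWORK_HUB),
        (2.0, 0.7, Role.CONNECTOR),
        (2.0, 0.5, Role.PERIPHERAL),
        (2.5, 0.62, Role.PERIPHERAL),   # both boundaries: strict inequalities
        (2.5, 0.7, Role.CONNECTOR),
        (3.0, 0.62, Role.MODULE_HUB),
    ])
    def test_role_threshold_table(self, zi, pi, expected):
        assert _role(zi, pi) == expected

    def test_unassigned_node_raises(self):
        G = nx.Graph([(0, 1)])
        with pytest.raises(ValueError):
            node_topology(G, {0: 0})

    def _brute_force(self, G, modules):
        """Recompute Zi/Pi from the adjacency matrix, edge by edge."""
        nodes = sorted(G.nodes)
        A = nx.to_numpy_array(G, nodelist=nodes)
        out = {}
        for ni, n in enumerate(nodes):
            k = int(A[ni].sum())
            kappa = int(sum(A[ni, nj] for nj, m in enumerate(nodes)
                            if modules[m] == modules[n]))
            same = [int(sum(A[mi, mj] for mj, m2 in enumerate(nodes)
                            if modules[m2] == modules[m1]))
                    for mi, m1 in enumerate(nodes)
                    if modules[m1] == modules[n]]
            mean, sd = np.mean(same), np.std(same)
            zi = (kappa - mean) / sd if sd > 0 else 0.0
            if k == 0:
                pi = 0.0
            else:
                counts = {}
                for nj, m in enumerate(nodes):
                    if A[ni, nj]:
                        counts[modules[m]] = counts.get(modules[m], 0) + 1
                pi = 1 - sum((c / k) ** 2 for c in counts.values())
            out[n] = (zi, pi)
        return out

    def test_exhaustive_small_graphs_match_brute_force(self):
        # every graph on 4 nodes, plus seeded random graphs on 5-7 nodes
        graphs = []
        pairs4 = list(itertools.combinations(range(4), 2))
        for mask in range(2 ** len(pairs4)):
            G = nx.Graph()
            G.add_nodes_from(range(4))
            G.add_edges_from(e for b, e in enumerate(pairs4) if mask >> b & 1)
            graphs.append(G)
        rng = np.random.default_rng(99)
        for _ in range(300):
            n = int(rng.integers(5, 8))
            G = nx.Graph()
            G.add_nodes_from(range(n))
            for i, j in itertools.combinations(range(n), 2):
                if rng.random() < 0.4:
                    G.add_edge(i, j)
            graphs.append(G)
        for G in graphs:
            modules = detect_modules(G)
            expected = self._brute_force(G, modules)
            for t in node_topology(G, modules):
                zi, pi = expected[t.node]
                assert t.zi == pytest.approx(zi)
                assert t.pi == pytest.approx(pi)
                assert 0.0 <= t.pi < 1.0

    def test_roles_invariant_under_relabeling(self):
        rng = np.random.default_rng(5)
        G = nx.gnp_random_graph(12, 0.3, seed=5)
        modules = detect_modules(G)
        roles = {t.node: t.role for t in node_topology(G, modules)}
        mapping = {n: f"node_{n}" for n in G.nodes}
        H = nx.relabel_nodes(G, mapping)
        h_modules = {mapping[n]: m for n, m in modules.items()}
        h_roles = {t.node: t.role for t in node_topology(H, h_modules)}
        assert all(h_roles[mapping[n]] == r for n, r in roles.items())


class _Res:
    def __init__(self, hit, cat=None):
        self._hit, self._cat = hit, cat

    def matched(self, tier):
        return self._hit

    def category_at(self, tier):
        return self._cat


class TestFlagUnderrepresentedPhyla:
    def _table(self):
        counts = pd.DataFrame(
            {"o1": [500, 500], "o2": [300, 300], "o3": [200, 200]},
            index=["s1", "s2"])
        tax = {"o1": "d__B;p__Proteobacteria;c__;o__;f__;g__;s__",
               "o2": "d__B;p__Patescibacteria;c__;o__;f__;g__;s__",
               "o3": "d__B;p__Proteobacteria;c__;o__;f__;g__;s__"}
        return _toy_otu_table(counts, tax)

    def test_unmatched_phylum_flagged_matched_not(self):
        table = self._table()
        res = {"o1": _Res(True), "o2": _Res(False), "o3": _Res(True)}
        assert flag_underrepresented_phyla(table, res) == ["Patescibacteria"]

    def test_unclassified_never_flagged(self):
        table = self._table()
        table.taxonomy["o2"] = ""
        res = {"o1": _Res(True), "o2": _Res(False), "o3": _Res(True)}
        assert flag_underrepresented_phyla(table, res) == []


class TestAssembleWantedList:
    def _topology(self, hubs, others=()):
        topo = [pytest.importorskip("mdmcensus.wanted").NodeTopology(
            node=h, degree=5, module=0, within_module_degree=5,
            zi=3.0, pi=0.2, role=Role.MODULE_HUB) for h in hubs]
        topo += [pytest.importorskip("mdmcensus.wanted").NodeTopology(
            node=o, degree=1, module=0, within_module_degree=1,
            zi=0.0, pi=0.0, role=Role.PERIPHERAL) for o in others]
        return topo

    def test_union_with_overlap_double_flagged(self):
        counts = pd.DataFrame({o: [10, 10] for o in ("A", "B", "C")},
                              index=["s1", "s2"])
        table = _toy_otu_table(counts)
        res = {o: _Res(False) for o in ("A", "B", "C")}
        wl = assemble_wanted_list({"A", "B"}, self._topology(["B", "C"]),
                                  res, [], table)
        assert list(wl.entries["otu_id"]) == ["A", "B", "C"]
        b = wl.entries.set_index("otu_id").loc["B"]
        assert b["flag_prevalence"] and b["flag_hub"]

    def test_knowledge_status(self):
        counts = pd.DataFrame({o: [10, 10] for o in ("iso", "mag", "dark")},
                              index=["s1", "s2"])
        table = _toy_otu_table(counts)
        res = {"iso": _Res(True, Category.ISOLATION),
               "mag": _Res(True, Category.MQ),
               "dark": _Res(False)}
        wl = assemble_wanted_list({"iso", "mag", "dark"}, [], res, [], table)
        status = wl.entries.set_index("otu_id")["status"]
        assert status["iso"] == "ISOLATE"
        assert status["mag"] == "GENOME_ONLY"
        assert status["dark"] == "DARK"

    def test_list_contains_prevalence_set(self, small_world, small_index):
        from mdmcensus.matching import classify_table

        table = build_otu_table(small_world.table)
        res = classify_table(small_world.table.sequences, small_index, [100.0])
        core = prevalence_filter(table)
        wl = assemble_wanted_list(core, [], res, [], table)
        assert core <= set(wl.entries["otu_id"])


class TestCrossEnvironmentMax:
    def test_planted_max_recovered_vs_full_scan(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            rng.integers(0, 500, size=(6, 4)),
            index=[f"e{i}" for i in range(6)],
            columns=["t1", "t2", "t3", "t4"])
        seqs = {f"t{i}": "".join(rng.choice(list("ACGT"), size=90))
                for i in range(1, 5)}
        envs = pd.Series(["soil"] * 3 + ["gut"] * 3, index=counts.index)
        external = AmpliconTable(counts=counts, sequences=seqs,
                                 environments=envs)
        otu_counts = pd.DataFrame({"O1": [1]}, index=["s"])
        otu_table = _toy_otu_table(otu_counts)
        otu_table.sequences["O1"] = seqs["t2"]
        out = cross_environment_max(["O1"], otu_table, external).iloc[0]
        rel = external.relative_abundance()["t2"]
        assert out["max_abundance"] == pytest.approx(rel.max())
        assert out["sample_id"] == rel.idxmax()

    def test_absent_centroid_gives_na(self):
        counts = pd.DataFrame({"t1": [10]}, index=["e1"])
        external = AmpliconTable(counts=counts, sequences={"t1": "A" * 90})
        otu_counts = pd.DataFrame({"O1": [1]}, index=["s"])
        otu_table = _toy_otu_table(otu_counts)
        otu_table.sequences["O1"] = "C" * 90
        out = cross_environment_max(["O1"], otu_table, external).iloc[0]
        assert np.isnan(out["max_abundance"])
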