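"""Interactome construction, centralities, permutation test and modules."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from dreg.network import (
    betweenness_dict,
    build_interactome,
    centrality_comparison,
    connectivity_permutation_test,
    detect_modules,
    find_hubs,
    induced_stats,
)


# -- interactome assembly --------------------------------------------------

def test_build_interactome_dedup_selfloops_and_union(tmp_path):
    f1 = tmp_path / "a.tsv"
    f1.write_text("A\tB\tsrc1\nA\tA\tsrc1\nC\tD\tsrc1\n")
    f2 = tmp_path / "b.tsv"
    f2.write_text("B\tA\tsrc2\nD\tE\tsrc2\n")
    g = build_interactome([f1, f2])
    assert g.number_of_edges() == 3  # A-B deduped across direction
    assert g.graph["n_self_loops"] == 1
    assert g.edges["A", "B"]["sources"] == {"src1", "src2"}


def test_build_interactome_set_union_oracle(tmp_path):
    rng = np.random.default_rng(4)
    nodes = [f"N{i}" for i in range(12)]
    files, union = [], set()
    for k in range(3):
        edges = set()
        while len(edges) < 10:
            a, b = rng.choice(nodes, 2, replace=False)
            edges.add(tuple(sorted((a, b))))
        union |= edges
        f = tmp_path / f"{k}.tsv"
        f.write_text("".join(f"{a}\t{b}\n" for a, b in sorted(edges)))
        files.append(f)
    g = build_interactome(files)
    assert set(map(lambda e: tuple(sorted(e)), g.edges)) == union


def test_malformed_edge_line_reports_location(tmp_path):
    f = tmp_path / "bad.tsv"
    f.write_text("A\tB\nonlyonefield\n")
    with pytest.raises(ValueError, match="bad.tsv:2"):
        build_interactome([f])


# -- betweenness -----------------------------------------------------------

def _brute_betweenness(g: nx.Graph) -> dict:
    """Shortest-path counting over unordered pairs, endpoints excluded."""
    out = {v: 0.0 for v in g}
    for s, t in combinations(g.nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for v in g:
            if v in (s, t):
                continue
            out[v] += sum(v in p for p in paths) / len(paths)
    return out


def test_betweenness_closed_forms():
    path = nx.path_graph(["A", "B", "C"])
    st = induced_stats(path, {"A", "B", "C"})
    assert st.per_node.loc["B", "betweenness"] == 1.0
    assert st.per_node.loc["A", "betweenness"] == 0.0

    star = nx.star_graph(4)  # center 0, leaves 1..4
    st = induced_stats(star, set(star.nodes))
    assert st.per_node.loc[0, "betweenness"] == 6.0  # C(4,2)


def test_betweenness_matches_exhaustive_oracle_on_small_graphs():
    for seed in range(8):
        g = nx.gnp_random_graph(int(6 + seed % 7), 0.35, seed=seed)
        ref = _brute_betweenness(g)
        fast = betweenness_dict(g)
        slow = nx.betweenness_centrality(g, normalized=False)
        for v in g:
            assert fast[v] == pytest.approx(ref[v], abs=1e-9)
            assert slow[v] == pytest.approx(ref[v], abs=1e-9)


# -- permutation test ------------------------------------------------------

def _clique_plus_background(k: int = 8, n: int = 120, seed: int = 0) -> tuple[nx.Graph, set]:
    g = nx.gnp_random_graph(n, 0.02, seed=seed)
    clique = set(range(k))
    for a, b in combinations(clique, 2):
        g.add_edge(a, b)
    return g, clique


def test_permutation_p_when_observed_beats_every_draw():
    g, clique = _clique_plus_background()
    res = connectivity_permutation_test(g, clique, n_permutations=1000, seed=1)
    assert (res.null >= res.observed).sum() == 0
    assert res.pvalue == pytest.approx(1 / 1001)


def test_permutation_reproducible_and_monotone():
    g, clique = _clique_plus_background(seed=2)
    a = connectivity_permutation_test(g, clique, 200, seed=9)
    b = connectivity_permutation_test(g, clique, 200, seed=9)
    assert np.array_equal(a.null, b.null) and a.pvalue == b.pvalue
    # monotone in the observed statistic against the same null sample
    for lower_obs in (a.observed - 5, a.observed - 1):
        p_lower = ((a.null >= lower_obs).sum() + 1) / (a.n_permutations + 1)
        assert p_lower >= a.pvalue


def test_permutation_input_validation():
    g = nx.path_graph(5)
    with pytest.raises(ValueError, match="at least two"):
        connectivity_permutation_test(g, {0}, 10, 0)
    with pytest.raises(ValueError, match="larger"):
        connectivity_permutation_test(g, set(range(10)), 10, 0)


# -- centrality comparison -------------------------------------------------

def test_ranksum_exact_small_groups_matches_enumeration():
    """Full enumeration of assignments reproduces the exact two-sided p."""
    x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    assert res.pvalue == pytest.approx(0.1)
    rng = np.random.default_rng(1)
    for _ in range(20):
        nx_, ny_ = rng.integers(2, 5), rng.integers(2, 5)
        vals = rng.permutation(np.arange(nx_ + ny_, dtype=float))
        x, y = vals[:nx_], vals[ny_ and nx_:]
        u_obs = sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)
        # enumerate all C(n, nx) group assignments
        us = [
            sum((vals[i] > vals[j]) + 0.5 * (vals[i] == vals[j])
                for i in idx for j in range(len(vals)) if j not in idx)
            for idx in map(set, combinations(range(len(vals)), len(x)))
        ]
        mean_u = len(x) * len(y) / 2
        p_exact = np.mean([abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12 for u in us])
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert res.pvalue == pytest.approx(p_exact, abs=1e-12)


def test_centrality_comparison_identical_groups_p_one():
    g = nx.circulant_graph(12, [1])  # every node degree 2
    out = centrality_comparison(g, set(range(6)))
    assert out.loc["degree", "pvalue"] == pytest.approx(1.0)


# -- hubs ------------------------------------------------------------------

def test_find_hubs_boundary():
    g = nx.Graph()
    hub_neighbors = [f"x{i}" for i in range(20)]
    for x in hub_neighbors:
        g.add_edge("hub", x)
    near = [f"y{i}" for i in range(19)]
    for y in near:
        g.add_edge("nearhub", y)
    members = {"hub", "nearhub", *hub_neighbors, *near}
    st = induced_stats(g, members)
    assert find_hubs(st, k_min=20) == ["hub"]
    assert "nearhub" not in find_hubs(st, k_min=20)
    assert set(find_hubs(st, k_min=0)) == members


# -- module detection ------------------------------------------------------

def test_detect_modules_two_triangles_with_bridge():
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"),
                      ("d", "e"), ("e", "f"), ("d", "f"), ("c", "d")])
    mods = detect_modules(g, penalty=0.0, min_size=3)
    members = sorted(tuple(sorted(m.members)) for m in mods)
    assert members == [("a", "b", "c"), ("d", "e", "f")]
    for m in mods:
        assert m.cohesiveness == pytest.approx(3 / 4)


def test_detect_modules_isolated_clique_cohesiveness_one():
    g = nx.complete_graph(5)
    mods = detect_modules(g, penalty=0.0, min_size=3)
    assert len(mods) == 1
    assert mods[0].members == frozenset(range(5))
    assert mods[0].cohesiveness == pytest.approx(1.0)


def test_overlap_score_arithmetic_blocks_merge():
    a, b = {"a", "b", "c"}, {"b", "c", "d"}
    omega = len(a & b) ** 2 / (len(a) * len(b))
    assert omega == pytest.approx(4 / 9)
    assert omega < 0.8  # default threshold would not merge these


def test_detect_modules_stable_under_relabeling():
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"), ("c", "d"),
                      ("d", "e"), ("e", "f"), ("d", "f")])
    mapping = {n: f"z{n}" for n in g.nodes}
    h = nx.relabel_nodes(g, mapping)
    mods_g = detect_modules(g, penalty=1.0, min_size=3)
    mods_h = detect_modules(h, penalty=1.0, min_size=3)
    relabeled = sorted(tuple(sorted(mapping[x] for x in m.members)) for m in mods_g)
    assert relabeled == sorted(tuple(sorted(m.members)) for m in mods_h)


def test_detect_modules_empty_graph():
    assert detect_modules(nx.Graph()) == []
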