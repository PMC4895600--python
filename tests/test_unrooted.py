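"""Edge classes, stars, rooting-cost profiles, plateaus, greedy descent."""

import pytest

import epiclust as ep
from epiclust.reconcile import DUPLICATION
from epiclust.unrooted import (DOUBLE, EMPTY, SINGLE, classify_edges,
                               classify_stars, directed_edge_maps,
                               naive_cost_profile, top_node)
from conftest import sim_population


def _edge(G, bipart):
    return G.edge_by_bipartition(bipart)


class TestDirectedMaps:
    def test_three_leaf_star(self, suite, abc_species):
        G = suite["star3_empty"].G
        S = abc_species
        maps = directed_edge_maps(G, S)
        c = next(v for v in G.leaves if G.labels[v] == "c")
        center = G.internal_nodes[0]
        assert maps[(center, c)] == S.leaf("c")
        assert tuple(S.clade_leaf_labels(maps[(c, center)])) == ("a", "b")

    def test_internal_edge_images(self):
        S = ep.parse_species_newick("((a,b),(c,d));")
        G = ep.parse_gene_newick("((a,b),(c,d));")
        maps = directed_edge_maps(G, S)
        u, v = _edge(G, "a,b|c,d")
        imgs = {tuple(S.clade_leaf_labels(maps[(u, v)])),
                tuple(S.clade_leaf_labels(maps[(v, u)]))}
        assert imgs == {("a", "b"), ("c", "d")}

    @pytest.mark.parametrize("i", range(0, 60, 6))
    def test_leaf_edge_base_case(self, i):
        S, sim = sim_population(60, seed0=300)[i]
        G = sim.unrooted
        maps = directed_edge_maps(G, S)
        for leaf in G.leaves:
            (nbr,) = G.adj[leaf]
            assert maps[(nbr, leaf)] == S.leaf(G.labels[leaf])


class TestEdgeClasses:
    def test_star3_empty_edge(self, suite, abc_species):
        G = suite["star3_empty"].G
        ec = classify_edges(G, abc_species)
        assert ec.classes[_edge(G, "a,b|c")] == EMPTY
        assert all(ec.classes[e] == SINGLE for e in G.edges
                   if e != _edge(G, "a,b|c"))

    def test_double_edge_fixture(self, suite, abc_species):
        G = suite["double_edge"].G
        ec = classify_edges(G, abc_species)
        assert ec.classes[_edge(G, "a,c|b,c")] == DOUBLE

    def test_single_edge_orientation(self):
        S = ep.parse_species_newick("((a,b),(c,d));")
        G = ep.parse_gene_newick("((a,b),(c,d));")
        ec = classify_edges(G, S)
        a = next(v for v in G.leaves if G.labels[v] == "a")
        e = tuple(sorted((a, G.adj[a][0])))
        assert ec.classes[e] == SINGLE
        assert ec.incoming[e] == a  # the a-side component misses the top node

    def test_nonspanning_top_node(self):
        S = ep.parse_species_newick("(((a,b),c),d);")
        G = ep.parse_gene_newick("(a,b,(a,b));")
        assert tuple(S.clade_leaf_labels(top_node(G, S))) == ("a", "b")


class TestStars:
    def test_fixture_star_types(self, suite, abc_species):
        G = suite["star3_empty"].G
        assert list(classify_stars(G, abc_species).values()) == ["S2"]
        G2 = suite["double_edge"].G
        assert sorted(classify_stars(G2, abc_species).values()) == ["S3", "S3"]
        f4 = suite["two_s2_stars"]
        assert sorted(classify_stars(f4.G, f4.S).values()) == \
               ["S1", "S1", "S2", "S2"]


class TestProfilesAndPlateaus:
    def test_star3_profile(self, suite, abc_species):
        G = suite["star3_empty"].G
        prof = ep.rooting_cost_profile(G, abc_species, "D")
        assert prof[_edge(G, "a,b|c")] == 0
        assert sorted(prof.values()) == [0, 1, 1]

    def test_double_fixture_profile(self, suite, abc_species):
        G = suite["double_edge"].G
        prof = ep.rooting_cost_profile(G, abc_species, "D")
        assert prof[_edge(G, "a,c|b,c")] == 1
        assert sorted(prof.values()) == [1, 2, 2, 2, 2]

    @pytest.mark.parametrize("name", ["star3_empty", "double_edge",
                                      "one_s2_star", "two_s2_stars"])
    def test_fixture_plateaus(self, suite, name):
        f = suite[name]
        G, S = f.G, f.S
        plat = ep.plateau(G, S, "D")
        assert plat.cost == f.expected["d_plateau_cost"]
        assert sorted(G.bipartition(e) for e in plat.edges) == \
               sorted(f.expected["d_plateau"])

    def test_min_profile_equals_plateau_cost(self, suite):
        for f in suite.values():
            G, S = f.G, f.S
            prof = ep.rooting_cost_profile(G, S, "D")
            assert min(prof.values()) == ep.plateau(G, S, "D").cost

    @pytest.mark.parametrize("i", range(0, 100, 4))
    def test_profile_matches_naive_rerooting_oracle(self, i):
        """Dual route: incremental per-edge D costs vs rooting from scratch."""
        S, sim = sim_population(100, seed0=0)[i]
        G = sim.unrooted
        assert ep.rooting_cost_profile(G, S, "D") == naive_cost_profile(G, S, "D")
        dl = ep.rooting_cost_profile(G, S, "DL")
        for e in G.edges:
            assert dl[e] == ep.dl_cost(G.root_at_edge(e), S)


class TestStructuralTheorems:
    """Plateau structure of simulated unrooted gene trees."""

    POP = staticmethod(lambda: sim_population(300, seed0=0))

    @pytest.mark.parametrize("chunk", range(10))
    def test_empty_xor_double_dichotomy(self, chunk):
        for S, sim in self.POP()[chunk * 30:(chunk + 1) * 30]:
            ec = classify_edges(sim.unrooted, S)
            n_empty = len(ec.empty_edges())
            n_double = len(ec.double_edges())
            assert (n_empty == 1 and n_double == 0) or \
                   (n_empty == 0 and n_double >= 1)

    @pytest.mark.parametrize("chunk", range(10))
    def test_dl_plateau_inside_d_plateau(self, chunk):
        for S, sim in self.POP()[chunk * 30:(chunk + 1) * 30]:
            G = sim.unrooted
            d = ep.plateau(G, S, "D")     # connectivity asserted internally
            dl = ep.plateau(G, S, "DL")
            assert set(dl.edges) <= set(d.edges)

    @pytest.mark.parametrize("chunk", range(6))
    def test_large_dl_plateau_contains_s4_s5_stars(self, chunk):
        for S, sim in self.POP()[chunk * 50:(chunk + 1) * 50]:
            G = sim.unrooted
            dl = ep.plateau(G, S, "DL")
            if len(dl.edges) <= 1:
                continue
            ec = classify_edges(G, S)
            stars = classify_stars(G, S, ec)
            for v, t in stars.items():
                if t in ("S4", "S5"):
                    for w in G.adj[v]:
                        e = (v, w) if v < w else (w, v)
                        if ec.classes[e] == DOUBLE:
                            assert e in dl.edges
            for e in G.edges:
                if e not in dl.edges:
                    assert ec.classes[e] == SINGLE

    @pytest.mark.parametrize("chunk", range(6))
    def test_plateau_internal_nodes_are_super_duplications(self, chunk):
        """With a double edge present, every internal plateau node is a
        duplication in every cost-minimal rooting."""
        for S, sim in self.POP()[chunk * 50:(chunk + 1) * 50]:
            G = sim.unrooted
            ec = classify_edges(G, S)
            if not ec.double_edges():
                continue
            plat = ep.plateau(G, S, "D")
            deg = {}
            for u, v in plat.edges:
                deg[u] = deg.get(u, 0) + 1
                deg[v] = deg.get(v, 0) + 1
            internal = {v for v, d in deg.items() if d >= 2}
            for e in plat.edges:
                T = G.root_at_edge(e)
                ev = ep.classify_events(T, S)
                for v in range(T.n_nodes):
                    if T.source_nodes[v] in internal:
                        assert ev[v] == DUPLICATION


class TestGreedyDescent:
    def test_fixture_results(self, suite, abc_species):
        G = suite["star3_empty"].G
        assert G.bipartition(ep.find_opt_edge(G, abc_species)) == "a,b|c"
        G2 = suite["double_edge"].G
        assert G2.bipartition(ep.find_opt_edge(G2, abc_species)) == "a,c|b,c"

    @pytest.mark.parametrize("i", range(0, 300, 9))
    def test_returns_empty_or_double_never_single(self, i):
        S, sim = sim_population(300, seed0=0)[i]
        G = sim.unrooted
        ec = classify_edges(G, S)
        e = ep.find_opt_edge(G, S)
        assert ec.classes[e] in (EMPTY, DOUBLE)
        if ec.classes[e] == EMPTY:
            assert ec.empty_edges() == [e]
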