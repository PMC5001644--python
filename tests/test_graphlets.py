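"""Graphlet canonicalization, counting, edit smoothing and kernels."""

import itertools

import networkx as nx
import numpy as np
import pytest

from funcshift import graphlets as gl
from funcshift.graphlets import Graphlet, GraphletError, KernelSpec

from conftest import build_env

ALPHA2 = ("A", "B")


def brute_force_phi(env, N):
    """Oracle: enumerate all vertex subsets, keep connected root-containing
    induced subgraphs, canonicalize by exhaustive isomorphism grouping."""
    g = env.graph
    others = [v for v in g.nodes if v != env.root]
    counts = {}
    for n in range(1, N + 1):
        for extra in itertools.combinations(others, n - 1):
            nodes = (env.root,) + extra
            sub = g.subgraph(nodes)
            if not nx.is_connected(sub):
                continue
            glet = gl.canonicalize(sub, env.root)
            counts[glet] = counts.get(glet, 0) + 1
    return counts


def random_env(rng, n_nodes, p=0.35, alphabet=ALPHA2):
    while True:
        g = nx.gnp_random_graph(n_nodes, p, seed=int(rng.integers(0, 2**31)))
        if 0 in g and (n_nodes == 1 or any(True for _ in g.neighbors(0))):
            break
    labels = {v: alphabet[int(rng.integers(0, len(alphabet)))] for v in g.nodes}
    return build_env(labels, list(g.edges), 0)


class TestCanonicalize:
    def test_single_vertex_stable(self):
        a = gl.canonical_form(["A"], [])
        b = gl.canonical_form(["A"], [])
        assert a == b and a.id == "1|A|"

    def test_mirror_paths_share_id(self):
        left = gl.canonical_form(["A", "B", "C"], [(0, 1), (1, 2)])
        right = gl.canonical_form(["A", "C", "B"], [(0, 2), (2, 1)])
        assert left == right

    def test_equality_matches_exhaustive_isomorphism(self):
        """All rooted labeled 3-vertex connected graphs over {A,B}: canonical
        ids agree exactly with brute-force root/label-preserving isomorphism."""
        edge_sets = [
            es for r in (2, 3)
            for es in itertools.combinations([(0, 1), (0, 2), (1, 2)], r)
        ]
        graphs = []
        for labels in itertools.product(ALPHA2, repeat=3):
            for es in edge_sets:
                g = nx.Graph()
                for i, lab in enumerate(labels):
                    g.add_node(i, label=lab)
                g.add_edges_from(es)
                if nx.is_connected(g):
                    graphs.append(g)

        def iso(g1, g2):
            # brute force over all mappings fixing the root
            for perm in itertools.permutations([1, 2]):
                mapping = {0: 0, 1: perm[0], 2: perm[1]}
                if all(
                    g1.nodes[v]["label"] == g2.nodes[mapping[v]]["label"]
                    for v in g1
                ) and all(
                    g2.has_edge(mapping[u], mapping[v]) for u, v in g1.edges
                ) and g1.number_of_edges() == g2.number_of_edges():
                    return True
            return False

        for g1, g2 in itertools.combinations(graphs, 2):
            same_id = gl.canonicalize(g1, 0) == gl.canonicalize(g2, 0)
            assert same_id == iso(g1, g2)

    def test_disconnected_and_oversize_rejected(self):
        with pytest.raises(GraphletError):
            gl.canonical_form(["A", "B"], [])
        with pytest.raises(GraphletError):
            gl.canonical_form(list("ABCABC"), [(i, i + 1) for i in range(5)])

    def test_id_round_trip(self):
        g = gl.canonical_form(["A", "B", "B"], [(0, 1), (0, 2), (1, 2)])
        assert Graphlet.from_id(g.id) == g


class TestCounting:
    def test_isolated_root(self):
        env = build_env({"r": "A"}, [], "r")
        prof = gl.count_graphlets(env, 5)
        assert prof.phi == {gl.canonical_form(["A"], []): 1}

    def test_root_with_two_leaves(self):
        env = build_env({"r": "A", "x": "B", "y": "C"},
                        [("r", "x"), ("r", "y")], "r")
        prof = gl.count_graphlets(env, 2)
        two = {g: c for g, c in prof.phi.items() if g.n == 2}
        assert two == {
            gl.canonical_form(["A", "B"], [(0, 1)]): 1,
            gl.canonical_form(["A", "C"], [(0, 1)]): 1,
        }
        # identical leaf labels merge into one entry of count 2
        env2 = build_env({"r": "A", "x": "B", "y": "B"},
                         [("r", "x"), ("r", "y")], "r")
        two2 = {g: c for g, c in gl.count_graphlets(env2, 2).phi.items() if g.n == 2}
        assert two2 == {gl.canonical_form(["A", "B"], [(0, 1)]): 2}

    @pytest.mark.parametrize("n_nodes", [4, 6, 8])
    def test_matches_exhaustive_oracle(self, rng, n_nodes):
        for _ in range(4):
            env = random_env(rng, n_nodes)
            prof = gl.count_graphlets(env, 4)
            assert prof.phi == brute_force_phi(env, 4)

    def test_invariant_to_vertex_relabeling(self, rng):
        env = random_env(rng, 7)
        mapping = {v: f"x{v}" for v in env.graph.nodes}
        g2 = nx.relabel_nodes(env.graph, mapping)
        env2 = build_env(
            {v: g2.nodes[v]["label"] for v in g2.nodes}, list(g2.edges), "x0"
        )
        assert gl.count_graphlets(env, 4).phi == gl.count_graphlets(env2, 4).phi


class TestEditNeighborhood:
    def test_m0_is_center_only(self):
        g = gl.canonical_form(["A", "B"], [(0, 1)])
        for mode in gl.MODES:
            assert gl.edit_neighborhood(g, 0, mode, ALPHA2, 4) == frozenset({g})

    def test_single_vertex_label_substitution(self):
        g = gl.canonical_form(["A"], [])
        nb = gl.edit_neighborhood(g, 1, "label_sub", ALPHA2, 4)
        assert nb == frozenset({
            gl.canonical_form(["A"], []), gl.canonical_form(["B"], [])
        })

    def test_path_edge_indel_matches_toggle_oracle(self):
        center = gl.canonical_form(["A", "B", "C"], [(0, 1), (1, 2)])
        # oracle: apply every single edge toggle, keep connected results
        expected = {center}
        all_pairs = [(0, 1), (0, 2), (1, 2)]
        for pair in all_pairs:
            edges = set(center.edges)
            edges ^= {pair}
            g = nx.Graph()
            for i, lab in enumerate(center.labels):
                g.add_node(i, label=lab)
            g.add_edges_from(edges)
            if nx.is_connected(g):
                expected.add(gl.canonicalize(g, 0))
        got = gl.edit_neighborhood(center, 1, "edge_indel", ALPHA2, 4)
        assert got == frozenset(expected)

    def test_full_includes_leaf_insertions_and_deletions(self):
        g = gl.canonical_form(["A", "B"], [(0, 1)])
        nb = gl.edit_neighborhood(g, 1, "full", ALPHA2, 3)
        # deletion of the non-root leaf
        assert gl.canonical_form(["A"], []) in nb
        # insertion of a new leaf (three vertices)
        assert any(x.n == 3 for x in nb)
        # size cap respected
        nb_capped = gl.edit_neighborhood(g, 1, "full", ALPHA2, 2)
        assert all(x.n <= 2 for x in nb_capped)

    def test_root_never_deleted(self):
        g = gl.canonical_form(["A", "B"], [(0, 1)])
        nb = gl.edit_neighborhood(g, 1, "full", ALPHA2, 3)
        assert gl.canonical_form(["B"], []) not in nb

    def test_neighborhood_is_symmetric(self):
        """g in E(h) iff h in E(g): required for scatter-based smoothing."""
        centers = [
            gl.canonical_form(["A"], []),
            gl.canonical_form(["A", "B"], [(0, 1)]),
            gl.canonical_form(["B", "A", "B"], [(0, 1), (1, 2)]),
            gl.canonical_form(["A", "A", "B"], [(0, 1), (0, 2), (1, 2)]),
        ]
        for mode in gl.MODES:
            universe = set(centers)
            for c in centers:
                universe |= gl.edit_neighborhood(c, 1, mode, ALPHA2, 3)
            for g in universe:
                for h in universe:
                    in_gh = h in gl.edit_neighborhood(g, 1, mode, ALPHA2, 3)
                    in_hg = g in gl.edit_neighborhood(h, 1, mode, ALPHA2, 3)
                    assert in_gh == in_hg


class TestSmoothing:
    def test_m0_identity(self, rng):
        env = random_env(rng, 6)
        spec = KernelSpec(N=3, m=0, mode="full", alphabet=ALPHA2)
        prof = gl.smooth(gl.count_graphlets(env, 3), spec)
        assert prof.psi == {g: float(c) for g, c in prof.phi.items()}

    def test_single_vertex_label_sub_spreads_count(self):
        env = build_env({"r": "A"}, [], "r")
        spec = KernelSpec(N=1, m=1, mode="label_sub", alphabet=ALPHA2)
        prof = gl.smooth(gl.count_graphlets(env, 1), spec)
        assert prof.psi == {
            gl.canonical_form(["A"], []): 1.0,
            gl.canonical_form(["B"], []): 1.0,
        }

    @pytest.mark.parametrize("mode", gl.MODES)
    def test_matches_incidence_matrix_oracle(self, rng, mode):
        env = random_env(rng, 7)
        spec = KernelSpec(N=3, m=1, mode=mode, alphabet=ALPHA2)
        prof = gl.smooth(gl.count_graphlets(env, 3), spec)
        # oracle: psi(gi) = sum_j W[i,j] phi(gj) over an explicit universe
        universe = sorted(prof.psi.keys(), key=lambda g: g.id)
        index = {g: i for i, g in enumerate(universe)}
        W = np.zeros((len(universe), len(universe)))
        for g in universe:
            for h in gl.edit_neighborhood(g, 1, mode, ALPHA2, 3):
                if h in index:
                    W[index[g], index[h]] = 1.0
        phi_vec = np.array([prof.phi.get(g, 0) for g in universe], dtype=float)
        psi_vec = W @ phi_vec
        for g in universe:
            assert prof.psi[g] == pytest.approx(psi_vec[index[g]])


class TestKernel:
    def _profile(self, env, spec):
        return gl.compute_profile(env, spec)

    def test_self_kernel_normalized_is_one(self, rng):
        spec = KernelSpec(N=3, m=1, mode="full", alphabet=ALPHA2)
        p = self._profile(random_env(rng, 6), spec)
        assert gl.kernel(p, p) == pytest.approx(1.0)

    def test_disjoint_support_gives_zero(self):
        spec = KernelSpec(N=1, m=0, mode="full", alphabet=ALPHA2)
        pa = self._profile(build_env({"r": "A"}, [], "r"), spec)
        pb = self._profile(build_env({"r": "B"}, [], "r"), spec)
        assert gl.kernel(pa, pb) == 0.0

    def test_m0_equals_raw_dot_product(self, rng):
        spec = KernelSpec(N=4, m=0, mode="full", alphabet=ALPHA2)
        u = self._profile(random_env(rng, 7), spec)
        v = self._profile(random_env(rng, 7), spec)
        expected = sum(
            c * v.phi.get(g, 0) for g, c in u.phi.items()
        )
        assert gl.kernel(u, v, normalized=False) == pytest.approx(expected)

    def test_spec_mismatch_is_an_error(self, rng):
        env = random_env(rng, 5)
        u = self._profile(env, KernelSpec(N=3, m=0, mode="full", alphabet=ALPHA2))
        v = self._profile(env, KernelSpec(N=4, m=0, mode="full", alphabet=ALPHA2))
        with pytest.raises(GraphletError):
            gl.kernel(u, v)

    def test_smoothing_monotonicity_and_mode_ordering(self, rng):
        """m=1 never shrinks the un-normalized kernel, and the full mode
        upper-bounds both restricted modes (neighborhood containment)."""
        envs = [random_env(rng, 6) for _ in range(4)]
        for u_env, v_env in itertools.combinations(envs, 2):
            vals = {}
            for m, mode in [(0, "full"), (1, "full"), (1, "label_sub"),
                            (1, "edge_indel")]:
                spec = KernelSpec(N=3, m=m, mode=mode, alphabet=ALPHA2)
                vals[(m, mode)] = gl.kernel(
                    self._profile(u_env, spec), self._profile(v_env, spec),
                    normalized=False,
                )
            assert vals[(1, "full")] >= vals[(0, "full")] - 1e-9
            assert vals[(1, "full")] >= vals[(1, "label_sub")] - 1e-9
            assert vals[(1, "full")] >= vals[(1, "edge_indel")] - 1e-9
            assert vals[(1, "label_sub")] >= vals[(0, "full")] - 1e-9
            assert vals[(1, "edge_indel")] >= vals[(0, "full")] - 1e-9

    @pytest.mark.parametrize("m,mode", [(0, "full"), (1, "full"), (1, "label_sub")])
    def test_kernel_matrix_psd_symmetric_unit_diagonal(self, rng, m, mode):
        spec = KernelSpec(N=3, m=m, mode=mode, alphabet=ALPHA2)
        profiles = [self._profile(random_env(rng, 6), spec) for _ in range(8)]
        km = gl.kernel_matrix(profiles)
        K = km.entries
        assert np.allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() >= -1e-8
        assert np.allclose(np.diag(K), 1.0)
        assert K.min() >= 0.0 and K.max() <= 1.0 + 1e-12
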