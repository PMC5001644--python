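"""Structure parsing, contact graphs, geometric site labels, variant mapping."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from funcshift import structgraph as sg
from funcshift.structgraph import (
    ContactRuleError,
    HetAtom,
    ParseError,
    SequenceIndex,
    VariantRecord,
)

from conftest import build_structure, linear_chain_structure


def pdb_line(serial, name, resname, chain, resnum, xyz, element,
             het=False, altloc=" ", occ=1.00):
    record = "HETATM" if het else "ATOM  "
    return (
        f"{record}{serial:5d}  {name:<3s}{altloc}{resname:<3s} {chain}{resnum:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occ:6.2f}{0.00:6.2f}"
        f"          {element:>2s}"
    )


THREE_RES_PDB = "\n".join([
    pdb_line(1, "N", "ALA", "A", 1, (0.0, 1.4, 0.0), "N"),
    pdb_line(2, "CA", "ALA", "A", 1, (0.0, 0.0, 0.0), "C"),
    pdb_line(3, "N", "GLY", "A", 2, (3.8, 1.4, 0.0), "N"),
    pdb_line(4, "CA", "GLY", "A", 2, (3.8, 0.0, 0.0), "C"),
    pdb_line(5, "N", "CYS", "A", 3, (7.6, 1.4, 0.0), "N"),
    pdb_line(6, "CA", "CYS", "A", 3, (7.6, 0.0, 0.0), "C"),
    "END",
]) + "\n"


class TestParseStructure:
    def test_minimal_three_residue_structure(self):
        s = sg.parse_structure(THREE_RES_PDB, "mini")
        assert list(s.chains) == ["A"]
        assert [r.aa for r in s.chains["A"]] == ["A", "G", "C"]
        assert all(len(r.atoms) == 2 for r in s.chains["A"])

    def test_hetatm_zinc_is_exposed(self):
        text = THREE_RES_PDB.replace(
            "END", pdb_line(7, "ZN", "ZN", "A", 4, (1.0, 2.0, 3.0), "ZN", het=True)
            + "\nEND"
        )
        s = sg.parse_structure(text, "zn")
        assert len(s.het_atoms) == 1
        assert s.het_atoms[0].element == "ZN"
        assert s.het_atoms[0].xyz == (1.0, 2.0, 3.0)

    def test_altloc_resolved_to_highest_occupancy(self):
        # CA present in two conformations; B has the higher occupancy
        lines = [
            pdb_line(1, "CA", "ALA", "A", 1, (0.0, 0.0, 0.0), "C",
                     altloc="A", occ=0.40),
            pdb_line(2, "CA", "ALA", "A", 1, (9.0, 9.0, 9.0), "C",
                     altloc="B", occ=0.60),
            "END",
        ]
        s = sg.parse_structure("\n".join(lines) + "\n", "alt")
        # oracle: manual occupancy-sorted parse of the same text
        best = max(
            [(0.40, (0.0, 0.0, 0.0)), (0.60, (9.0, 9.0, 9.0))], key=lambda t: t[0]
        )
        (res,) = s.chains["A"]
        assert len(res.atoms) == 1
        assert res.atoms[0].xyz == best[1]

    def test_nonstandard_residue_dropped_with_warning(self, caplog):
        text = THREE_RES_PDB.replace("ALA", "XYZ")
        with caplog.at_level("WARNING"):
            s = sg.parse_structure(text, "odd")
        assert [r.aa for r in s.chains["A"]] == ["G", "C"]
        assert any("non-standard" in rec.message for rec in caplog.records)

    @pytest.mark.parametrize("bad_field", ["   x.xxx", "        "])
    def test_malformed_coordinate_names_line(self, bad_field):
        good = pdb_line(1, "CA", "ALA", "A", 1, (0.0, 0.0, 0.0), "C")
        bad = good[:30] + bad_field + good[38:]
        text = good + "\n" + bad + "\nEND\n"
        with pytest.raises(ParseError, match="line 2"):
            sg.parse_structure(text)

    def test_no_atom_records_is_an_error(self):
        with pytest.raises(ParseError):
            sg.parse_structure("REMARK nothing here\nEND\n")


class TestContactGraph:
    def _two_residue_structure(self, distance):
        return build_structure({"A": [
            (1, "A", [("C", "CA", (0.0, 0.0, 0.0)), ("C", "CB", (1.0, 0.0, 0.0))]),
            (2, "G", [("C", "CA", (1.0 + distance, 0.0, 0.0))]),
        ]})

    def test_edge_present_just_inside_threshold(self):
        cg = sg.build_contact_graph(self._two_residue_structure(4.4), "any_atom", 4.5)
        assert cg.graph.has_edge(("A", "1"), ("A", "2"))

    def test_edge_absent_just_outside_threshold(self):
        cg = sg.build_contact_graph(self._two_residue_structure(4.4), "any_atom", 4.3)
        assert not cg.graph.has_edge(("A", "1"), ("A", "2"))

    @pytest.mark.parametrize("rule,threshold", [
        ("any_atom", 4.5), ("c_alpha", 6.0),
    ])
    def test_adjacency_matches_brute_force_oracle(self, rng, rule, threshold):
        # compact random coil: 12 residues with CA + one side-chain atom
        residues = []
        pos = np.cumsum(rng.normal(scale=2.2, size=(12, 3)), axis=0)
        for i, p in enumerate(pos):
            side = p + rng.normal(scale=1.0, size=3)
            residues.append((i + 1, "L", [
                ("C", "CA", tuple(p)), ("C", "CB", tuple(side)),
            ]))
        s = build_structure({"A": residues})
        cg = sg.build_contact_graph(s, rule, threshold)

        expected = set()
        rs = s.chains["A"]
        for a, b in itertools.combinations(range(len(rs)), 2):
            if rule == "c_alpha":
                d = math.dist(rs[a].atom("CA").xyz, rs[b].atom("CA").xyz)
            else:
                d = min(
                    math.dist(x.xyz, y.xyz)
                    for x in rs[a].atoms for y in rs[b].atoms
                )
            if d <= threshold:
                expected.add(frozenset({("A", rs[a].index), ("A", rs[b].index)}))
        got = {frozenset(e) for e in cg.graph.edges()}
        assert got == expected
        assert all(u != v for u, v in cg.graph.edges())  # no self-loops

    def test_c_alpha_rule_requires_ca_atoms(self):
        s = build_structure({"A": [
            (1, "A", [("C", "CA", (0.0, 0.0, 0.0))]),
            (2, "G", [("C", "CB", (3.0, 0.0, 0.0))]),
        ]})
        with pytest.raises(ContactRuleError, match="A:2"):
            sg.build_contact_graph(s, "c_alpha", 6.0)

    def test_invalid_rule_and_threshold(self):
        s = self._two_residue_structure(3.0)
        with pytest.raises(ValueError):
            sg.build_contact_graph(s, "nearest", 4.5)
        with pytest.raises(ValueError):
            sg.build_contact_graph(s, "any_atom", -1.0)


class TestExtractEnvironment:
    def test_level_zero_is_single_vertex(self, env_factory):
        env = env_factory({"a": "A", "b": "B"}, [("a", "b")], "a")
        ball = sg.extract_environment(env, "a", 0)
        assert set(ball.graph.nodes) == {"a"}

    def test_path_level_one(self, env_factory):
        env = env_factory({"a": "A", "b": "B", "c": "C"},
                          [("a", "b"), ("b", "c")], "a")
        ball = sg.extract_environment(env, "a", 1)
        assert set(ball.graph.nodes) == {"a", "b"}
        assert ball.graph.number_of_edges() == 1

    def test_matches_independent_bfs_oracle(self, rng):
        g = nx.gnp_random_graph(30, 0.12, seed=5)
        for v in g.nodes:
            g.nodes[v]["label"] = "A"
        cg = sg.ContactGraph(graph=g, alphabet=("A",))
        for level in (0, 1, 2, 3):
            ball = sg.extract_environment(cg, 0, level)
            # oracle: hand-rolled breadth-first search
            frontier, seen = {0}, {0}
            for _ in range(level):
                frontier = {
                    u for v in frontier for u in g.neighbors(v) if u not in seen
                }
                seen |= frontier
            assert set(ball.graph.nodes) == seen

    def test_large_level_gives_connected_component(self):
        g = nx.Graph()
        g.add_edges_from([(1, 2), (2, 3)])
        g.add_node(99)
        for v in g.nodes:
            g.nodes[v]["label"] = "A"
        cg = sg.ContactGraph(graph=g, alphabet=("A",))
        ball = sg.extract_environment(cg, 1, 10**6)
        assert set(ball.graph.nodes) == {1, 2, 3}

    def test_missing_root_is_an_error(self, env_factory):
        env = env_factory({"a": "A"}, [], "a")
        with pytest.raises(KeyError):
            sg.extract_environment(env, "zzz", 2)


class TestMetalLabeling:
    def _structure_with_zn(self, atoms):
        zn = HetAtom(element="ZN", name="ZN", resname="ZN",
                     chain="A", index="9", xyz=(0.0, 0.0, 0.0))
        return build_structure({"A": [(1, "D", atoms)]}, het_atoms=[zn])

    def test_oxygen_within_3A_is_labeled(self):
        s = self._structure_with_zn([("O", "OD1", (2.5, 0.0, 0.0))])
        labels = sg.label_metal_sites(s)
        assert [(l.index, l.function) for l in labels] == [("1", "Zn")]

    def test_carbon_is_excluded_even_when_close(self):
        s = self._structure_with_zn([("C", "CB", (2.0, 0.0, 0.0))])
        assert sg.label_metal_sites(s) == []

    def test_nitrogen_outside_3A_not_labeled(self):
        s = self._structure_with_zn([("N", "NE2", (3.5, 0.0, 0.0))])
        assert sg.label_metal_sites(s) == []

    def test_invariant_under_rigid_transformation(self, rng):
        # random rotation (QR orthonormalisation) plus translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        t = rng.normal(scale=20.0, size=3)

        def move(xyz):
            return tuple(q @ np.asarray(xyz) + t)

        atoms = [("O", "OD1", (2.5, 0.0, 0.0)), ("N", "N", (4.0, 0.0, 0.0))]
        s1 = self._structure_with_zn(atoms)
        zn2 = HetAtom("ZN", "ZN", "ZN", "A", "9", move((0.0, 0.0, 0.0)))
        s2 = build_structure(
            {"A": [(1, "D", [(e, n, move(x)) for e, n, x in atoms])]},
            het_atoms=[zn2],
        )
        assert sg.label_metal_sites(s1) == sg.label_metal_sites(s2)

    def test_no_metals_gives_empty_list(self):
        s = build_structure({"A": [(1, "D", [("O", "OD1", (0, 0, 0))])]})
        assert sg.label_metal_sites(s) == []


class TestConservationSplit:
    def _graph(self, aas):
        g = nx.Graph()
        for i, aa in enumerate(aas):
            g.add_node(("A", str(i + 1)), aa=aa, label=aa)
        return sg.ContactGraph(graph=g, alphabet=sg.AA20)

    def test_all_above_pivot_all_conserved(self):
        cg = self._graph("AGC")
        scores = {v: 0.9 for v in cg.graph.nodes}
        out = sg.split_alphabet_by_conservation(cg, scores, pivot=0.5)
        assert all(out.label(v).isupper() for v in out.graph.nodes)
        assert len(out.alphabet) == 40

    def test_tie_at_pivot_goes_to_conserved_class(self):
        cg = self._graph("A")
        out = sg.split_alphabet_by_conservation(
            cg, {("A", "1"): 0.5}, pivot=0.5
        )
        assert out.label(("A", "1")) == "A"

    def test_mixed_scores_match_scalar_threshold_oracle(self, rng):
        aas = [sg.AA20[i] for i in rng.integers(0, 20, size=25)]
        cg = self._graph(aas)
        scores = {v: float(rng.random()) for v in cg.graph.nodes}
        pivot = sg.conservation_pivot(scores.values())
        out = sg.split_alphabet_by_conservation(cg, scores, pivot)
        for v in out.graph.nodes:
            aa = out.graph.nodes[v]["aa"]
            expected = aa.upper() if scores[v] >= pivot else aa.lower()
            assert out.label(v) == expected
            assert out.graph.nodes[v]["aa"] == aa  # amino acid recoverable

    def test_missing_score_lists_residues(self):
        cg = self._graph("AG")
        with pytest.raises(KeyError, match="2"):
            sg.split_alphabet_by_conservation(cg, {("A", "1"): 0.5}, 0.4)


class TestVariantMapping:
    @staticmethod
    def _index(*structures, **kw):
        return SequenceIndex.from_structures(structures, **kw)

    def test_window_matched_in_single_chain(self, rng):
        seq = "".join(sg.AA20[i] for i in rng.integers(0, 20, size=60))
        struct = linear_chain_structure(seq, "pdb1", resolution=1.8)
        v = VariantRecord("prot", 26, seq[25], "G" if seq[25] != "G" else "A")
        out = sg.map_variant_to_structure(v, self._index(struct), {"prot": seq})
        assert out.mapped == ("pdb1", "A", "26")

    def test_best_resolution_wins(self, rng):
        seq = "".join(sg.AA20[i] for i in rng.integers(0, 20, size=60))
        s_low = linear_chain_structure(seq, "pdb_low", resolution=2.0)
        s_high = linear_chain_structure(seq, "pdb_high", resolution=1.5)
        v = VariantRecord("prot", 30, seq[29], "G" if seq[29] != "G" else "A")
        out = sg.map_variant_to_structure(
            v, self._index(s_low, s_high), {"prot": seq}
        )
        assert out.mapped[0] == "pdb_high"

    def test_resolution_tie_broken_lexicographically(self, rng):
        seq = "".join(sg.AA20[i] for i in rng.integers(0, 20, size=60))
        s_b = linear_chain_structure(seq, "pdbB", resolution=1.5)
        s_a = linear_chain_structure(seq, "pdbA", resolution=1.5)
        v = VariantRecord("prot", 30, seq[29], "G" if seq[29] != "G" else "A")
        out = sg.map_variant_to_structure(v, self._index(s_b, s_a), {"prot": seq})
        assert out.mapped[0] == "pdbA"

    def test_single_mismatch_leaves_variant_unmapped(self, rng):
        seq = "".join(sg.AA20[i] for i in rng.integers(0, 20, size=60))
        mutated = list(seq)
        mutated[40] = "W" if seq[40] != "W" else "F"
        struct = linear_chain_structure("".join(mutated), "pdb1")
        v = VariantRecord("prot", 26, seq[25], "G" if seq[25] != "G" else "A")
        out = sg.map_variant_to_structure(v, self._index(struct), {"prot": seq})
        assert out.mapped is None
        assert "match" in out.reason

    def test_wildtype_mismatch_rejected_with_reason(self):
        seq = "A" * 60
        struct = linear_chain_structure(seq, "pdb1")
        v = VariantRecord("prot", 10, "C", "G")  # protein has A at 10
        out = sg.map_variant_to_structure(v, self._index(struct), {"prot": seq})
        assert out.mapped is None
        assert "mismatch" in out.reason

    def test_short_chains_excluded_from_index(self):
        struct = linear_chain_structure("A" * 40, "pdb1")
        idx = self._index(struct)
        assert idx.entries == []

    def test_terminal_window_is_clamped_not_padded(self, rng):
        seq = "".join(sg.AA20[i] for i in rng.integers(0, 20, size=60))
        struct = linear_chain_structure(seq, "pdb1")
        v = VariantRecord("prot", 2, seq[1], "G" if seq[1] != "G" else "A")
        out = sg.map_variant_to_structure(v, self._index(struct), {"prot": seq})
        assert out.mapped == ("pdb1", "A", "2")

    def test_mapping_is_deterministic(self, rng):
        seq = "".join(sg.AA20[i] for i in rng.integers(0, 20, size=60))
        structs = [
            linear_chain_structure(seq, f"pdb{i}", resolution=1.5 + 0.1 * i)
            for i in range(3)
        ]
        v = VariantRecord("prot", 26, seq[25], "G" if seq[25] != "G" else "A")
        results = {
            sg.map_variant_to_structure(v, self._index(*structs), {"prot": seq}).mapped
            for _ in range(5)
        }
        assert len(results) == 1

    def test_wt_equal_mt_forbidden(self):
        with pytest.raises(ValueError):
            VariantRecord("p", 1, "A", "A")
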