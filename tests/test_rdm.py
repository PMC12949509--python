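"""RDM code parsing, tree expansion and type-graph merging."""

import itertools

import pytest

from rdm2dpo import (parse_rdm, build_trees, expand_tree, make_pattern_graphs,
                     RDMParseError, NonConvertibleCodeError, lookup)
from rdm2dpo.chemgraph import MoleculeGraph
from rdm2dpo._match import rooted_isomorphic


class TestParse:
    def test_three_sections_with_star_and_plus(self):
        code = parse_rdm("C1a-C1b:*-C1a:C1b-C1b")
        assert code.r_pair == ("C1a", "C1b")
        assert code.d_pairs == (("*", "C1a"),)
        assert code.m_pairs == (("C1b", "C1b"),)

    def test_plus_separates_multiple_d_atoms(self):
        code = parse_rdm("N1b-N1b:C1a-*+C5a-*:C1a-C1a")
        assert code.d_pairs == (("C1a", "*"), ("C5a", "*"))

    def test_missing_section_is_parse_error(self):
        with pytest.raises(RDMParseError, match="3"):
            parse_rdm("C1a-C1a:*-*")

    def test_star_in_r_position_rejected(self):
        with pytest.raises(RDMParseError):
            parse_rdm("*-C1a:*-*:*-*")

    def test_star_in_m_position_rejected(self):
        with pytest.raises(RDMParseError, match="M"):
            parse_rdm("C1a-C1a:*-*:C1b-*")

    def test_unknown_type_code_rejected(self):
        with pytest.raises(RDMParseError, match="unknown"):
            parse_rdm("C9q-C1a:*-*:*-*")


class TestTrees:
    def test_r_only_code_gives_single_node_trees(self):
        lt, rt = build_trees(parse_rdm("C1a-C1b:*-*:*-*"))
        assert lt.children == () and rt.children == ()

    def test_one_sided_d_atom_omitted_from_other_tree(self):
        lt, rt = build_trees(parse_rdm("C1b-C1a:C1a-*:*-*"))
        assert len(lt.children) == 1 and rt.children == ()

    def test_m_atoms_appear_in_both_trees(self):
        lt, rt = build_trees(parse_rdm("C1b-C1b:*-*:C1a-C1a+C1a-C1a"))
        assert len(lt.children) == 2 and len(rt.children) == 2
        assert all(c.role == "M" for c in lt.children)


def _fragments(tree):
    return expand_tree(tree)


def _shape(frag):
    g = frag.graph
    return (sorted((g.nodes[v]["element"], g.nodes[v].get("hcount"))
                   for v in g.nodes),
            sorted(tuple(sorted((g.nodes[u]["element"], g.nodes[v]["element"])))
                   + (d["order"],) for u, v, d in g.edges(data=True)))


class TestMergeSemantics:
    def test_two_adjacent_c2b_yield_both_alkene_readings(self):
        lt, _ = build_trees(parse_rdm("C2b-C1a:*-*:C2b-C1a"))
        frags = _fragments(lt)
        assert len(frags) == 2
        shapes = {tuple(map(tuple, map(tuple, _shape(f)[1]))) for f, _ in frags}
        # R-HC=CH-R: the two carbons share the double bond
        assert (("*", "C", "single"), ("*", "C", "single"),
                ("C", "C", "double")) in shapes
        # R=CH-HC=R: the two carbons share the single bond
        assert (("*", "C", "double"), ("*", "C", "double"),
                ("C", "C", "single")) in shapes

    def test_extension_by_c1a_prunes_to_one_reading(self):
        lt, _ = build_trees(parse_rdm("C2b-C1a:*-*:C2b-C1a+C1a-C1a"))
        frags = _fragments(lt)
        assert len(frags) == 1
        nodes, edges = _shape(frags[0][0])
        assert ("C", 3) in nodes           # the methyl survived
        assert ("C", "C", "double") in edges

    def test_o1c_p1b_merge_at_shared_po_motif(self):
        from rdm2dpo.rdm import merge_type_graph
        o1c = lookup("O1c")[0]
        frag = MoleculeGraph()
        frag.graph = o1c.fragment.graph.copy()
        merged = merge_type_graph(frag, 0, {("R", 0): 0}, lookup("P1b")[0])
        assert len(merged) == 1
        result, _ = merged[0]
        assert len(result) == 2            # H-O-P: no extra atoms created
        assert sorted(result.element(v) for v in result.graph.nodes) == ["O", "P"]
        assert result.hcount(0) == 1


def _oracle_star_merge(root_code, child_codes):
    """Independent brute force for type graphs that are stars of the focal
    atom with wildcard-only neighbours: every injective assignment of
    children to root wildcard slots with matching bond orders, where the
    child reciprocally consumes one of its own slots of the same order."""
    results = []
    root_alts = lookup(root_code)
    child_alts = [lookup(c) for c in child_codes]
    for combo in itertools.product(root_alts, *child_alts):
        root, children = combo[0], combo[1:]
        rg = root.fragment.graph
        slots = sorted(rg.adj[root.focal])
        for placement in itertools.permutations(slots, len(children)):
            for child_slots in itertools.product(
                    *(sorted(c.fragment.graph.adj[c.focal]) for c in children)):
                ok = True
                for child, rslot, cslot in zip(children, placement, child_slots):
                    ro = rg.edges[root.focal, rslot]["order"]
                    co = child.fragment.graph.edges[child.focal, cslot]["order"]
                    if ro != co:
                        ok = False
                        break
                if not ok:
                    continue
                frag = MoleculeGraph()
                frag.graph = rg.copy()
                nxt = max(rg.nodes) + 1
                for child, rslot, cslot in zip(children, placement, child_slots):
                    cg = child.fragment.graph
                    frag.graph.nodes[rslot].update(dict(cg.nodes[child.focal]))
                    for nb in cg.adj[child.focal]:
                        if nb == cslot:
                            continue
                        frag.graph.add_node(nxt, **dict(cg.nodes[nb]))
                        frag.graph.add_edge(rslot, nxt,
                                            **dict(cg.edges[child.focal, nb]))
                        nxt += 1
                results.append(frag)
    # dedup up to rooted isomorphism
    kept = []
    for f in results:
        if not any(rooted_isomorphic(f, root_alts[0].focal, k,
                                     root_alts[0].focal, with_roles=False)
                   for k in kept):
            kept.append(f)
    return kept


@pytest.mark.parametrize("root,children", [
    ("C2b", ["C2b"]),
    ("C2b", ["C2b", "C1a"]),
    ("C1b", ["C1a", "C1a"]),
    ("C2c", ["C2a", "C1a"]),
    ("N1b", ["C1a"]),
])
def test_expansion_matches_brute_force_oracle(root, children):
    """On wildcard-star type graphs the branch-and-bound merge must equal an
    exhaustive enumeration of alternative combinations and slot pairings."""
    m_section = "+".join(f"{c}-{c}" for c in children) if children else "*-*"
    code = parse_rdm(f"{root}-{root}:*-*:{m_section}")
    lt, _ = build_trees(code)
    got = expand_tree(lt)
    expected = _oracle_star_merge(root, children)
    assert len(got) == len(expected)
    for frag, nm in got:
        assert any(rooted_isomorphic(frag, nm[("R", 0)], e, 0, with_roles=False)
                   for e in expected)


class TestPatternGraphs:
    def test_single_node_trees_give_root_correspondence(self):
        pats = make_pattern_graphs(parse_rdm("C1a-C1b:*-*:*-*", "RC1"))
        assert len(pats) == 1
        p = pats[0]
        assert p.corr == {p.left_nodes[("R", 0)]: p.right_nodes[("R", 0)]}

    def test_cartesian_pairing_of_side_expansions(self):
        # left side of C2y is ambiguous (2 readings) on both sides
        pats = make_pattern_graphs(parse_rdm("C2y-C2y:*-*:*-*", "RC2"))
        assert len(pats) == 4

    def test_undefined_code_marks_non_convertible(self):
        with pytest.raises(NonConvertibleCodeError):
            make_pattern_graphs(parse_rdm("C1a-C1a:Z-*:*-*"))

    def test_d_atoms_never_in_corr(self):
        pats = make_pattern_graphs(parse_rdm("C1b-C1a:C1a-*:C1a-C1a", "RC3"))
        for p in pats:
            d_vertex = p.left_nodes[("D", 0)]
            assert d_vertex not in p.corr
            roles = p.roles("left")
            assert roles[d_vertex] == "D"

    def test_determinism_across_runs(self):
        code = parse_rdm("C2b-C2b:C2b-*:C1a-C1a", "RC4")
        a = make_pattern_graphs(code)
        b = make_pattern_graphs(code)
        assert len(a) == len(b)
        for pa, pb in zip(a, b):
            assert _shape(pa.left) == _shape(pb.left)
            assert _shape(pa.right) == _shape(pb.right)
            assert pa.corr == pb.corr
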