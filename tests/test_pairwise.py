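"""Embedding of RDM pattern graphs and pairwise-pattern assembly."""

import itertools

import pytest

from rdm2dpo import (enumerate_embeddings, orient_sides, assemble_pairwise,
                     check_overlap_consistency, make_pattern_graphs,
                     parse_rdm, CombinatoricsLimitError)
from rdm2dpo.chemgraph import MoleculeGraph

from conftest import mol


def pattern(atoms, bonds, roles, corr_partner=None):
    m = mol(atoms, bonds)
    for v, role in roles.items():
        m.graph.nodes[v]["role"] = role
    return m


class TestEnumerateEmbeddings:
    def test_single_carbon_into_ethane_by_symmetry(self):
        p = pattern([(0, "C", 3)], [], {0: "R"})
        ethane = mol([(0, "C", 3), (1, "C", 3)], [(0, 1, "single")])
        assert len(enumerate_embeddings(p, ethane)) == 2

    def test_path_pattern_into_ethanol_is_forced(self):
        p = pattern([(0, "C", 3), (1, "C", 2), (2, "O", 1)],
                    [(0, 1, "single"), (1, 2, "single")],
                    {0: "M", 1: "R", 2: "M"})
        ethanol = mol([(0, "C", 3), (1, "C", 2), (2, "O", 1)],
                      [(0, 1, "single"), (1, 2, "single")])
        assert len(enumerate_embeddings(p, ethanol)) == 1

    def test_epoxide_wildcard_collision_yields_zero(self):
        """A 3-ring host versus a path-shaped pattern: both wildcards would
        need to land on the same atom, which a monomorphism forbids."""
        epoxide = mol([(0, "C", 1), (1, "C", 1), (2, "O", 0), (3, "C", 3),
                       (4, "C", 3)],
                      [(0, 1, "single"), (0, 2, "single"), (1, 2, "single"),
                       (0, 3, "single"), (1, 4, "single")])
        path = pattern([(0, "*", None), (1, "C", 1), (2, "O", 0),
                        (3, "*", None)],
                       [(0, 1, "single"), (1, 2, "single"), (2, 3, "single")],
                       {1: "R", 2: "M", 0: "wildcard", 3: "wildcard"})
        # the ring bonds of the host defeat the non-ring path: check both
        # with and without ring flags on the pattern
        assert enumerate_embeddings(path, epoxide) == []

    def test_hcount_equality_enforced_at_reaction_roles(self):
        p = pattern([(0, "C", 3)], [], {0: "R"})
        host = mol([(0, "C", 2), (1, "C", 2)], [(0, 1, "double")])
        assert enumerate_embeddings(p, host) == []


class TestOrientSides:
    def test_asymmetric_pattern_orients_uniquely(self):
        pats = make_pattern_graphs(parse_rdm("O1a-O2a:*-*:C1b-C1b", "RC"))
        A = mol([(0, "C", 3), (1, "C", 2), (2, "O", 1)],
                [(0, 1, "single"), (1, 2, "single")])          # has O1a
        B = mol([(0, "C", 3), (1, "C", 2), (2, "O", 0), (3, "C", 3)],
                [(0, 1, "single"), (1, 2, "single"), (2, 3, "single")])  # O2a
        assert orient_sides(pats, A, B) == "as-is"
        assert orient_sides(pats, B, A) == "swapped"

    def test_symmetric_molecules_admit_both(self):
        pats = make_pattern_graphs(parse_rdm("C1a-C1a:*-*:*-*", "RC"))
        A = mol([(0, "C", 3), (1, "C", 3)], [(0, 1, "single")])
        assert orient_sides(pats, A, A.copy()) == "both"

    def test_unembeddable_gives_neither(self):
        pats = make_pattern_graphs(parse_rdm("N1a-N1a:*-*:*-*", "RC"))
        A = mol([(0, "C", 4)])
        assert orient_sides(pats, A, A.copy()) == "neither"


class TestOverlapConsistency:
    def _two_codes(self):
        # two codes of one RCLASS sharing the central carbon of propanol
        c1 = make_pattern_graphs(parse_rdm("C1b-C1b:*-*:C1a-C1a", "RC"))[0]
        c2 = make_pattern_graphs(parse_rdm("C1b-C1b:*-*:O1a-O1a", "RC"))[0]
        return c1, c2

    def test_disjoint_images_are_vacuously_consistent(self):
        c1, c2 = self._two_codes()
        e1 = ({v: v for v in c1.left.graph.nodes},
              {v: v for v in c1.right.graph.nodes})
        e2 = ({v: v + 10 for v in c2.left.graph.nodes},
              {v: v + 10 for v in c2.right.graph.nodes})
        assert check_overlap_consistency(c1, e1, c2, e2)

    def test_shared_vertex_matched_to_same_partner_is_consistent(self):
        c1, c2 = self._two_codes()
        r1 = c1.left_nodes[("R", 0)]
        r2 = c2.left_nodes[("R", 0)]
        e1 = ({v: v for v in c1.left.graph.nodes},
              {v: v for v in c1.right.graph.nodes})
        # overlay code 2's R-atom on the same host atom, mapped to the same
        # product atom
        m2l = {r2: r1}
        m2r = {c2.corr[r2]: c1.corr[r1]}
        for v in c2.left.graph.nodes:
            m2l.setdefault(v, v + 10)
        for v in c2.right.graph.nodes:
            m2r.setdefault(v, v + 10)
        assert check_overlap_consistency(c1, e1, c2, (m2l, m2r))
        # ... and inconsistent when the partners diverge
        m2r_bad = dict(m2r)
        m2r_bad[c2.corr[r2]] = 99
        assert not check_overlap_consistency(c1, e1, c2, (m2l, m2r_bad))

    def test_matched_vs_d_vertex_is_inconsistent(self):
        cm = make_pattern_graphs(parse_rdm("C1b-C1b:*-*:C1a-C1a", "RC"))[0]
        cd = make_pattern_graphs(parse_rdm("C1b-C1a:C1a-*:*-*", "RC"))[0]
        shared = 50
        m1l = {cm.left_nodes[("M", 0)]: shared}
        for v in cm.left.graph.nodes:
            m1l.setdefault(v, v)
        m1r = {v: v for v in cm.right.graph.nodes}
        m2l = {cd.left_nodes[("D", 0)]: shared}
        for v in cd.left.graph.nodes:
            m2l.setdefault(v, v + 20)
        m2r = {v: v + 20 for v in cd.right.graph.nodes}
        assert not check_overlap_consistency(cm, (m1l, m1r), cd, (m2l, m2r))


def _brute_force_pairwise(patterns, A, B):
    """Independent oracle: enumerate embeddings by raw permutation search,
    take the Cartesian product over codes, filter by the overlap condition
    stated for pairwise patterns, and collect the union matchings."""
    def embeds(frag, host):
        fnodes = sorted(frag.graph.nodes)
        out = []
        for perm in itertools.permutations(sorted(host.graph.nodes),
                                           len(fnodes)):
            m = dict(zip(fnodes, perm))
            ok = True
            for v in fnodes:
                fe = frag.element(v)
                he = host.element(m[v])
                if fe != "*" and fe != he:
                    ok = False
                    break
                fh = frag.hcount(v)
                role = frag.graph.nodes[v].get("role")
                if fh is not None and fe != "*":
                    if role in ("R", "D", "M") and host.hcount(m[v]) != fh:
                        ok = False
                        break
                    if host.hcount(m[v]) < fh:
                        ok = False
                        break
            if not ok:
                continue
            for u, v in frag.graph.edges:
                if not host.graph.has_edge(m[u], m[v]):
                    ok = False
                    break
                fo = frag.order(u, v)
                ho = host.order(m[u], m[v])
                els = {frag.element(u), frag.element(v),
                       host.element(m[u]), host.element(m[v])}
                if fo != ho and not ("O" in els
                                     and {fo, ho} <= {"single", "double"}):
                    ok = False
                    break
            if ok:
                out.append(m)
        return out

    by_code = {}
    for p in patterns:
        by_code.setdefault(p.code_index, []).append(p)
    options = {ci: [(p, lm, rm)
                    for p in ps
                    for lm in embeds(p.left, A)
                    for rm in embeds(p.right, B)]
               for ci, ps in by_code.items()}
    matchings = set()
    for combo in itertools.product(*(options[ci] for ci in sorted(options))):
        ok = True
        for (pa, la, ra), (pb, lb, rb) in itertools.combinations(combo, 2):
            if not check_overlap_consistency(pa, (la, ra), pb, (lb, rb)):
                ok = False
                break
        if not ok:
            continue
        M = {}
        good = True
        for p, lm, rm in combo:
            for x, y in p.corr.items():
                hx, hy = lm[x], rm[y]
                if M.get(hx, hy) != hy:
                    good = False
                M[hx] = hy
        vals = list(M.values())
        if good and len(set(vals)) == len(vals):
            matchings.add(tuple(sorted(M.items())))
    return matchings


class TestAssemblePairwise:
    def _fixture(self):
        codes = [parse_rdm("C1b-C1b:*-*:O1a-O1a", "RC"),
                 parse_rdm("O1a-O1a:*-*:C1b-C1b", "RC")]
        patterns = []
        for i, c in enumerate(codes):
            for p in make_pattern_graphs(c):
                p.code_index = i
                patterns.append(p)
        A = mol([(0, "C", 3), (1, "C", 2), (2, "O", 1)],
                [(0, 1, "single"), (1, 2, "single")])
        B = mol([(0, "C", 3), (1, "C", 2), (2, "O", 1)],
                [(0, 1, "single"), (1, 2, "single")])
        return patterns, A, B

    def test_single_code_single_embedding_is_the_pattern_itself(self):
        pats = make_pattern_graphs(parse_rdm("O1a-O1a:*-*:C1b-C1b", "RC"))
        A = mol([(0, "C", 3), (1, "C", 2), (2, "O", 1)],
                [(0, 1, "single"), (1, 2, "single")])
        out = assemble_pairwise(pats, A, A.copy(), rclass_id="RC")
        assert len(out) == 1
        ppg = out[0]
        assert set(ppg.matching) == {2, 1}   # the O (R) and its C (M)

    def test_union_matches_brute_force_oracle(self):
        patterns, A, B = self._fixture()
        out = assemble_pairwise(patterns, A, B, rclass_id="RC")
        got = {tuple(sorted(p.matching.items())) for p in out}
        assert got == _brute_force_pairwise(patterns, A, B)

    def test_overlapping_codes_cover_overlap_once(self):
        patterns, A, B = self._fixture()
        out = assemble_pairwise(patterns, A, B, rclass_id="RC")
        for ppg in out:
            assert ppg.check_invariants()
            vals = list(ppg.matching.values())
            assert len(set(vals)) == len(vals)

    def test_isolated_vertex_does_not_change_output(self):
        patterns, A, B = self._fixture()
        base = assemble_pairwise(patterns, A, B, rclass_id="RC")
        A2 = A.copy()
        A2.add_atom(99, "S", hcount=2)
        bigger = assemble_pairwise(patterns, A2, B, rclass_id="RC")
        assert ({tuple(sorted(p.matching.items())) for p in base}
                == {tuple(sorted(p.matching.items())) for p in bigger})

    def test_combination_cap_raises(self):
        patterns, A, B = self._fixture()
        with pytest.raises(CombinatoricsLimitError):
            assemble_pairwise(patterns, A, B, max_combinations=0,
                              rclass_id="RC")
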