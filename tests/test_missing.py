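"""Missing-RCLASS completion: D-subgraph matching and rule repair."""

import itertools

import pytest

from rdm2dpo import (extract_d_subgraphs, match_d_subgraphs,
                     carboxy_special_case, complete_small_molecule_rule,
                     apply_rule)
from rdm2dpo.assembly import GlobalMatchState
from rdm2dpo.missing import DSubgraph
from rdm2dpo.dpo import DPORule
from rdm2dpo._match import molecules_isomorphic

from conftest import mol


def _state(l_nodes=(), r_nodes=(), roles_left=None, roles_right=None, M=None,
           pattern_images=()):
    return GlobalMatchState(M=dict(M or {}),
                            roles_left={k: set(v) for k, v in (roles_left or {}).items()},
                            roles_right={k: set(v) for k, v in (roles_right or {}).items()},
                            l_nodes=set(l_nodes), r_nodes=set(r_nodes),
                            l_edges=set(), r_edges=set(),
                            pattern_images=list(pattern_images))


class TestExtractDSubgraphs:
    def test_connected_components_per_side(self):
        G = mol([(0, "C", 3), (1, "O", 1), (2, "O", 1)],
                [(0, 1, "single")])
        H = mol([(0, "C", 4)])
        st = _state(l_nodes=[0, 1, 2],
                    roles_left={0: {"R"}, 1: {"D"}, 2: {"D"}})
        ds = extract_d_subgraphs(st, G, H)
        assert [sorted(d.vertices) for d in ds] == [[1], [2]]
        for d in ds:
            assert d.check_invariants()


class TestMatchConditions:
    def _phosphate_setup(self, pattern_images=(), roles_right=None):
        # reactant: methanol whose O leaves; product side holds methane and
        # a free phosphorous acid P(-O)(-O)(-O)
        G = mol([(0, "C", 3), (1, "O", 1)], [(0, 1, "single")])
        H = mol([(10, "C", 4), (20, "P", 0), (21, "O", 1), (22, "O", 1),
                 (23, "O", 1)],
                [(20, 21, "single"), (20, 22, "single"), (20, 23, "single")])
        st = _state(l_nodes=[0, 1], roles_left={0: {"R"}, 1: {"D"}},
                    M={0: 10}, roles_right=roles_right,
                    pattern_images=pattern_images)
        ds = [DSubgraph(side="reactant", vertices=frozenset([1]),
                        graph=G.subgraph([1]))]
        return G, H, st, ds

    def test_single_oxygen_matches_every_phosphate_oxygen(self):
        G, H, st, ds = self._phosphate_setup()
        (exts,) = match_d_subgraphs(ds, st, G, H)
        assert sorted(e[1] for e in exts) == [21, 22, 23]

    def test_candidate_equal_to_pattern_image_is_excluded(self):
        G, H, st, ds = self._phosphate_setup(
            pattern_images=[("right", frozenset([21]), "RCX")])
        (exts,) = match_d_subgraphs(ds, st, G, H)
        assert sorted(e[1] for e in exts) == [22, 23]

    def test_overlap_without_nearby_r_atom_is_excluded(self):
        # the image overlaps an integrated pattern that has no R-atom
        # anywhere near the overlap -> condition (2) rejects it
        G, H, st, ds = self._phosphate_setup(
            pattern_images=[("right", frozenset([21, 20]), "RCX")],
            roles_right={22: {"R"}})     # R-atom exists but is elsewhere
        (exts,) = match_d_subgraphs(ds, st, G, H)
        assert sorted(e[1] for e in exts) == [22, 23]

    def test_overlap_adjacent_to_r_atom_is_admitted(self):
        G, H, st, ds = self._phosphate_setup(
            pattern_images=[("right", frozenset([21, 20]), "RCX")],
            roles_right={20: {"R"}})     # R-atom adjacent to the overlap
        (exts,) = match_d_subgraphs(ds, st, G, H)
        assert sorted(e[1] for e in exts) == [21, 22, 23]

    def test_d_on_d_only_as_pure_d_match(self):
        G, H, st, ds = self._phosphate_setup(
            roles_right={21: {"D"}, 20: {"R"}},
            pattern_images=[("right", frozenset([20, 21]), "RCX")])
        (exts,) = match_d_subgraphs(ds, st, G, H)
        # image {21} consists exclusively of D-vertices: admitted
        assert 21 in {e[1] for ext in [exts] for e in ext}

    def test_matches_equal_brute_force_oracle(self):
        """DERIVED check: enumerate every injective map of the D-subgraph
        into the opposite side by hand and apply the conditions literally."""
        G, H, st, ds = self._phosphate_setup(
            pattern_images=[("right", frozenset([21]), "RCX")])
        (got,) = match_d_subgraphs(ds, st, G, H, include_carboxy=False)
        got = {tuple(sorted(e.items(), key=str)) for e in got}

        expected = set()
        d_vertices = sorted(ds[0].vertices)
        taken = set(st.M.values())
        images = [vs for side, vs, _ in st.pattern_images if side == "right"]
        for perm in itertools.permutations(sorted(H.graph.nodes, key=str),
                                           len(d_vertices)):
            m = dict(zip(d_vertices, perm))
            if any(G.element(v) != H.element(m[v]) for v in d_vertices):
                continue
            ok = all(H.graph.has_edge(m[u], m[v])
                     and H.order(m[u], m[v]) == G.order(u, v)
                     for u, v in ds[0].graph.graph.edges)
            if not ok:
                continue
            image = frozenset(m.values())
            if image & taken:
                continue
            if any(image == vs for vs in images):       # condition (1)
                continue
            d_roles = {v for v in H.graph.nodes
                       if "D" in st.roles_right.get(v, ())}
            hits = image & d_roles
            if hits and hits != image:                  # condition (3)
                continue
            cond2 = True
            for vs in images:
                overlap = image & vs
                if not overlap:
                    continue
                r_atoms = {v for v in vs
                           if "R" in st.roles_right.get(v, ())}
                near = set(overlap)
                for v in overlap:
                    near.update(H.graph.adj[v])
                if not near & r_atoms:                  # condition (2)
                    cond2 = False
            if cond2:
                expected.add(tuple(sorted(m.items(), key=str)))
        assert got == expected


class TestCarboxySpecialCase:
    def _carboxy_ds(self):
        # pyruvate-like fragment: the leaving group C(-O)(=O)
        g = mol([(0, "C", 0), (1, "O", 1), (2, "O", 0)],
                [(0, 1, "single"), (0, 2, "double")])
        return DSubgraph(side="reactant", vertices=frozenset([0, 1, 2]),
                         graph=g)

    def test_decarboxylation_maps_onto_co2(self):
        co2 = mol([(10, "C", 0), (11, "O", 0), (12, "O", 0)],
                  [(10, 11, "double"), (10, 12, "double")])
        cands = carboxy_special_case(self._carboxy_ds(), co2)
        assert len(cands) == 1
        assert cands[0][0] == 10      # carbon onto carbon

    def test_no_co2_present_yields_nothing(self):
        other = mol([(0, "C", 4)])
        assert carboxy_special_case(self._carboxy_ds(), other) == []

    def test_two_co2_products_give_two_candidates(self):
        h = mol([(10, "C", 0), (11, "O", 0), (12, "O", 0),
                 (20, "C", 0), (21, "O", 0), (22, "O", 0)],
                [(10, 11, "double"), (10, 12, "double"),
                 (20, 21, "double"), (20, 22, "double")])
        cands = carboxy_special_case(self._carboxy_ds(), h)
        assert len(cands) == 2
        assert {c[0] for c in cands} == {10, 20}


class TestCompleteSmallMoleculeRule:
    def _hydration(self):
        # C=C + water -> C-C-O: the O-H bookkeeping of water changes but no
        # RCLASS described the water molecule
        G = mol([(0, "C", 2), (1, "C", 2), (2, "O", 2)],
                [(0, 1, "double")])
        H = mol([(0, "C", 3), (1, "C", 1), (2, "O", 1)],
                [(0, 1, "single"), (1, 2, "single")])
        return G, H

    def test_uncovered_water_bond_is_added(self):
        G, H = self._hydration()
        L = G.subgraph([0, 1, 2], [(0, 1)])
        R = H.subgraph([0, 1, 2], [(0, 1)])   # the new C-O bond is missing
        rule = DPORule(L=L, R=R, beta={0: 0, 1: 1, 2: 2})
        fixed = complete_small_molecule_rule(rule, G, H)
        assert fixed.R.graph.has_edge(1, 2)
        H2, _ = apply_rule(fixed, G, {v: v for v in fixed.L.graph.nodes})
        assert molecules_isomorphic(H2, H)

    def test_completion_is_idempotent(self):
        G, H = self._hydration()
        L = G.subgraph([0, 1, 2], [(0, 1)])
        R = H.subgraph([0, 1, 2], [(0, 1)])
        rule = DPORule(L=L, R=R, beta={0: 0, 1: 1, 2: 2})
        once = complete_small_molecule_rule(rule, G, H)
        twice = complete_small_molecule_rule(once, G, H)
        assert molecules_isomorphic(once.L, twice.L)
        assert molecules_isomorphic(once.R, twice.R)

    def test_changed_edge_outside_map_stays_incomplete(self):
        G, H = self._hydration()
        L = G.subgraph([0, 1], [(0, 1)])
        R = H.subgraph([0, 1], [(0, 1)])
        rule = DPORule(L=L, R=R, beta={0: 0, 1: 1})   # water unmapped
        fixed = complete_small_molecule_rule(rule, G, H)
        assert 2 not in fixed.L.graph.nodes
        # the rule still cannot explain the reaction
        from rdm2dpo import validate_rule
        assert validate_rule(fixed, G, H) == []
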