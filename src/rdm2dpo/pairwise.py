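"""Embedding RDM pattern graphs into molecule pairs.

The RDM pattern graphs of an RCLASS are isomorphic to subgraphs of the
reactant and product molecules, so every subgraph embedding is enumerated.
KEGG stores patterns without saying which side is the reactant, so the
embeddings first fix the orientation.  When several codes of one RCLASS are
embedded, overlapping images must agree: two pattern vertices landing on the
same molecule atom must either both be D-atoms or both be matched — and then
to the same partner atom on the other side.  Every consistent combination of
(variant, embedding) choices is unioned into one pairwise pattern graph.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .chemgraph import MoleculeGraph
from ._match import find_monomorphisms, pattern_node_pred, pattern_edge_pred


class CombinatoricsLimitError(RuntimeError):
    """The number of embedding combinations exceeds the configured cap."""


@dataclass
class Embedding:
    """One injective map of one side of an RDM pattern into a host molecule."""

    pattern: object            # RDMPatternGraph
    side: str                  # 'left' | 'right'
    host: MoleculeGraph
    map: dict                  # pattern vertex -> host vertex

    @property
    def image(self):
        return frozenset(self.map.values())


@dataclass
class PairwisePatternGraph:
    """The union of consistently embedded patterns of one RCLASS in one
    reactant/product pair: subgraphs ``lhat`` of A and ``rhat`` of B plus the
    bipartite matching between their vertex sets."""

    lhat: MoleculeGraph
    rhat: MoleculeGraph
    matching: dict             # V(lhat) -> V(rhat); R/M atoms only
    roles_left: dict           # host vertex -> frozenset of roles seen there
    roles_right: dict
    rclass_id: str = ""
    provenance: tuple = ()     # ((code_idx, variant_id, l_emb_idx, r_emb_idx), ...)

    def check_invariants(self):
        vals = list(self.matching.values())
        if len(set(vals)) != len(vals):
            raise AssertionError("matching is not injective")
        for v, w in self.matching.items():
            if self.lhat.element(v) != self.rhat.element(w):
                raise AssertionError(f"matching breaks element label at {v}")
        for v, roles in self.roles_left.items():
            if roles & {"R", "M"} and v not in self.matching:
                raise AssertionError(f"R/M vertex {v} is unmatched")
            if roles == {"D"} and v in self.matching:
                raise AssertionError(f"pure D vertex {v} is matched")
        return True


def enumerate_embeddings(pattern_side: MoleculeGraph, host: MoleculeGraph):
    """All subgraph monomorphisms of one pattern side into a molecule under
    the lenient label predicates, in deterministic order."""
    return find_monomorphisms(pattern_side, host,
                              pattern_node_pred(pattern_side, host),
                              pattern_edge_pred(pattern_side, host))


def orient_sides(patterns, A: MoleculeGraph, B: MoleculeGraph) -> str:
    """Decide which molecule carries the left-hand side of the RDM codes.

    ``patterns`` holds all variants of all codes of one RCLASS.  An
    orientation is admissible when every code has at least one variant whose
    left side embeds into the reactant slot and right side into the product
    slot.  Returns ``'as-is'``, ``'swapped'``, ``'both'`` or ``'neither'``.
    """
    by_code = {}
    for p in patterns:
        by_code.setdefault(p.code_index, []).append(p)

    def admits(ra, rb):
        for code_pats in by_code.values():
            if not any(enumerate_embeddings(p.left, ra)
                       and enumerate_embeddings(p.right, rb)
                       for p in code_pats):
                return False
        return True

    as_is = admits(A, B)
    swapped = admits(B, A)
    if as_is and swapped:
        return "both"
    if as_is:
        return "as-is"
    if swapped:
        return "swapped"
    return "neither"


def swap_pattern(p):
    """The same RDM pattern graph read in the opposite direction."""
    from .rdm import RDMPatternGraph
    return RDMPatternGraph(
        left=p.right, right=p.left,
        corr={w: v for v, w in p.corr.items()},
        left_nodes=dict(p.right_nodes), right_nodes=dict(p.left_nodes),
        rclass_id=p.rclass_id, code_index=p.code_index,
        variant_id=p.variant_id, warnings=p.warnings)


def check_overlap_consistency(p1, e1, p2, e2) -> bool:
    """Consistency of two embedded codes of one RCLASS.

    ``e1``/``e2`` are (left-map, right-map) pairs.  For every host atom
    shared by the two left images, the two pattern vertices must either both
    be D-atoms or both be matched — and their partners must land on the same
    host atom on the right side.  Context and wildcard vertices impose no
    constraint.  The symmetric condition is checked on the right images.
    """
    for side in (0, 1):
        m1, m2 = e1[side], e2[side]
        om1, om2 = e1[1 - side], e2[1 - side]
        inv1 = {h: v for v, h in m1.items()}
        inv2 = {h: v for v, h in m2.items()}
        pat1 = (p1.left if side == 0 else p1.right)
        pat2 = (p2.left if side == 0 else p2.right)
        corr1 = p1.corr if side == 0 else {w: v for v, w in p1.corr.items()}
        corr2 = p2.corr if side == 0 else {w: v for v, w in p2.corr.items()}
        for h in set(inv1) & set(inv2):
            x1, x2 = inv1[h], inv2[h]
            r1 = pat1.graph.nodes[x1].get("role", "context")
            r2 = pat2.graph.nodes[x2].get("role", "context")
            if r1 not in ("R", "D", "M") or r2 not in ("R", "D", "M"):
                continue
            d1, d2 = (r1 == "D"), (r2 == "D")
            if d1 and d2:
                continue
            if d1 != d2:
                return False
            # both matched: partners must coincide on the opposite side
            if om1[corr1[x1]] != om2[corr2[x2]]:
                return False
    return True


def assemble_pairwise(patterns, A: MoleculeGraph, B: MoleculeGraph,
                      orientation="as-is", max_combinations=1000,
                      rclass_id=""):
    """All pairwise pattern graphs of one RCLASS on one molecule pair.

    ``patterns`` holds all variants of all codes.  Every combination that
    picks one (variant, left-embedding, right-embedding) per code is checked
    for pairwise overlap consistency and for the union matching remaining a
    matching; survivors are unioned.  Exceeding ``max_combinations`` raises
    :class:`CombinatoricsLimitError` (the combinatorics filter).
    """
    if orientation == "swapped":
        patterns = [swap_pattern(p) for p in patterns]
    elif orientation not in ("as-is", "both"):
        raise ValueError(f"cannot assemble with orientation {orientation!r}")

    by_code = {}
    for p in patterns:
        by_code.setdefault(p.code_index, []).append(p)

    options = {}   # code index -> [(pattern, l_map, r_map, l_idx, r_idx)]
    for ci, pats in sorted(by_code.items()):
        opts = []
        for p in pats:
            l_embs = enumerate_embeddings(p.left, A)
            r_embs = enumerate_embeddings(p.right, B)
            for li, lm in enumerate(l_embs):
                for ri, rm in enumerate(r_embs):
                    opts.append((p, lm, rm, li, ri))
        if not opts:
            return []          # this code cannot embed: RCLASS unusable here
        options[ci] = opts

    total = 1
    for opts in options.values():
        total *= len(opts)
        if total > max_combinations:
            raise CombinatoricsLimitError(
                f"{total}+ embedding combinations exceed the cap "
                f"of {max_combinations}")

    out = []
    code_order = sorted(options)
    for combo in itertools.product(*(options[ci] for ci in code_order)):
        ok = True
        for (pa, la, ra, _, _), (pb, lb, rb, _, _) in itertools.combinations(combo, 2):
            if not check_overlap_consistency(pa, (la, ra), pb, (lb, rb)):
                ok = False
                break
        if not ok:
            continue
        ppg = _union_combo(combo, A, B, rclass_id, code_order)
        if ppg is not None:
            out.append(ppg)
    return out


def _union_combo(combo, A, B, rclass_id, code_order):
    matching = {}
    roles_left, roles_right = {}, {}
    l_nodes, r_nodes = set(), set()
    l_edges, r_edges = set(), set()
    prov = []

    for (p, lm, rm, li, ri), ci in zip(combo, code_order):
        prov.append((ci, p.variant_id, li, ri))
        for pv, hv in lm.items():
            l_nodes.add(hv)
            role = p.left.graph.nodes[pv].get("role", "context")
            if role in ("R", "D", "M"):
                roles_left.setdefault(hv, set()).add(role)
        for pv, hv in rm.items():
            r_nodes.add(hv)
            role = p.right.graph.nodes[pv].get("role", "context")
            if role in ("R", "D", "M"):
                roles_right.setdefault(hv, set()).add(role)
        for (u, v) in p.left.graph.edges:
            l_edges.add(tuple(sorted((lm[u], lm[v]))))
        for (u, v) in p.right.graph.edges:
            r_edges.add(tuple(sorted((rm[u], rm[v]))))
        for x, y in p.corr.items():
            hx, hy = lm[x], rm[y]
            if matching.get(hx, hy) != hy:
                return None    # contradictory map (caught here for safety)
            matching[hx] = hy
    vals = list(matching.values())
    if len(set(vals)) != len(vals):
        return None
    ppg = PairwisePatternGraph(
        lhat=A.subgraph(sorted(l_nodes), sorted(l_edges)),
        rhat=B.subgraph(sorted(r_nodes), sorted(r_edges)),
        matching=matching,
        roles_left={v: frozenset(r) for v, r in roles_left.items()},
        roles_right={v: frozenset(r) for v, r in roles_right.items()},
        rclass_id=rclass_id, provenance=tuple(prov))
    ppg.check_invariants()
    return ppg
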