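"""Completion of atom maps when RCLASSes are missing.

KEGG does not always annotate every reactant/product pair (free phosphate,
CO2 and other small molecules are frequent omissions), so the union of the
pairwise pattern graphs can leave D-atoms unmatched.  The connected
D-subgraphs of each side are then matched against the opposite side of the
reaction by subgraph isomorphism, subject to the documented candidate
conditions, and every surviving extension is enumerated.  Two small-molecule
special cases are handled: carboxy groups losing their internal bond orders
on the way to CO2, and rules left incomplete because bond changes inside an
uncovered small molecule are not described by any code.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx

from .chemgraph import MoleculeGraph
from .dpo import DPORule
from ._match import find_monomorphisms
from .assembly import GlobalMatchState


@dataclass
class DSubgraph:
    side: str                  # 'reactant' | 'product'
    vertices: frozenset
    graph: MoleculeGraph

    def check_invariants(self):
        if not nx.is_connected(self.graph.graph):
            raise AssertionError("D-subgraph must be connected")
        return True


def extract_d_subgraphs(state: GlobalMatchState, G: MoleculeGraph,
                        H: MoleculeGraph):
    """Connected components of the unmatched D-atoms on each side."""
    out = []
    for side, mol in (("reactant", G), ("product", H)):
        key = "left" if side == "reactant" else "right"
        dv = set(state.unmatched_d(key))
        sub = mol.graph.subgraph(dv)
        for comp in sorted(nx.connected_components(sub), key=sorted):
            out.append(DSubgraph(side=side, vertices=frozenset(comp),
                                 graph=mol.subgraph(sorted(comp))))
    # larger subgraphs constrain the search first
    out.sort(key=lambda d: (-len(d.vertices), sorted(map(str, d.vertices))))
    return out


def _candidate_conditions(image, state, opp_side, adjacency):
    """The four documented admissibility conditions for a D-subgraph match
    (hydrogens are implicit, so condition 4 holds by construction)."""
    image = frozenset(image)
    roles = state.roles_right if opp_side == "right" else state.roles_left
    pattern_images = [vs for side, vs, _ in state.pattern_images
                      if side == opp_side]

    # (1) the match must not reproduce an original pattern image
    if any(image == vs for vs in pattern_images):
        return False
    # (3) mapping onto D-atoms of other patterns only as an all-D match
    d_hits = sum(1 for v in image if "D" in roles.get(v, ()))
    if d_hits and d_hits != len(image):
        return False
    # (2) overlap with an integrated pattern needs an R-atom at or next to
    #     the overlap: the match must touch the reaction centre rather than
    #     drift into plain context
    for vs in pattern_images:
        overlap = image & vs
        if not overlap:
            continue
        r_atoms = {v for v in vs if "R" in roles.get(v, ())}
        near = set(overlap)
        for v in overlap:
            near.update(adjacency.get(v, ()))
        if not (near & r_atoms):
            return False
    return True


def match_d_subgraphs(d_subgraphs, state: GlobalMatchState,
                      G: MoleculeGraph, H: MoleculeGraph,
                      include_carboxy=True):
    """All admissible match extensions for the unmatched D-subgraphs.

    Returns a list of extension dicts per D-subgraph (reactant-side vertices
    to product-side vertices in the direction of M); a D-subgraph without
    any candidate yields an empty list, leaving the rule incomplete.
    """
    per_ds = []
    for ds in d_subgraphs:
        opposite = H if ds.side == "reactant" else G
        opp_side = "right" if ds.side == "reactant" else "left"
        adjacency = {v: set(opposite.graph.adj[v])
                     for v in opposite.graph.nodes}

        def node_pred(pv, hv, _ds=ds, _opp=opposite):
            return _ds.graph.element(pv) == _opp.element(hv)

        def edge_pred(pu, pv, hu, hv, _ds=ds, _opp=opposite):
            return _ds.graph.order(pu, pv) == _opp.order(hu, hv)

        matches = find_monomorphisms(ds.graph, opposite, node_pred, edge_pred)
        if include_carboxy:
            matches = matches + carboxy_special_case(ds, opposite)

        taken = set(state.M.values()) if opp_side == "right" else set(state.M)
        exts = []
        seen = set()
        for m in matches:
            image = frozenset(m.values())
            if image & taken:
                continue           # would break the union matching
            if not _candidate_conditions(image, state, opp_side, adjacency):
                continue
            if ds.side == "reactant":
                ext = dict(m)                       # G vertex -> H vertex
            else:
                ext = {w: v for v, w in m.items()}  # G vertex -> H vertex
            key = tuple(sorted(ext.items(), key=str))
            if key in seen:
                continue
            seen.add(key)
            exts.append(ext)
        per_ds.append(exts)
    return per_ds


def carboxy_special_case(ds: DSubgraph, opposite: MoleculeGraph):
    """Match a carboxy-shaped D-subgraph (C with two O neighbours) onto CO2
    despite the internal bond-order changes that defeat plain isomorphism.

    Yields one canonical mapping per CO2 component on the opposite side.
    """
    g = ds.graph.graph
    if len(g) != 3:
        return []
    cs = [v for v in g if ds.graph.element(v) == "C"]
    os_ = sorted(v for v in g if ds.graph.element(v) == "O")
    if len(cs) != 1 or len(os_) != 2:
        return []
    c = cs[0]
    if not all(g.has_edge(c, o) for o in os_):
        return []

    out = []
    for comp in sorted(nx.connected_components(opposite.graph), key=sorted):
        if len(comp) != 3:
            continue
        ccs = [v for v in comp if opposite.element(v) == "C"]
        cos = sorted(v for v in comp if opposite.element(v) == "O")
        if len(ccs) != 1 or len(cos) != 2:
            continue
        if not all(opposite.graph.has_edge(ccs[0], o) for o in cos):
            continue
        out.append({c: ccs[0], os_[0]: cos[0], os_[1]: cos[1]})
    return out


def extend_states(state: GlobalMatchState, G, H, include_carboxy=True):
    """All completions of an incomplete state: one admissible candidate per
    D-subgraph, mutually disjoint.  Returns (extended states, report)."""
    ds = extract_d_subgraphs(state, G, H)
    if not ds:
        return [state], []
    per_ds = match_d_subgraphs(ds, state, G, H, include_carboxy=include_carboxy)
    report = [(d, len(e)) for d, e in zip(ds, per_ds)]
    if any(not e for e in per_ds):
        return [], report

    out = []
    for combo in itertools.product(*per_ds):
        M = dict(state.M)
        rev = {w: v for v, w in M.items()}
        ok = True
        for ext in combo:
            for v, w in ext.items():
                if M.get(v) == w:
                    continue   # the mirrored D-subgraph found the same pair
                if v in M or w in rev:
                    ok = False
                    break
                M[v] = w
                rev[w] = v
            if not ok:
                break
        if not ok:
            continue
        new = GlobalMatchState(
            M=M, roles_left=dict(state.roles_left),
            roles_right=dict(state.roles_right),
            l_nodes=set(state.l_nodes) | {v for ext in combo for v in ext},
            r_nodes=set(state.r_nodes) | {w for ext in combo for w in ext.values()},
            l_edges=set(state.l_edges), r_edges=set(state.r_edges),
            pattern_images=list(state.pattern_images),
            provenance=state.provenance + ("d-completion",))
        # the freshly matched atoms count as D on both sides now
        for ext in combo:
            for v, w in ext.items():
                new.roles_left.setdefault(v, set()).add("D")
                new.roles_right.setdefault(w, set()).add("D")
        out.append(new)
    return out, report


def complete_small_molecule_rule(rule: DPORule, G: MoleculeGraph,
                                 H: MoleculeGraph) -> DPORule:
    """Add to L and R every edge (and its endpoints) that changes under the
    atom map but is not yet part of the rule — bond rearrangements inside
    small molecules whose structure no RCLASS describes.  Idempotent; a
    changed edge whose endpoint has no map image leaves the rule flagged
    incomplete."""
    beta = dict(rule.beta)
    dom = set(beta)
    changed = []
    for u, v in itertools.combinations(sorted(dom, key=str), 2):
        gu, gv = u, v
        hu, hv = beta[u], beta[v]
        og = G.order(gu, gv) if G.graph.has_edge(gu, gv) else None
        oh = H.order(hu, hv) if H.graph.has_edge(hu, hv) else None
        if og != oh:
            changed.append((u, v, og, oh))

    L, R = rule.L.copy(), rule.R.copy()
    for (u, v, og, oh) in changed:
        for x, mol, host in ((u, L, G), (v, L, G)):
            if x not in mol.graph.nodes:
                mol.add_atom(x, host.element(x), hcount=host.hcount(x),
                             loops=host.loops(x))
        for x, mol, host in ((beta[u], R, H), (beta[v], R, H)):
            if x not in mol.graph.nodes:
                mol.add_atom(x, host.element(x), hcount=host.hcount(x),
                             loops=host.loops(x))
        if og is not None and not L.graph.has_edge(u, v):
            L.add_bond(u, v, order=og)
        if oh is not None and not R.graph.has_edge(beta[u], beta[v]):
            R.add_bond(beta[u], beta[v], order=oh)
    # hydrogen-count updates on mapped atoms not yet in the rule
    for x in sorted(dom, key=str):
        if x not in L.graph.nodes and G.hcount(x) != H.hcount(beta[x]):
            L.add_atom(x, G.element(x), hcount=G.hcount(x), loops=G.loops(x))
            R.add_atom(beta[x], H.element(beta[x]), hcount=H.hcount(beta[x]),
                       loops=H.loops(beta[x]))

    out = DPORule(L=L, R=R,
                  beta={v: beta[v] for v in L.graph.nodes},
                  rule_id=rule.rule_id, provenance=dict(rule.provenance),
                  roles_left=dict(rule.roles_left),
                  roles_right=dict(rule.roles_right))
    out.check_invariants()
    return out
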