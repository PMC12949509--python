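"""Chemical DPO rewriting and the imaginary transition state (ITS) graph.

A chemical reaction is a pair of graphs G (reactants) and H (products) with
an atom-to-atom map α.  The ITS graph Υ lives on V(G) and has an edge
wherever a bond exists on at least one side, labelled with the pair of bond
orders (∅ for absence); *reaction edges* are those whose two labels differ.
Any subgraph Ψ of Υ covering all reaction edges is equivalent to a DPO rule
L ← K → R: L collects the first label components, R the second, and the
maximal context K the edges on which both sides agree.  Applying that rule
back to G at its defining match regenerates H — the validity check used
throughout the pipeline.

Chemical rules preserve atoms, so only edges (and the hydrogen-count /
charge annotations, formally labelled loops) ever change.  Implicit-hydrogen
counts are carried as a vertex annotation and treated as a relabelled loop:
a rule may change a vertex's hcount but never its element.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .chemgraph import MoleculeGraph, RuleFormatError
from ._match import (find_monomorphisms, strict_node_pred, strict_edge_pred,
                     component_multiset_isomorphic)


class RuleApplicationConflict(ValueError):
    """The match violates the gluing condition: inserting an edge would
    create a parallel edge in the product."""


@dataclass
class DPORule:
    """Span L ← K → R over a common atom set with bijection ``beta``.

    K is not stored: the *maximal* context (all edges on which L and R agree)
    is recomputed on demand, which makes every stored rule canonical among
    its equivalents.
    """

    L: MoleculeGraph
    R: MoleculeGraph
    beta: dict                     # V(L) -> V(R), total bijection
    rule_id: str = ""
    complete: bool | None = None   # covers all bond changes? unknown until validated
    provenance: dict = field(default_factory=dict)
    roles_left: dict = field(default_factory=dict)    # accumulated R/D/M role sets
    roles_right: dict = field(default_factory=dict)

    def check_invariants(self):
        VL, VR = set(self.L.graph.nodes), set(self.R.graph.nodes)
        if set(self.beta) != VL or set(self.beta.values()) != VR:
            raise AssertionError("beta is not a bijection V(L) -> V(R)")
        if len(set(self.beta.values())) != len(self.beta):
            raise AssertionError("beta is not injective")
        for x, y in self.beta.items():
            if self.L.element(x) != self.R.element(y):
                raise AssertionError(f"beta does not preserve elements at {x}")
        return True

    def context_edges(self):
        """Edges of the maximal context K̂: present in both L and R (under
        beta) with equal bond order."""
        out = []
        for (u, v) in self.L.graph.edges:
            bu, bv = self.beta[u], self.beta[v]
            if self.R.graph.has_edge(bu, bv) and \
                    self.R.order(bu, bv) == self.L.order(u, v):
                out.append((u, v))
        return sorted(tuple(sorted(e)) for e in out)

    def k_graph(self) -> MoleculeGraph:
        """The maximal context K̂ on V(L)."""
        return self.L.subgraph(self.L.graph.nodes, self.context_edges())

    def reaction_edge_count(self):
        k = set(map(frozenset, self.context_edges()))
        left_only = [e for e in self.L.graph.edges if frozenset(e) not in k]
        binv = {y: x for x, y in self.beta.items()}
        right_only = []
        for (u, v) in self.R.graph.edges:
            lu, lv = binv[u], binv[v]
            if frozenset((lu, lv)) in k:
                continue
            if not self.L.graph.has_edge(lu, lv):
                right_only.append((u, v))
        # an edge changing its order is counted once
        changed = set()
        for (u, v) in left_only:
            changed.add(frozenset((u, v)))
        for (u, v) in right_only:
            lu, lv = binv[u], binv[v]
            if not self.L.graph.has_edge(lu, lv):
                changed.add(frozenset(("+R", u, v)))
        return len(changed)

    def h_exchange_count(self):
        """Total absolute change in implicit hydrogen counts across the rule
        (the hydrogen-exchange size used for rule filtering)."""
        tot = 0
        for x, y in self.beta.items():
            hl, hr = self.L.hcount(x), self.R.hcount(y)
            if hl is not None and hr is not None:
                tot += abs(hl - hr)
        return tot


@dataclass
class ITSGraph:
    """Union graph Υ over V(G): per-edge label pairs (b_G, b_H), per-vertex
    element plus the (h_G, h_H) and loop pairs.  ``alpha`` recovers H's
    vertex ids; Υ itself lives on V(G)."""

    graph: nx.Graph
    alpha: dict
    is_rule_graph: bool = False    # flags Ψ (a rule subgraph of some Υ)

    def reaction_edges(self):
        return sorted(tuple(sorted((u, v)))
                      for u, v, d in self.graph.edges(data=True)
                      if d["order_g"] != d["order_h"])

    def context_edges(self):
        return sorted(tuple(sorted((u, v)))
                      for u, v, d in self.graph.edges(data=True)
                      if d["order_g"] == d["order_h"])

    def changed_vertices(self):
        """Vertices whose annotations (hcount / loops) change."""
        return sorted(v for v, d in self.graph.nodes(data=True)
                      if d["h_g"] != d["h_h"] or d["loops_g"] != d["loops_h"])


def build_its(G: MoleculeGraph, H: MoleculeGraph, alpha: dict) -> ITSGraph:
    """Construct Υ(G, H, α).  ``alpha`` must be a total element-preserving
    bijection V(G) -> V(H)."""
    if set(alpha) != set(G.graph.nodes) or set(alpha.values()) != set(H.graph.nodes):
        raise ValueError("alpha is not a bijection V(G) -> V(H)")
    g = nx.Graph()
    for v in G.graph.nodes:
        w = alpha[v]
        if G.element(v) != H.element(w):
            raise ValueError(f"alpha does not preserve the element at {v}")
        g.add_node(v, element=G.element(v),
                   h_g=G.hcount(v), h_h=H.hcount(w),
                   loops_g=G.loops(v), loops_h=H.loops(w))
    ainv = {w: v for v, w in alpha.items()}
    for (u, v) in G.graph.edges:
        g.add_edge(u, v, order_g=G.order(u, v), order_h=None)
    for (wu, wv) in H.graph.edges:
        u, v = ainv[wu], ainv[wv]
        if g.has_edge(u, v):
            g.edges[u, v]["order_h"] = H.order(wu, wv)
        else:
            g.add_edge(u, v, order_g=None, order_h=H.order(wu, wv))
    return ITSGraph(graph=g, alpha=dict(alpha))


def extract_rule(its: ITSGraph, keep, edges=None, rule_id="") -> DPORule:
    """Turn a reaction-edge-covering subgraph Ψ of Υ into the unique DPO rule
    it defines.

    ``keep`` is the vertex set of Ψ; ``edges`` its edge set (default: all Υ
    edges induced on ``keep``).  Ψ must contain every reaction edge and its
    endpoints.
    """
    keep = set(keep)
    g = its.graph
    if edges is None:
        edges = [tuple(sorted((u, v))) for u, v in g.edges
                 if u in keep and v in keep]
    edges = {frozenset(e) for e in edges}
    for (u, v) in its.reaction_edges():
        if u not in keep or v not in keep or frozenset((u, v)) not in edges:
            raise ValueError(
                f"rule subgraph must cover reaction edge ({u}, {v})")

    L = MoleculeGraph()
    R = MoleculeGraph()
    beta = {}
    for v in sorted(keep):
        d = g.nodes[v]
        L.add_atom(v, d["element"], hcount=d["h_g"], loops=d["loops_g"])
        R.add_atom(v, d["element"], hcount=d["h_h"], loops=d["loops_h"])
        beta[v] = v
    for e in sorted(map(tuple, map(sorted, edges))):
        u, v = e
        d = g.edges[u, v]
        if d["order_g"] is not None:
            L.add_bond(u, v, order=d["order_g"])
        if d["order_h"] is not None:
            R.add_bond(u, v, order=d["order_h"])
    return DPORule(L=L, R=R, beta=beta, rule_id=rule_id,
                   provenance={"from_its": True})


def rule_to_its(rule: DPORule) -> ITSGraph:
    """The rule graph Ψ of a DPO rule (an ITS over V(L))."""
    return ITSGraph(graph=build_its(rule.L, rule.R, rule.beta).graph,
                    alpha=dict(rule.beta), is_rule_graph=True)


# ---------------------------------------------------------------------------
# rule application
# ---------------------------------------------------------------------------

def apply_rule(rule: DPORule, G: MoleculeGraph, match: dict):
    """Apply ``rule`` to ``G`` at ``match`` (a strict monomorphism L -> G).

    Returns ``(H, alpha)`` where ``alpha`` is the induced map on all of
    V(G) (the identity on vertex ids: atoms are preserved).  Raises
    :class:`RuleApplicationConflict` when inserting an edge would collide
    with a retained edge of G (the only gluing-condition failure possible
    for chemical rules).
    """
    Lg = rule.L.graph
    # verify the match is a strict label-preserving monomorphism
    if len(set(match.values())) != len(match) or set(match) != set(Lg.nodes):
        raise ValueError("match must be injective and total on V(L)")
    for x in Lg.nodes:
        if rule.L.element(x) != G.element(match[x]):
            raise ValueError(f"match does not preserve the element at {x}")
    for (u, v) in Lg.edges:
        gu, gv = match[u], match[v]
        if not G.graph.has_edge(gu, gv) or G.order(gu, gv) != rule.L.order(u, v):
            raise ValueError(f"match does not preserve the edge ({u}, {v})")

    k_edges = set(map(frozenset, rule.context_edges()))
    H = G.copy()
    # delete m(L \ K)
    for (u, v) in Lg.edges:
        if frozenset((u, v)) not in k_edges:
            H.graph.remove_edge(match[u], match[v])
    # glue in R \ K
    binv = {y: x for x, y in rule.beta.items()}
    for (ru, rv) in rule.R.graph.edges:
        lu, lv = binv[ru], binv[rv]
        if frozenset((lu, lv)) in k_edges:
            continue
        gu, gv = match[lu], match[lv]
        if H.graph.has_edge(gu, gv):
            raise RuleApplicationConflict(
                f"inserting ({gu}, {gv}) collides with a retained edge")
        H.graph.add_edge(gu, gv, order=rule.R.order(ru, rv), ring=False)
    # annotation (hcount / loop) relabelling on matched vertices
    for x in Lg.nodes:
        y = rule.beta[x]
        hv = H.graph.nodes[match[x]]
        if rule.R.hcount(y) is not None:
            hv["hcount"] = rule.R.hcount(y)
        hv["loops"] = rule.R.loops(y)
    H.recompute_ring_flags()
    alpha = {v: v for v in G.graph.nodes}
    return H, alpha


@dataclass
class MatchReport:
    match: dict
    applied: bool                  # gluing condition satisfied
    product_ok: bool | None = None # product multiset isomorphic to expected H
    product: MoleculeGraph | None = None
    alpha: dict | None = None


def enumerate_matches(rule: DPORule, G: MoleculeGraph, expected_H=None,
                      limit=None):
    """All strict monomorphisms L -> G, each applied and (optionally)
    compared against the expected product graph componentwise."""
    matches = find_monomorphisms(rule.L, G,
                                 strict_node_pred(rule.L, G),
                                 strict_edge_pred(rule.L, G),
                                 limit=limit)
    reports = []
    for m in matches:
        try:
            H, alpha = apply_rule(rule, G, m)
        except RuleApplicationConflict:
            reports.append(MatchReport(match=m, applied=False))
            continue
        ok = None
        if expected_H is not None:
            ok = component_multiset_isomorphic(H, expected_H)
        reports.append(MatchReport(match=m, applied=True, product_ok=ok,
                                   product=H, alpha=alpha))
    return reports


def validate_rule(rule: DPORule, G: MoleculeGraph, H: MoleculeGraph,
                  limit=None):
    """Final plausibility check: does at least one application of the rule
    to G produce the expected products?  Returns the successful reports."""
    reports = enumerate_matches(rule, G, expected_H=H, limit=limit)
    return [r for r in reports if r.applied and r.product_ok]


# ---------------------------------------------------------------------------
# GML rule dialect
# ---------------------------------------------------------------------------

_ORDER_TO_SYM = {"single": "-", "double": "=", "triple": "#", "aromatic": ":"}
_SYM_TO_ORDER = {v: k for k, v in _ORDER_TO_SYM.items()}


def _node_label(mol, v):
    el = mol.element(v)
    for lp in mol.loops(v):
        if lp.startswith("charge:"):
            q = int(lp.split(":")[1])
            el += ("+" * q) if q > 0 else ("-" * (-q))
    return el


def write_rule_gml(rule: DPORule) -> str:
    """Serialize a rule in the three-section GML dialect used by DPO
    rewriting tools (left / context / right over shared vertex ids).

    Vertices always appear in ``context`` (atoms are preserved); a vertex
    whose annotations change additionally appears in ``left`` and ``right``
    with its side-specific labels.  Our dialect stores the implicit hydrogen
    count as an ``hcount`` attribute.
    """
    rule.check_invariants()
    ids = {v: i + 1 for i, v in enumerate(sorted(rule.L.graph.nodes))}
    k_edges = set(map(frozenset, rule.context_edges()))

    left, context, right = [], [], []
    for v in sorted(rule.L.graph.nodes):
        w = rule.beta[v]
        lab_l, lab_r = _node_label(rule.L, v), _node_label(rule.R, w)
        h_l, h_r = rule.L.hcount(v), rule.R.hcount(w)
        if lab_l == lab_r and h_l == h_r:
            context.append(f'node [ id {ids[v]} label "{lab_l}" hcount {h_l} ]')
        else:
            left.append(f'node [ id {ids[v]} label "{lab_l}" hcount {h_l} ]')
            right.append(f'node [ id {ids[v]} label "{lab_r}" hcount {h_r} ]')
    for (u, v) in sorted(map(tuple, map(sorted, rule.L.graph.edges))):
        line = (f'edge [ source {ids[u]} target {ids[v]} '
                f'label "{_ORDER_TO_SYM[rule.L.order(u, v)]}" ]')
        if frozenset((u, v)) in k_edges:
            context.append(line)
        else:
            left.append(line)
    binv = {y: x for x, y in rule.beta.items()}
    for (ru, rv) in sorted(map(tuple, map(sorted, rule.R.graph.edges))):
        u, v = binv[ru], binv[rv]
        if frozenset((u, v)) in k_edges:
            continue
        right.append(f'edge [ source {ids[u]} target {ids[v]} '
                     f'label "{_ORDER_TO_SYM[rule.R.order(ru, rv)]}" ]')

    def section(name, lines):
        body = "\n".join(f"      {ln}" for ln in lines)
        return f"   {name} [\n{body}\n   ]" if lines else f"   {name} [ ]"

    return (f'rule [\n   ruleID "{rule.rule_id or "rule"}"\n'
            f'{section("left", left)}\n'
            f'{section("context", context)}\n'
            f'{section("right", right)}\n]\n')


def _tokenize_gml(text):
    out = []
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
        elif c in "[]":
            out.append(c)
            i += 1
        elif c == '"':
            j = text.index('"', i + 1)
            out.append(("str", text[i + 1:j]))
            i = j + 1
        else:
            j = i
            while j < n and not text[j].isspace() and text[j] not in "[]":
                j += 1
            out.append(("atom", text[i:j]))
            i = j
    return out


def _parse_gml(tokens):
    """Parse a token stream into nested (key, value) lists."""
    def parse_list(pos):
        items = []
        while pos < len(tokens) and tokens[pos] != "]":
            kind, key = tokens[pos]
            pos += 1
            if pos < len(tokens) and tokens[pos] == "[":
                sub, pos = parse_list(pos + 1)
                pos += 1  # closing ]
                items.append((key, sub))
            else:
                kind, val = tokens[pos]
                pos += 1
                if kind == "atom":
                    try:
                        val = int(val)
                    except ValueError:
                        pass
                items.append((key, val))
        return items, pos

    items, pos = parse_list(0)
    return items


def read_rule_gml(text: str) -> DPORule:
    """Parse the GML rule dialect back into a :class:`DPORule`; the writer
    and reader round-trip up to vertex renumbering."""
    items = _parse_gml(_tokenize_gml(text))
    rule_items = dict((k, v) for k, v in items).get("rule")
    if rule_items is None:
        raise RuleFormatError("no rule [...] block found")
    sections = {"left": [], "context": [], "right": []}
    rule_id = ""
    for k, v in rule_items:
        if k == "ruleID":
            rule_id = v
        elif k in sections:
            sections[k] = v

    def parse_label(lab):
        el = lab.rstrip("+-")
        q = lab.count("+") - lab.count("-")
        loops = (f"charge:{q:+d}",) if q else ()
        return el, loops

    L, R = MoleculeGraph(), MoleculeGraph()
    for sec, mols in (("left", (L,)), ("context", (L, R)), ("right", (R,))):
        for k, v in sections[sec]:
            d = dict(v)
            if k == "node":
                el, loops = parse_label(d["label"])
                h = d.get("hcount")
                h = None if h in (None, "None") else int(h)
                for mol in mols:
                    mol.add_atom(d["id"], el, hcount=h, loops=loops)
            elif k == "edge":
                for mol in mols:
                    mol.add_bond(d["source"], d["target"],
                                 order=_SYM_TO_ORDER[d["label"]])
    missing = set(L.graph.nodes) ^ set(R.graph.nodes)
    if missing:
        raise RuleFormatError(
            f"vertices {sorted(missing)} do not appear on both sides; "
            f"chemical rules preserve atoms")
    beta = {v: v for v in L.graph.nodes}
    return DPORule(L=L, R=R, beta=beta, rule_id=rule_id)
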