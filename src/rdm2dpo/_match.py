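"""Labelled-subgraph matching utilities.

One backtracking monomorphism finder (VF2-flavoured) is shared by every stage
of the pipeline; the stages differ only in the node/edge compatibility
predicates they pass in.  Pattern matching against molecules uses *lenient*
predicates: bonds involving oxygen do not distinguish single from double
order, within-ring bonds are interchangeable with aromatic bonds, and charge
loops are ignored.  Rule application uses strict label equality.
"""

from __future__ import annotations

import itertools

import networkx as nx

from .chemgraph import HALOGENS

WILDCARD = "*"
HALOGEN_CLASS = "X"


def element_match(pattern_el: str, host_el: str) -> bool:
    """Pattern-side element predicate.  ``*`` matches any heavy atom, ``X``
    matches the halogen class."""
    if pattern_el == WILDCARD:
        return host_el != "H"
    if pattern_el == HALOGEN_CLASS:
        return host_el in HALOGENS or host_el == HALOGEN_CLASS
    return pattern_el == host_el


def bond_match_lenient(p_order, p_ring, h_order, h_ring, endpoint_elements):
    """Bond compatibility under the documented leniencies.

    ``endpoint_elements`` is the set of element symbols at the four endpoints;
    it drives the oxygen single/double leniency.
    """
    if p_order == h_order:
        return bool(p_ring) == bool(h_ring)
    if "O" in endpoint_elements and {p_order, h_order} <= {"single", "double"} \
            and bool(p_ring) == bool(h_ring):
        return True
    # within-ring bonds may be read as aromatic and vice versa
    if p_order == "aromatic" and h_ring and h_order in ("single", "double"):
        return True
    if h_order == "aromatic" and p_ring and p_order in ("single", "double"):
        return True
    return False


def pattern_node_pred(pattern, host, strict_h_roles=("R", "D", "M")):
    """Node predicate for embedding an RDM pattern fragment into a molecule.

    Hydrogen counts: equality is required at reaction-annotated vertices
    (roles R/D/M), the host must carry at least the pattern's count elsewhere;
    unspecified pattern counts (``None``) match anything.  Charge loops are
    deliberately ignored (charge leniency).
    """
    pg, hg = pattern.graph, host.graph

    def pred(pv, hv):
        pd, hd = pg.nodes[pv], hg.nodes[hv]
        if not element_match(pd["element"], hd["element"]):
            return False
        ph = pd.get("hcount")
        if ph is None or pd["element"] in (WILDCARD, HALOGEN_CLASS):
            return True
        hh = hd.get("hcount")
        if hh is None:
            return True
        if pd.get("role") in strict_h_roles:
            return hh == ph
        return hh >= ph

    return pred


def pattern_edge_pred(pattern, host):
    pg, hg = pattern.graph, host.graph

    def pred(pu, pv, hu, hv):
        pd = pg.edges[pu, pv]
        hd = hg.edges[hu, hv]
        els = {pg.nodes[pu]["element"], pg.nodes[pv]["element"],
               hg.nodes[hu]["element"], hg.nodes[hv]["element"]}
        return bond_match_lenient(pd["order"], pd.get("ring", False),
                                  hd["order"], hd.get("ring", False), els)

    return pred


def strict_node_pred(pattern, host):
    """Exact element + hcount (where specified) equality; loops compared."""
    pg, hg = pattern.graph, host.graph

    def pred(pv, hv):
        pd, hd = pg.nodes[pv], hg.nodes[hv]
        if pd["element"] != hd["element"]:
            return False
        ph, hh = pd.get("hcount"), hd.get("hcount")
        if ph is not None and hh is not None and ph != hh:
            return False
        return pd.get("loops", ()) == hd.get("loops", ())

    return pred


def strict_edge_pred(pattern, host):
    pg, hg = pattern.graph, host.graph

    def pred(pu, pv, hu, hv):
        return pg.edges[pu, pv]["order"] == hg.edges[hu, hv]["order"]

    return pred


def find_monomorphisms(pattern, host, node_pred, edge_pred,
                       seed=None, limit=None):
    """All injective maps V(pattern) -> V(host) preserving edges under the
    given predicates (subgraph monomorphisms: host may have extra edges).

    ``seed`` optionally pins pattern vertices to host vertices.  Results are
    returned as dicts in a deterministic order (host candidates are explored
    in sorted order).
    """
    pg, hg = pattern.graph, host.graph
    pnodes = list(pg.nodes)
    if not pnodes:
        return [{}]

    seed = dict(seed or {})
    # order pattern vertices: seeded first, then by connectivity to the
    # already-ordered set (keeps candidate sets small), ties by node id
    order = [v for v in sorted(seed)]
    remaining = set(pnodes) - set(order)
    while remaining:
        anchored = [v for v in remaining
                    if any(u in order for u in pg.adj[v])]
        pool = anchored or sorted(remaining)
        nxt = min(pool, key=lambda v: (-sum(1 for u in pg.adj[v] if u in order), v))
        order.append(nxt)
        remaining.discard(nxt)

    hnodes = sorted(hg.nodes)
    results = []

    def backtrack(i, mapping, used):
        if limit is not None and len(results) >= limit:
            return
        if i == len(order):
            results.append(dict(mapping))
            return
        pv = order[i]
        if pv in seed:
            candidates = [seed[pv]]
        else:
            anchors = [u for u in pg.adj[pv] if u in mapping]
            if anchors:
                candidates = sorted(set(hg.adj[mapping[anchors[0]]]))
            else:
                candidates = hnodes
        for hv in candidates:
            if hv in used:
                continue
            if not node_pred(pv, hv):
                continue
            ok = True
            for pu in pg.adj[pv]:
                if pu in mapping:
                    hu = mapping[pu]
                    if not hg.has_edge(hu, hv) or not edge_pred(pu, pv, hu, hv):
                        ok = False
                        break
            if not ok:
                continue
            mapping[pv] = hv
            used.add(hv)
            backtrack(i + 1, mapping, used)
            del mapping[pv]
            used.discard(hv)

    # validate seed
    for pv, hv in seed.items():
        if not node_pred(pv, hv):
            return []
    for (pu, pv) in pg.edges:
        if pu in seed and pv in seed:
            hu, hv = seed[pu], seed[pv]
            if not hg.has_edge(hu, hv) or not edge_pred(pu, pv, hu, hv):
                return []

    backtrack(len(seed), dict(seed), set(seed.values()))
    results.sort(key=lambda m: tuple(sorted(m.items(), key=lambda kv: str(kv))))
    return results


# ---------------------------------------------------------------------------
# isomorphism helpers for deduplication and product comparison
# ---------------------------------------------------------------------------

def _nm_exact(a, b):
    return (a["element"] == b["element"]
            and a.get("hcount") == b.get("hcount")
            and a.get("loops", ()) == b.get("loops", ()))


def _em_exact(a, b):
    return (a["order"] == b["order"]
            and a.get("ring", False) == b.get("ring", False))


def molecules_isomorphic(m1, m2, with_roles=False):
    """Exact labelled-graph isomorphism between two molecule fragments."""
    if with_roles:
        def nm(a, b):
            return _nm_exact(a, b) and a.get("role") == b.get("role")
    else:
        nm = _nm_exact
    return nx.is_isomorphic(m1.graph, m2.graph, node_match=nm, edge_match=_em_exact)


def rooted_isomorphic(m1, root1, m2, root2, with_roles=True):
    """Isomorphism of fragments with the two roots pinned to each other."""
    if m1.graph.number_of_nodes() != m2.graph.number_of_nodes():
        return False
    if m1.graph.number_of_edges() != m2.graph.number_of_edges():
        return False

    def nm(a, b):
        if with_roles and a.get("role") != b.get("role"):
            return False
        return _nm_exact(a, b)

    g1 = m1.graph.copy()
    g2 = m2.graph.copy()
    g1.nodes[root1]["_root"] = True
    g2.nodes[root2]["_root"] = True

    def nm_root(a, b):
        return a.get("_root", False) == b.get("_root", False) and nm(a, b)

    return nx.is_isomorphic(g1, g2, node_match=nm_root, edge_match=_em_exact)


def component_multiset_isomorphic(g1, g2):
    """Componentwise multiset isomorphism between two (possibly disconnected)
    molecule graphs — the product-comparison predicate."""
    c1 = [g1.subgraph(c) for c in nx.connected_components(g1.graph)]
    c2 = [g2.subgraph(c) for c in nx.connected_components(g2.graph)]
    if len(c1) != len(c2):
        return False
    used = [False] * len(c2)
    # match larger components first to fail fast
    for a in sorted(c1, key=lambda m: -len(m)):
        hit = False
        for j, b in enumerate(c2):
            if used[j] or len(b) != len(a):
                continue
            if molecules_isomorphic(a, b):
                used[j] = True
                hit = True
                break
        if not hit:
            return False
    return True


def fragment_signature(mol, root=None):
    """Cheap deterministic sort key for a fragment (not canonical, used only
    for stable ordering before isomorphism-based dedup)."""
    g = mol.graph
    nodes = sorted(
        (g.nodes[v]["element"], str(g.nodes[v].get("hcount")),
         g.nodes[v].get("role", ""), g.degree[v])
        for v in g.nodes)
    edges = sorted(
        tuple(sorted((g.nodes[u]["element"], g.nodes[v]["element"]))) + (d["order"],)
        for u, v, d in g.edges(data=True))
    rootinfo = ()
    if root is not None:
        rootinfo = (g.nodes[root]["element"], str(g.nodes[root].get("hcount")),
                    g.degree[root])
    return (g.number_of_nodes(), g.number_of_edges(), rootinfo,
            tuple(nodes), tuple(edges))


def all_label_preserving_bijections(g1, g2):
    """Brute-force enumeration of element-preserving bijections V(g1)->V(g2).
    Exponential; intended for oracle tests on tiny graphs."""
    n1 = sorted(g1.graph.nodes)
    n2 = sorted(g2.graph.nodes)
    if len(n1) != len(n2):
        return
    by_el = {}
    for v in n2:
        by_el.setdefault(g2.element(v), []).append(v)
    groups = {}
    for v in n1:
        groups.setdefault(g1.element(v), []).append(v)
    if set(groups) != set(by_el):
        return
    for el in groups:
        if len(groups[el]) != len(by_el[el]):
            return
    els = sorted(groups)
    perms = [itertools.permutations(by_el[el]) for el in els]
    for combo in itertools.product(*perms):
        mapping = {}
        for el, perm in zip(els, combo):
            mapping.update(zip(groups[el], perm))
        yield mapping
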