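"""Completion of the atom-to-atom map.

A DPO rule fixes the map on every atom incident to a bond change; outside
the rule nothing changes, so a VF2-style search seeded with the rule's
partial map extends it pair by pair, admitting a pair only when all bonds to
previously matched atoms are preserved with their labels.  A seed that
cannot be extended to a bijection cannot belong to a correct rule — this is
the filter criterion for ambiguous rule candidates.

When the rule is incomplete, all combinations of embeddings of its two sides
are enumerated instead, each seeded map is extended, and the resulting full
maps are ranked by the number of bonds that still change outside the rule
(exact minimisation at desk scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .chemgraph import MoleculeGraph
from .dpo import DPORule, build_its
from ._match import find_monomorphisms, strict_node_pred, strict_edge_pred


def seeded_extension(G: MoleculeGraph, H: MoleculeGraph, seed: dict,
                     limit=None):
    """All full label-preserving bijections V(G) -> V(H) extending ``seed``.

    Every added pair must preserve bond existence and bond order against all
    previously matched pairs (including the seed); elements must agree and,
    outside the seed, implicit hydrogen counts as well.  Returns ``[]`` when
    the seed does not extend (the filter criterion).
    """
    vals = list(seed.values())
    if len(set(vals)) != len(vals):
        raise ValueError("seed must be injective")
    for x, y in seed.items():
        if G.element(x) != H.element(y):
            return []

    gg, hg = G.graph, H.graph
    if gg.number_of_nodes() != hg.number_of_nodes():
        return []

    order = []
    placed = set(seed)
    remaining = set(gg.nodes) - placed
    while remaining:
        anchored = sorted((v for v in remaining
                           if any(u in placed or u in seed for u in gg.adj[v])),
                          key=str)
        nxt = anchored[0] if anchored else sorted(remaining, key=str)[0]
        order.append(nxt)
        placed.add(nxt)
        remaining.discard(nxt)

    by_el = {}
    used0 = set(seed.values())
    for w in hg.nodes:
        if w not in used0:
            by_el.setdefault((H.element(w), H.hcount(w)), []).append(w)
    for k in by_el:
        by_el[k].sort(key=str)

    results = []

    def consistent(x, y, mapping):
        for xp, yp in mapping.items():
            ge = gg.has_edge(x, xp)
            he = hg.has_edge(y, yp)
            if ge != he:
                return False
            if ge and G.order(x, xp) != H.order(y, yp):
                return False
        return True

    def backtrack(i, mapping, used):
        if limit is not None and len(results) >= limit:
            return
        if i == len(order):
            results.append(dict(mapping))
            return
        x = order[i]
        for y in by_el.get((G.element(x), G.hcount(x)), ()):
            if y in used:
                continue
            if not consistent(x, y, mapping):
                continue
            mapping[x] = y
            used.add(y)
            backtrack(i + 1, mapping, used)
            del mapping[x]
            used.discard(y)

    backtrack(0, dict(seed), set(seed.values()))
    results.sort(key=lambda m: tuple(sorted(m.items(), key=str)))
    return results


def changing_bond_count(G, H, alpha):
    """Number of bonds created, deleted or relabelled under the map."""
    return len(build_its(G, H, alpha).reaction_edges())


def minimal_change_extensions(G: MoleculeGraph, H: MoleculeGraph, seed: dict,
                              max_results=64):
    """All element-preserving bijections extending ``seed`` that minimise the
    number of bonds changing *outside* the seeded reaction centre.

    Exact branch-and-bound: the cost of a partial map only grows as pairs
    are added, so branches whose cost exceeds the best complete map are
    pruned.  Returns ``(extensions, best_outside_cost)``; an incomplete rule
    is thereby completed with as few additional bond changes as the data
    allows (the minimisation objective of the second completion stage).
    """
    vals = list(seed.values())
    if len(set(vals)) != len(vals):
        raise ValueError("seed must be injective")
    gg, hg = G.graph, H.graph
    if gg.number_of_nodes() != hg.number_of_nodes():
        return [], None

    order = []
    placed = set(seed)
    remaining = set(gg.nodes) - placed
    while remaining:
        anchored = sorted((v for v in remaining
                           if any(u in placed for u in gg.adj[v])), key=str)
        nxt = anchored[0] if anchored else sorted(remaining, key=str)[0]
        order.append(nxt)
        placed.add(nxt)
        remaining.discard(nxt)

    by_el = {}
    used0 = set(seed.values())
    for w in hg.nodes:
        if w not in used0:
            by_el.setdefault(H.element(w), []).append(w)
    for k in by_el:
        by_el[k].sort(key=str)

    best = [None]
    results = []
    seed_set = set(seed)

    def pair_cost(x, y, mapping):
        c = 0
        for xp, yp in mapping.items():
            ge = gg.has_edge(x, xp)
            he = hg.has_edge(y, yp)
            if ge != he or (ge and G.order(x, xp) != H.order(y, yp)):
                c += 1
        return c

    def backtrack(i, mapping, used, cost):
        if best[0] is not None and cost > best[0]:
            return
        if i == len(order):
            if best[0] is None or cost < best[0]:
                best[0] = cost
                results.clear()
            if cost == best[0] and len(results) < max_results:
                results.append(dict(mapping))
            return
        x = order[i]
        for y in by_el.get(G.element(x), ()):
            if y in used:
                continue
            c = cost + pair_cost(x, y, mapping)
            if best[0] is not None and c > best[0]:
                continue
            mapping[x] = y
            used.add(y)
            backtrack(i + 1, mapping, used, c)
            del mapping[x]
            used.discard(y)

    backtrack(0, dict(seed), set(seed.values()), 0)
    results.sort(key=lambda m: tuple(sorted(m.items(), key=str)))
    return results, best[0]


@dataclass
class AAMResult:
    alpha: dict
    changing_bonds: int
    minimal: bool = False


def complete_via_rule_embeddings(rule: DPORule, G: MoleculeGraph,
                                 H: MoleculeGraph, limit_per_seed=None,
                                 max_embeddings=1000):
    """All full AAMs obtained by embedding the rule's two sides
    independently, seeding the extension with each combination, and ranking
    by the number of bonds changing outside the rule.

    Returns the deduplicated list of :class:`AAMResult`, minimal-score
    entries first; results whose induced ITS graphs are isomorphic are
    reported once.
    """
    l_embs = find_monomorphisms(rule.L, G, strict_node_pred(rule.L, G),
                                strict_edge_pred(rule.L, G),
                                limit=max_embeddings)
    r_embs = find_monomorphisms(rule.R, H, strict_node_pred(rule.R, H),
                                strict_edge_pred(rule.R, H),
                                limit=max_embeddings)
    results = []
    for ml in l_embs:
        for mr in r_embs:
            seed = {}
            ok = True
            used = set()
            for x, y in rule.beta.items():
                gx, hy = ml[x], mr[y]
                if gx in seed or hy in used:
                    ok = False
                    break
                seed[gx] = hy
                used.add(hy)
            if not ok:
                continue
            # strict extension first (a complete rule needs no extra
            # changes); otherwise minimise the remaining bond changes
            alphas = seeded_extension(G, H, seed, limit=limit_per_seed)
            if not alphas:
                alphas, _ = minimal_change_extensions(
                    G, H, seed, max_results=limit_per_seed or 64)
            for alpha in alphas:
                results.append(AAMResult(
                    alpha=alpha,
                    changing_bonds=changing_bond_count(G, H, alpha)))

    results = _dedup_by_its(G, H, results)
    if results:
        best = min(r.changing_bonds for r in results)
        for r in results:
            r.minimal = r.changing_bonds == best
        results.sort(key=lambda r: (r.changing_bonds,
                                    tuple(sorted(r.alpha.items(), key=str))))
    return results


def _dedup_by_its(G, H, results):
    seen = []
    out = []
    for r in results:
        its = build_its(G, H, r.alpha)
        composite = nx.Graph()
        for v, d in its.graph.nodes(data=True):
            composite.add_node(v, lab=(d["element"], d["h_g"], d["h_h"]))
        for u, v, d in its.graph.edges(data=True):
            composite.add_edge(u, v, lab=(d["order_g"], d["order_h"]))
        dup = False
        for prev in seen:
            if nx.is_isomorphic(prev, composite,
                                node_match=lambda a, b: a["lab"] == b["lab"],
                                edge_match=lambda a, b: a["lab"] == b["lab"]):
                dup = True
                break
        if not dup:
            seen.append(composite)
            out.append(r)
    return out


def aam_to_pairs(alpha):
    """Bit-exact serialisable form: sorted list of (G atom id, H atom id)."""
    return sorted(((list(k) if isinstance(k, tuple) else k,
                    list(v) if isinstance(v, tuple) else v)
                   for k, v in alpha.items()), key=str)


def aam_to_reaction_smiles(G: MoleculeGraph, H: MoleculeGraph, alpha: dict):
    """Mapped reaction SMILES via RDKit (atom-map numbers follow the AAM)."""
    from rdkit import Chem

    mapno = {v: i + 1 for i, v in enumerate(sorted(G.graph.nodes, key=str))}

    def to_rdkit(mol, number):
        rw = Chem.RWMol()
        idx = {}
        for v in sorted(mol.graph.nodes, key=str):
            a = Chem.Atom(mol.element(v))
            for lp in mol.loops(v):
                if lp.startswith("charge:"):
                    a.SetFormalCharge(int(lp.split(":")[1]))
            h = mol.hcount(v)
            if h is not None:
                a.SetNumExplicitHs(h)
                a.SetNoImplicit(True)
            a.SetAtomMapNum(number[v])
            idx[v] = rw.AddAtom(a)
        bt = {"single": Chem.BondType.SINGLE, "double": Chem.BondType.DOUBLE,
              "triple": Chem.BondType.TRIPLE, "aromatic": Chem.BondType.AROMATIC}
        for u, v in mol.graph.edges:
            rw.AddBond(idx[u], idx[v], bt[mol.order(u, v)])
        m = rw.GetMol()
        Chem.SanitizeMol(m, Chem.SanitizeFlags.SANITIZE_FINDRADICALS
                         | Chem.SanitizeFlags.SANITIZE_SETAROMATICITY)
        return m

    h_number = {w: mapno[v] for v, w in alpha.items()}
    gs = Chem.MolToSmiles(to_rdkit(G, mapno))
    hs = Chem.MolToSmiles(to_rdkit(H, h_number))
    return f"{gs}>>{hs}"
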