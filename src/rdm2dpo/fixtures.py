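"""Synthetic reactions with ground-truth atom maps and KEGG-style RDM codes.

The generator builds small random acyclic molecules (C/N/O/S skeletons with
valence-consistent implicit hydrogens), derives a product graph by a few
random bond edits (delete / insert / order change; implicit hydrogens keep
every valence balanced, exchanging protons with the implicit solvent the way
KEGG reactions do), and then *emits the RDM codes KEGG
would write* for every reactant/product pair that shares atoms: the R-atom
is a matched atom adjacent to an unmatched (D) atom, or — when the pair has
no unmatched atoms — a matched atom whose type changes; D- and M-atoms are
its unmatched and matched neighbours.  Atom types are assigned by looking
the local neighbourhood up in the bundled type-graph table, so the emitted
codes are guaranteed to expand back into embeddable patterns.

The ground truth (reaction graphs, atom map, ITS) is retained so that
end-to-end tests can verify that the pipeline recovers an equivalent map.

What this emulates — and what it does not: real KEGG molecules have rings,
aromatic systems and charges; the generator stays acyclic and neutral so
that every emitted code falls into the unambiguous part of the vocabulary.
A green end-to-end test therefore establishes the reconstruction logic, not
coverage of the full KEGG vocabulary (that is what the table and merge unit
tests are for).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import networkx as nx

from .chemgraph import MoleculeGraph, ReactionRecord
from .atomtypes import load_table
from .dpo import build_its, ITSGraph
from ._match import find_monomorphisms, pattern_node_pred, pattern_edge_pred

_ORDER_VAL = {"single": 1, "double": 2, "triple": 3}
_VAL = {"C": 4, "N": 3, "O": 2, "S": 2}


class FixtureError(ValueError):
    pass


@dataclass
class Fixture:
    molecules: dict                 # compound_id -> MoleculeGraph
    reaction: ReactionRecord
    rdm_codes: dict                 # rclass_id -> [code strings]
    G: MoleculeGraph                # reactant graph on global ids
    H: MoleculeGraph
    alpha: dict                     # ground-truth AAM
    its: ITSGraph = None

    def __post_init__(self):
        if self.its is None:
            self.its = build_its(self.G, self.H, self.alpha)


# ---------------------------------------------------------------------------
# random molecules
# ---------------------------------------------------------------------------

def random_molecule(rng: random.Random, n_atoms=5, elements="CCCCNO",
                    p_double=0.15, p_triple=0.03, compound_id=""):
    """Random acyclic molecule: a tree grown atom by atom, bond orders drawn
    where the valence budget allows, hydrogens filling the rest."""
    mol = MoleculeGraph(compound_id)
    free = {}
    el = rng.choice(elements)
    mol.add_atom(0, el, hcount=_VAL[el])
    free[0] = _VAL[el]
    for i in range(1, n_atoms):
        candidates = [v for v, f in free.items() if f >= 1]
        if not candidates:
            break
        parent = rng.choice(sorted(candidates))
        el = rng.choice(elements)
        r = rng.random()
        order = "single"
        if r < p_triple and free[parent] >= 3 and _VAL[el] >= 3:
            order = "triple"
        elif r < p_triple + p_double and free[parent] >= 2 and _VAL[el] >= 2:
            order = "double"
        k = _ORDER_VAL[order]
        mol.add_atom(i, el, hcount=_VAL[el] - k)
        mol.add_bond(parent, i, order=order)
        free[parent] -= k
        free[i] = _VAL[el] - k
        mol.graph.nodes[parent]["hcount"] -= k
    mol.recompute_ring_flags()
    return mol


# ---------------------------------------------------------------------------
# random reactions
# ---------------------------------------------------------------------------

_ORDER_SEQ = ["single", "double", "triple"]


def _edit_reaction(rng, G, n_edits, allow_rings=False):
    """Apply random bond edits to a copy of G, keeping hydrogen bookkeeping
    balanced; returns the product graph H (same vertex ids).

    By default inserted bonds may only join separate fragments: a ring
    closure produces 3-ring-like local structures that RDM codes cannot
    express as embeddable patterns (wildcards collide), which is tested
    separately as a negative control."""
    H = G.copy()
    g = H.graph
    edits = 0
    attempts = 0
    per_vertex = {}
    while edits < n_edits and attempts < 400:
        attempts += 1
        kind = rng.choice(["delete", "insert", "order"])
        if kind == "delete" and g.number_of_edges():
            u, v = sorted(rng.choice(sorted(map(tuple, map(sorted, g.edges)))))
            if per_vertex.get(u, 0) >= 4 or per_vertex.get(v, 0) >= 4:
                continue
            k = _ORDER_VAL[g.edges[u, v]["order"]]
            g.remove_edge(u, v)
            g.nodes[u]["hcount"] += k
            g.nodes[v]["hcount"] += k
        elif kind == "insert":
            nodes = sorted(g.nodes)
            u = rng.choice(nodes)
            v = rng.choice(nodes)
            if u == v or g.has_edge(u, v):
                continue
            if g.nodes[u]["hcount"] < 1 or g.nodes[v]["hcount"] < 1:
                continue
            if not allow_rings and nx.has_path(g, u, v):
                continue
            g.add_edge(u, v, order="single", ring=False)
            g.nodes[u]["hcount"] -= 1
            g.nodes[v]["hcount"] -= 1
        elif kind == "order" and g.number_of_edges():
            u, v = sorted(rng.choice(sorted(map(tuple, map(sorted, g.edges)))))
            cur = g.edges[u, v]["order"]
            if cur == "aromatic":
                continue
            i = _ORDER_SEQ.index(cur)
            delta = rng.choice([-1, 1])
            j = i + delta
            if not 0 <= j < len(_ORDER_SEQ):
                continue
            if delta > 0 and (g.nodes[u]["hcount"] < 1 or g.nodes[v]["hcount"] < 1):
                continue
            g.edges[u, v]["order"] = _ORDER_SEQ[j]
            g.nodes[u]["hcount"] -= delta
            g.nodes[v]["hcount"] -= delta
        else:
            continue
        edits += 1
        for x in (u, v):
            per_vertex[x] = per_vertex.get(x, 0) + 1
    if edits < n_edits:
        raise FixtureError("could not place the requested bond edits")
    if any(c > 4 for c in per_vertex.values()):
        raise FixtureError("more than 4 bonds changed at one atom")
    H.recompute_ring_flags()
    return H


# ---------------------------------------------------------------------------
# atom typing against the bundled table
# ---------------------------------------------------------------------------

def assign_atom_type(mol: MoleculeGraph, v) -> str:
    """The most specific atom-type code whose type graph embeds at ``v``
    (focal pinned, focal hydrogen count exact).  By construction every code
    this emits expands back into a pattern that matches the molecule."""
    table = load_table()
    best = None
    for code in table.codes:
        if table.is_undefined(code):
            continue
        for tg in table._entries[code]:
            frag = tg.fragment
            if frag.element(tg.focal) != mol.element(v):
                continue
            fh = frag.hcount(tg.focal)
            if fh is not None and fh != mol.hcount(v):
                continue
            if frag.loops(tg.focal) != mol.loops(v):
                continue
            if frag.graph.degree[tg.focal] != mol.graph.degree[v]:
                continue
            def exact_edge(pu, pv, hu, hv, _f=frag, _m=mol):
                pe, he = _f.graph.edges[pu, pv], _m.graph.edges[hu, hv]
                return (pe["order"] == he["order"]
                        and pe.get("ring", False) == he.get("ring", False))

            node_pred = pattern_node_pred(frag, mol, strict_h_roles=())
            exact = bool(find_monomorphisms(frag, mol, node_pred, exact_edge,
                                            seed={tg.focal: v}, limit=1))
            if not exact and not find_monomorphisms(
                    frag, mol, node_pred, pattern_edge_pred(frag, mol),
                    seed={tg.focal: v}, limit=1):
                continue
            concrete = sum(1 for x in frag.graph.nodes
                           if frag.element(x) not in ("*", "X"))
            key = (int(exact), concrete, len(frag), -tg.alt_index, code)
            if best is None or key > best[0]:
                best = (key, code)
            break
    if best is None:
        raise FixtureError(
            f"no atom type covers atom {v} ({mol.element(v)}, "
            f"h={mol.hcount(v)}, deg={mol.graph.degree[v]})")
    return best[1]


# ---------------------------------------------------------------------------
# RDM code emission
# ---------------------------------------------------------------------------

def emit_rdm_codes(Ai, Bj, shared):
    """The RDM codes KEGG would write for one reactant/product pair.

    ``shared`` is the set of atoms present on both sides (the restriction of
    the identity atom map).  Case (i): pairs with unmatched atoms get one
    code per matched atom adjacent to an unmatched one.  Case (ii): pairs
    without unmatched atoms get one code per atom whose type changes.
    """
    un_a = set(Ai.graph.nodes) - shared
    un_b = set(Bj.graph.nodes) - shared

    def typ(mol, v):
        return assign_atom_type(mol, v)

    codes = []
    # case (i): matched atoms adjacent to an unmatched atom; case (ii) and
    # bond changes inside the matched part: matched atoms whose type changes
    r_atoms = sorted({v for v in shared
                      if (set(Ai.graph.adj[v]) & un_a)
                      or (set(Bj.graph.adj[v]) & un_b)}
                     | {v for v in shared if typ(Ai, v) != typ(Bj, v)})

    for r in r_atoms:
        r_pair = f"{typ(Ai, r)}-{typ(Bj, r)}"
        d_left = sorted(typ(Ai, d) for d in set(Ai.graph.adj[r]) & un_a)
        d_right = sorted(typ(Bj, d) for d in set(Bj.graph.adj[r]) & un_b)
        n = max(len(d_left), len(d_right), 1)
        d_left += ["*"] * (n - len(d_left))
        d_right += ["*"] * (n - len(d_right))
        d_sec = "+".join(f"{a}-{b}" for a, b in zip(d_left, d_right))
        # M-atoms must be adjacent to R on both sides: the RDM grammar has no
        # absence marker in the M section, so a bond between matched atoms
        # that is formed or broken is not expressible (a documented KEGG
        # limitation); such changes surface later as incomplete rules.
        m_atoms = sorted(set(Ai.graph.adj[r]) & set(Bj.graph.adj[r]) & shared)
        if m_atoms:
            m_sec = "+".join(f"{typ(Ai, m)}-{typ(Bj, m)}" for m in m_atoms)
        else:
            m_sec = "*-*"
        codes.append(f"{r_pair}:{d_sec}:{m_sec}")
    return codes


# ---------------------------------------------------------------------------
# full fixture
# ---------------------------------------------------------------------------

def make_fixture(seed: int, n_reactants=2, atoms_per_molecule=(3, 5),
                 n_edits=2, elements="CCCCNO") -> Fixture:
    """One random reaction with ground truth and KEGG-style annotation.

    Retries internally (with sub-seeds) until the random edits yield a
    reaction whose product components are all non-trivial.
    """
    rng = random.Random(seed)
    for attempt in range(60):
        try:
            return _try_fixture(rng, n_reactants, atoms_per_molecule,
                                n_edits, elements, tag=str(seed))
        except FixtureError:
            continue
    raise FixtureError(f"no viable fixture for seed {seed}")


def _try_fixture(rng, n_reactants, atoms_per_molecule, n_edits, elements,
                 tag=""):
    mols = []
    for i in range(n_reactants):
        n = rng.randint(*atoms_per_molecule)
        mols.append(random_molecule(rng, n_atoms=n, elements=elements,
                                    compound_id=f"S{tag}_{i}"))
    G = MoleculeGraph("G")
    for i, m in enumerate(mols):
        rel = m.relabeled({v: (m.compound_id, 0, v) for v in m.graph.nodes})
        G.graph.update(rel.graph)

    H = _edit_reaction(rng, G, n_edits)
    if nx.number_connected_components(H.graph) > 4:
        raise FixtureError("too fragmented")
    if any(len(c) < 2 for c in nx.connected_components(H.graph)):
        raise FixtureError("single-atom product (KEGG leaves these untyped)")

    # product compounds = connected components of H
    products = {}
    for k, comp in enumerate(sorted(nx.connected_components(H.graph), key=sorted)):
        cid = f"P{tag}_{k}"
        sub = H.subgraph(sorted(comp))
        products[cid] = sub

    # global ids: reactants keep theirs; products get fresh per-compound ids
    alpha = {}
    prod_mols = {}
    H_global = MoleculeGraph("H")
    for cid, sub in products.items():
        mapping = {v: (cid, 0, i) for i, v in enumerate(sorted(sub.graph.nodes))}
        rel = sub.relabeled(mapping)
        H_global.graph.update(rel.graph)
        for v, w in mapping.items():
            alpha[v] = w
        local = rel.relabeled({w: w[2] for w in rel.graph.nodes})
        local.compound_id = cid
        prod_mols[cid] = local

    reactant_mols = {m.compound_id: m for m in mols}
    molecules = {**reactant_mols, **prod_mols}

    # RCLASS links and RDM codes per sharing pair
    rclass_links = []
    rdm_codes = {}
    n_rc = 0
    for rc_id_a, Am in sorted(reactant_mols.items()):
        a_globals = {(rc_id_a, 0, v) for v in Am.graph.nodes}
        for cid_b, Bm in sorted(prod_mols.items()):
            b_globals = {alpha[g] for g in a_globals if g in alpha}
            shared_b = {w for w in b_globals if w[0] == cid_b}
            if not shared_b:
                continue
            # express the pair on local compound ids
            shared_local = set()
            pair_map = {}
            for g in a_globals:
                w = alpha[g]
                if w[0] == cid_b:
                    shared_local.add(g[2])
                    pair_map[g[2]] = w[2]
            Ai = Am
            Bj = Bm
            # build the pair view: Ai on its ids, Bj relabelled so that
            # shared atoms carry the same id as in Ai
            relab = {}
            nxt = max(Ai.graph.nodes) + 1 if Ai.graph.nodes else 0
            inv_pair = {w: v for v, w in pair_map.items()}
            for w in Bj.graph.nodes:
                if w in inv_pair:
                    relab[w] = inv_pair[w]
                else:
                    relab[w] = nxt
                    nxt += 1
            Bj_view = Bj.relabeled(relab)
            codes = emit_rdm_codes(Ai, Bj_view, shared_local)
            if not codes:
                continue
            rc = f"RC{tag}_{n_rc}"
            n_rc += 1
            rclass_links.append((rc, (rc_id_a, cid_b)))
            rdm_codes[rc] = codes

    if not rdm_codes:
        raise FixtureError("reaction produced no RDM annotation")

    reaction = ReactionRecord(
        reaction_id=f"RF{tag}_{rng.randrange(10**6):06d}",
        reactants=[(cid, 1) for cid in sorted(reactant_mols)],
        products=[(cid, 1) for cid in sorted(prod_mols)],
        rclass_links=rclass_links)
    reaction.validate()

    return Fixture(molecules=molecules, reaction=reaction,
                   rdm_codes=rdm_codes, G=G, H=H_global, alpha=alpha)


def random_reaction(seed: int, n_atoms=8, n_edits=2, elements="CCCCNO"):
    """Bare (G, H, alpha) triple on one molecule — the light-weight fixture
    for rewriting/ITS property tests (no RDM emission)."""
    rng = random.Random(seed)
    for attempt in range(40):
        mol = random_molecule(rng, n_atoms=n_atoms, elements=elements,
                              compound_id="G")
        try:
            H = _edit_reaction(rng, mol, n_edits)
        except FixtureError:
            continue
        alpha = {v: v for v in mol.graph.nodes}
        return mol, H, alpha
    raise FixtureError(f"no viable reaction for seed {seed}")
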