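"""From RDM code strings to RDM pattern graphs.

An RDM code ``R:D:M`` names the reaction-centre atom (R), the difference
atoms (D, present on one side only) and the matched neighbour atoms (M) of
one reactant/product pair, each as a ``reactant-product`` pair of KEGG atom
types.  ``+`` separates multiple D/M entries, ``*`` marks absence.

Expansion proceeds in two stages.  Each side of the code first becomes a
depth-1 tree rooted at the R-atom (all D/M atoms are by definition adjacent
to it).  Each tree node's atom type is then replaced by its type graph(s) and
the type graphs are merged progressively into the root: two graphs merge at a
shared atom pair (e.g. O1c's H-O-P and P1b's P-O merge on the P-O motif) or,
failing that, by consuming a matched pair of wildcard residues whose bond
orders agree.  Merges can fail only in later steps, so the enumeration is a
branch-and-bound search over all alternative type graphs and all merge
points; the surviving fragments are deduplicated up to rooted isomorphism.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .chemgraph import MoleculeGraph
from .atomtypes import AmbiguityTable, load_table, UndefinedAtomTypeError
from ._match import (element_match, fragment_signature, rooted_isomorphic)


class RDMParseError(ValueError):
    pass


class NonConvertibleCodeError(ValueError):
    """The code involves undefined-atom classes or admits no expansion."""


@dataclass(frozen=True)
class RDMCode:
    rclass_id: str
    r_pair: tuple              # (reactant code, product code)
    d_pairs: tuple = ()        # ((reactant code | '*', product code | '*'), ...)
    m_pairs: tuple = ()


@dataclass(frozen=True)
class RDMTreeNode:
    node_id: tuple             # ('R', 0) / ('D', i) / ('M', i)
    role: str                  # 'R' | 'D' | 'M'
    code: str


@dataclass(frozen=True)
class RDMTree:
    side: str                  # 'reactant' | 'product'
    root: RDMTreeNode
    children: tuple = ()       # depth <= 1


@dataclass
class RDMPatternGraph:
    """A reactant-side / product-side fragment pair with the partial atom
    correspondence covering exactly the R- and M-atoms."""

    left: MoleculeGraph
    right: MoleculeGraph
    corr: dict                 # left vertex -> right vertex (R and M atoms)
    left_nodes: dict           # tree node_id -> left vertex
    right_nodes: dict
    rclass_id: str = ""
    code_index: int = 0
    variant_id: int = 0
    warnings: tuple = ()

    def roles(self, side="left"):
        mol = self.left if side == "left" else self.right
        return {v: mol.graph.nodes[v].get("role", "context") for v in mol.graph.nodes}


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def parse_rdm(code: str, rclass_id: str = "") -> RDMCode:
    """Parse one RDM code string (sections ``R:D:M``, sides split by ``-``,
    multiples by ``+``, absence by ``*``)."""
    sections = code.strip().split(":")
    if len(sections) != 3:
        raise RDMParseError(
            f"expected 3 colon-separated sections (R:D:M), got {len(sections)} "
            f"in {code!r}")

    def split_pairs(section, name, allow_star):
        pairs = []
        for k, part in enumerate(section.split("+")):
            halves = part.split("-")
            if len(halves) != 2:
                raise RDMParseError(
                    f"{name} entry {k} of {code!r}: expected "
                    f"'reactant-product', got {part!r}")
            a, b = halves[0].strip(), halves[1].strip()
            if not allow_star and "*" in (a, b):
                raise RDMParseError(
                    f"{name} entry {k} of {code!r}: '*' is not allowed here")
            pairs.append((a, b))
        return tuple(pairs)

    (r_pair,) = split_pairs(sections[0], "R", allow_star=False)
    d_pairs = split_pairs(sections[1], "D", allow_star=True)
    m_pairs = split_pairs(sections[2], "M", allow_star=True)
    # a lone '*-*' D or M section means "no atoms of this kind"
    if d_pairs == (("*", "*"),):
        d_pairs = ()
    if m_pairs == (("*", "*"),):
        m_pairs = ()
    for k, (a, b) in enumerate(m_pairs):
        if "*" in (a, b):
            raise RDMParseError(
                f"M entry {k} of {code!r}: M-atoms are matched by definition "
                f"and cannot be absent")
    table = load_table()
    for side in (0, 1):
        for c in [r_pair[side]] + [p[side] for p in d_pairs] + [p[side] for p in m_pairs]:
            if c != "*" and c not in table._entries:
                raise RDMParseError(f"unknown atom type {c!r} in {code!r}")
    return RDMCode(rclass_id=rclass_id, r_pair=r_pair,
                   d_pairs=d_pairs, m_pairs=m_pairs)


def build_trees(code: RDMCode):
    """Expand a parsed code into its (reactant, product) depth-1 trees; nodes
    absent on one side ('*') are omitted from that side's tree."""
    trees = []
    for side_idx, side in ((0, "reactant"), (1, "product")):
        root = RDMTreeNode(("R", 0), "R", code.r_pair[side_idx])
        children = []
        for i, pair in enumerate(code.d_pairs):
            if pair[side_idx] != "*":
                children.append(RDMTreeNode(("D", i), "D", pair[side_idx]))
        for i, pair in enumerate(code.m_pairs):
            children.append(RDMTreeNode(("M", i), "M", pair[side_idx]))
        trees.append(RDMTree(side=side, root=root, children=tuple(children)))
    return trees[0], trees[1]


# ---------------------------------------------------------------------------
# type-graph merging
# ---------------------------------------------------------------------------

def _merge_bond_compat(o1, r1, o2, r2):
    if o1 == o2:
        return r1 == r2
    # a bond drawn as within-ring may be read as aromatic, and vice versa
    if o1 == "aromatic" and r2 and o2 in ("single", "double"):
        return True
    if o2 == "aromatic" and r1 and o1 in ("single", "double"):
        return True
    return False


def _atom_compat(d1, d2):
    e1, e2 = d1["element"], d2["element"]
    if e1 != "*" and e2 != "*":
        if not (element_match(e1, e2) or element_match(e2, e1)):
            return False
    h1, h2 = d1.get("hcount"), d2.get("hcount")
    if h1 is not None and h2 is not None and h1 != h2:
        return False
    return True


def _fuse_attrs(fd, cd):
    """Merge child atom attributes into a fragment atom in place; the more
    specific value wins (concrete element over wildcard, specified hcount
    over None)."""
    if fd["element"] == "*" and cd["element"] != "*":
        fd["element"] = cd["element"]
    if cd.get("hcount") is not None:
        fd["hcount"] = cd["hcount"]
    fd["loops"] = tuple(sorted(set(fd.get("loops", ())) | set(cd.get("loops", ()))))


def merge_type_graph(frag, anchor, node_map, child_tg):
    """All legal merges of ``child_tg`` into ``frag`` such that the child's
    focal atom ends up adjacent to ``anchor`` (the root focal vertex).

    Yields ``(new_frag, child_focal_vertex)`` pairs.  A merge identifies the
    child focal with a concrete anchor neighbour of matching element (shared
    motif) or with a wildcard anchor neighbour, then enumerates every
    consistent overlap between the remaining child atoms and the existing
    fragment.  Two completeness constraints shape the search: the focal
    atom's type defines its *entire* heavy neighbourhood, so (a) every
    pre-existing neighbour of the fused atom must be covered by a child
    atom, and (b) atoms that are focals of already-merged type graphs can
    never gain additional neighbours.
    """
    fg = frag.graph
    cg = child_tg.fragment.graph
    cf = child_tg.focal
    taken = set(node_map.values())

    out = []
    for w in sorted(fg.adj[anchor], key=str):
        if w in taken:
            continue  # already serves as the focal atom of another tree node
        if not _atom_compat(fg.nodes[w], cg.nodes[cf]):
            continue
        # atoms whose heavy neighbourhood is already fully specified: the
        # focals of previously merged type graphs.  The fused atom w itself
        # is re-specified by the child's type graph, so it is exempt.
        complete = set(taken)

        # child atoms in BFS order from the focal: each has a mapped parent
        order = []
        seen = {cf}
        queue = [cf]
        while queue:
            cur = queue.pop(0)
            for nb in sorted(cg.adj[cur]):
                if nb not in seen:
                    seen.add(nb)
                    order.append(nb)
                    queue.append(nb)

        overlaps = []

        def backtrack(i, psi, used_f):
            if i == len(order):
                if set(fg.adj[w]) <= {u for u in psi.values()
                                      if not isinstance(u, tuple)}:
                    overlaps.append(dict(psi))
                return
            cv = order[i]
            parents = [cp for cp in cg.adj[cv] if cp in psi]
            mapped_parents = [psi[cp] for cp in parents
                              if not isinstance(psi[cp], tuple)]
            new_parents = [cp for cp in parents if isinstance(psi[cp], tuple)]

            # candidates: existing fragment atoms adjacent to every mapped
            # parent (identification)
            cand = None
            for fp in mapped_parents:
                s = {u for u in fg.adj[fp] if u not in used_f}
                cand = s if cand is None else cand & s
            for u in sorted(cand or [], key=str):
                if new_parents:
                    break       # an edge to a fresh atom cannot pre-exist
                if not _atom_compat(fg.nodes[u], cg.nodes[cv]):
                    continue
                ok = True
                for cp in parents:
                    fp = psi[cp]
                    fb = fg.edges[u, fp]
                    cb = cg.edges[cv, cp]
                    if not _merge_bond_compat(fb["order"], fb.get("ring", False),
                                              cb["order"], cb.get("ring", False)):
                        ok = False
                        break
                if not ok:
                    continue
                psi[cv] = u
                used_f.add(u)
                backtrack(i + 1, psi, used_f)
                del psi[cv]
                used_f.discard(u)

            # or a fresh atom — only if no parent has a complete neighbourhood
            if all(isinstance(psi[cp], tuple) or psi[cp] not in complete
                   for cp in parents):
                psi[cv] = ("new", cv)
                backtrack(i + 1, psi, used_f)
                del psi[cv]

        backtrack(0, {cf: w}, {w})
        for psi in overlaps:
            out.append(_apply_merge(frag, w, child_tg, psi))
    return out


def _apply_merge(frag, w, child_tg, psi):
    """Build the merged fragment from an overlap map ``psi`` (child atom ->
    fragment atom, or ``('new', id)`` for fresh atoms)."""
    out = frag.copy()
    g = out.graph
    cg = child_tg.fragment.graph

    ident = {}
    nxt = (max(g.nodes) + 1) if g.nodes else 0
    for cv in sorted(psi, key=str):
        tgt = psi[cv]
        if isinstance(tgt, tuple):
            g.add_node(nxt, **dict(cg.nodes[cv]))
            ident[cv] = nxt
            nxt += 1
        else:
            _fuse_attrs(g.nodes[tgt], cg.nodes[cv])
            ident[cv] = tgt

    for cu, cv in cg.edges:
        fu, fv = ident[cu], ident[cv]
        cb = cg.edges[cu, cv]
        if g.has_edge(fu, fv):
            fb = g.edges[fu, fv]
            # prefer the aromatic reading when ring/aromatic interchange fired
            if "aromatic" in (fb["order"], cb["order"]):
                fb["order"] = "aromatic"
                fb["ring"] = True
        else:
            g.add_edge(fu, fv, order=cb["order"], ring=cb.get("ring", False))
    return out, w


def expand_tree(tree: RDMTree, table: AmbiguityTable | None = None):
    """Enumerate all merge results for one RDM tree.

    Returns a deterministically ordered, deduplicated list of
    ``(fragment, node_map)`` pairs where ``node_map`` sends each tree node id
    to its focal vertex in the fragment.  Fragments carry per-vertex ``role``
    attributes (R/D/M for focal atoms, ``wildcard`` for R-residues,
    ``context`` otherwise).
    """
    table = table or load_table()
    root_alts = table.lookup(tree.root.code)    # may raise Undefined/Unknown

    states = []
    for tg in root_alts:
        frag = MoleculeGraph()
        frag.graph = tg.fragment.graph.copy()
        states.append((frag, {tree.root.node_id: tg.focal}))

    for child in tree.children:
        child_alts = table.lookup(child.code)
        new_states = []
        for frag, node_map in states:
            anchor = node_map[tree.root.node_id]
            for tg in child_alts:
                for merged, focal_v in merge_type_graph(frag, anchor, node_map, tg):
                    nm = dict(node_map)
                    nm[child.node_id] = focal_v
                    new_states.append((merged, nm))
        states = new_states
        if not states:
            break   # non-extensible branch set: the code has no expansion

    # annotate roles
    for frag, node_map in states:
        focal_roles = {v: nid[0] for nid, v in node_map.items()}
        for v, d in frag.graph.nodes(data=True):
            if v in focal_roles:
                d["role"] = focal_roles[v]
            elif d["element"] == "*":
                d["role"] = "wildcard"
            else:
                d["role"] = "context"

    # dedup up to rooted isomorphism (root pinned), deterministic order
    states.sort(key=lambda s: fragment_signature(s[0], s[1][tree.root.node_id]))
    kept = []
    for frag, nm in states:
        root_v = nm[tree.root.node_id]
        if any(rooted_isomorphic(frag, root_v, kf, knm[tree.root.node_id])
               for kf, knm in kept):
            continue
        kept.append((frag, nm))
    return kept


def make_pattern_graphs(code: RDMCode, table: AmbiguityTable | None = None):
    """All RDM pattern graphs for one code: the Cartesian pairing of
    reactant-side and product-side expansions, with the partial
    correspondence linking the R-atom and each positional M-atom pair.

    Raises :class:`NonConvertibleCodeError` when either side has no
    expansion (undefined atoms or a dead merge search).
    """
    table = table or load_table()
    left_tree, right_tree = build_trees(code)
    try:
        left_exp = expand_tree(left_tree, table)
        right_exp = expand_tree(right_tree, table)
    except UndefinedAtomTypeError as e:
        raise NonConvertibleCodeError(str(e)) from e
    if not left_exp or not right_exp:
        raise NonConvertibleCodeError(
            f"RDM code of {code.rclass_id or '<anon>'} admits no expansion")

    shared = [("R", 0)] + [("M", i) for i in range(len(code.m_pairs))]
    out = []
    vid = 0
    for (lf, lnm), (rf, rnm) in itertools.product(left_exp, right_exp):
        corr = {}
        warnings = []
        ok = True
        for nid in shared:
            lv, rv = lnm[nid], rnm[nid]
            if lf.element(lv) != rf.element(rv):
                # positional M pairing is assumed; disagreement is surfaced,
                # not silently repaired
                warnings.append(
                    f"element mismatch at {nid}: {lf.element(lv)} vs {rf.element(rv)}")
                ok = False
                break
            corr[lv] = rv
        if not ok:
            continue
        out.append(RDMPatternGraph(
            left=lf, right=rf, corr=corr,
            left_nodes=dict(lnm), right_nodes=dict(rnm),
            rclass_id=code.rclass_id, variant_id=vid,
            warnings=tuple(warnings)))
        vid += 1
    if not out:
        raise NonConvertibleCodeError(
            f"no side pairing of {code.rclass_id or '<anon>'} preserves element labels")
    return out


def expand_rclass(rclass_id: str, code_strings, table=None):
    """Parse and expand all RDM codes of one RCLASS; returns
    ``{code_index: [RDMPatternGraph, ...]}``."""
    table = table or load_table()
    result = {}
    for idx, s in enumerate(code_strings):
        code = parse_rdm(s, rclass_id)
        pats = make_pattern_graphs(code, table)
        for p in pats:
            p.code_index = idx
        result[idx] = pats
    return result
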