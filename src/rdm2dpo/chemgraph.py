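"""Molecule graphs and readers for the structure formats the pipeline touches.

Molecules are modelled as vertex- and edge-labelled simple graphs: vertices
carry a chemical element and an implicit hydrogen count, edges carry a bond
order from ``{single, double, triple, aromatic}`` plus a derived in-ring flag.
Charges and unpaired electrons are annotated as labelled *loops* on a vertex
(rather than as part of the element label) so that transformation rules never
have to change a vertex label.

Hydrogens are implicit throughout: the ``hcount`` attribute holds the number
of hydrogens bound to a heavy atom.  ``hcount`` may be ``None`` on pattern
fragments, meaning "unspecified".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

BOND_ORDERS = ("single", "double", "triple", "aromatic")

#: numeric valence contribution per bond order (aromatic counts 1.5)
_ORDER_VALENCE = {"single": 1.0, "double": 2.0, "triple": 3.0, "aromatic": 1.5}

#: default valences; elements with several common valence states list them all
_VALENCES = {
    "C": (4,),
    "N": (3,),
    "O": (2,),
    "S": (2, 4, 6),
    "P": (3, 5),
    "H": (1,),
    "F": (1,),
    "Cl": (1,),
    "Br": (1,),
    "I": (1,),
    "B": (3,),
    "Si": (4,),
    "Se": (2, 4, 6),
    "As": (3, 5),
}

HALOGENS = frozenset({"F", "Cl", "Br", "I"})


class MolParseError(ValueError):
    """Raised when a structure file cannot be parsed."""


class NonConvertibleStructureError(MolParseError):
    """Structure contains pseudo-atoms (abbreviated residues such as ``R`` or
    ``*``) and cannot be converted into a concrete molecule graph."""


class RuleFormatError(ValueError):
    """Raised when a DPO rule cannot be (de)serialized."""


class MoleculeGraph:
    """A labelled simple graph representing one compound (or a disjoint union
    of compounds).

    Thin wrapper around :class:`networkx.Graph`.  Node attributes: ``element``
    (symbol, ``"*"`` marks a wildcard in pattern fragments), ``hcount``
    (``int`` or ``None``), ``loops`` (sorted tuple of annotation strings such
    as ``"charge:+1"``), and optionally ``role``/``kcf_type`` advisory tags.
    Edge attributes: ``order`` and ``ring`` (bool).
    """

    def __init__(self, compound_id: str = ""):
        self.graph = nx.Graph()
        self.compound_id = compound_id

    # -- construction -----------------------------------------------------
    def add_atom(self, aid, element, hcount=None, loops=(), **extra):
        self.graph.add_node(aid, element=element, hcount=hcount,
                            loops=tuple(sorted(loops)), **extra)
        return aid

    def add_bond(self, u, v, order="single", ring=False, **extra):
        if u == v:
            raise ValueError("loops carry annotations only, never bond orders")
        if order not in BOND_ORDERS:
            raise ValueError(f"unknown bond order {order!r}")
        self.graph.add_edge(u, v, order=order, ring=bool(ring), **extra)

    # -- accessors --------------------------------------------------------
    def atoms(self):
        return sorted(self.graph.nodes)

    def element(self, v):
        return self.graph.nodes[v]["element"]

    def hcount(self, v):
        return self.graph.nodes[v].get("hcount")

    def loops(self, v):
        return self.graph.nodes[v].get("loops", ())

    def order(self, u, v):
        return self.graph.edges[u, v]["order"]

    def bonds(self):
        return sorted(tuple(sorted(e)) for e in self.graph.edges)

    def __len__(self):
        return self.graph.number_of_nodes()

    # -- derived data ------------------------------------------------------
    def recompute_ring_flags(self):
        """Set every edge's ``ring`` flag from cycle membership (idempotent)."""
        cycle_edges = set()
        for cyc in nx.cycle_basis(self.graph):
            n = len(cyc)
            for i in range(n):
                cycle_edges.add(frozenset((cyc[i], cyc[(i + 1) % n])))
        # cycle_basis misses chords of 2-connected components; use biconnected
        # components of size > 2 instead, which cover exactly the cyclic edges
        cyclic = set()
        for comp in nx.biconnected_component_edges(self.graph):
            comp = list(comp)
            if len(comp) > 1:
                cyclic.update(frozenset(e) for e in comp)
        for u, v, d in self.graph.edges(data=True):
            d["ring"] = frozenset((u, v)) in cyclic or d["order"] == "aromatic"

    def copy(self):
        out = MoleculeGraph(self.compound_id)
        out.graph = self.graph.copy()
        return out

    def subgraph(self, nodes, edges=None):
        """Non-induced subgraph: ``nodes`` plus either the listed ``edges`` or
        (if ``edges is None``) all induced edges."""
        out = MoleculeGraph(self.compound_id)
        for n in nodes:
            out.graph.add_node(n, **dict(self.graph.nodes[n]))
        if edges is None:
            edges = [e for e in self.graph.edges(nodes) if e[0] in nodes and e[1] in nodes]
        for (u, v) in edges:
            out.graph.add_edge(u, v, **dict(self.graph.edges[u, v]))
        return out

    def relabeled(self, mapping):
        out = MoleculeGraph(self.compound_id)
        out.graph = nx.relabel_nodes(self.graph, mapping, copy=True)
        return out

    def check_invariants(self):
        for v in self.graph.nodes:
            h = self.hcount(v)
            if h is not None and h < 0:
                raise ValueError(f"negative hcount at atom {v}")
        return True


@dataclass
class ReactionRecord:
    """One reaction: two compound lists with multiplicities plus the
    RCLASS-to-compound-pair assignments."""

    reaction_id: str
    reactants: list  # [(compound_id, multiplicity)]
    products: list
    rclass_links: list = field(default_factory=list)  # [(rclass_id, (cid_a, cid_b))]

    def validate(self):
        known = {c for c, _ in self.reactants} | {c for c, _ in self.products}
        for rc, (a, b) in self.rclass_links:
            if a not in known or b not in known:
                raise ValueError(
                    f"{self.reaction_id}: RCLASS {rc} references unknown compound "
                    f"pair ({a}, {b})")
        return True


def default_valence(element, charge=0, bond_sum=0.0):
    """Smallest standard valence state that accommodates ``bond_sum``.

    The charge convention follows the usual organic bookkeeping: cationic N/P
    gain a bond, anionic O/S/N lose one, cationic C loses one.
    """
    states = _VALENCES.get(element)
    if states is None:
        return None
    adj = 0
    if charge:
        if element in ("N", "P"):
            adj = charge
        elif element in ("O", "S", "Se"):
            adj = charge
        elif element == "C":
            adj = -abs(charge)
    for s in states:
        if s + adj >= bond_sum - 1e-9:
            return s + adj
    return states[-1] + adj


def _implicit_hcount(element, charge, bond_sum):
    val = default_valence(element, charge, bond_sum)
    if val is None:
        return 0
    return max(0, int(round(val - bond_sum)))


# ---------------------------------------------------------------------------
# MDL MOL (V2000)
# ---------------------------------------------------------------------------

_PSEUDO_ATOMS = {"R", "R#", "*", "A", "Q", "X"}


def read_mol(text: str, compound_id: str = "") -> MoleculeGraph:
    """Parse a V2000 MOL block into a :class:`MoleculeGraph`.

    Charges (``M  CHG``) become ``charge:±n`` loops, implicit hydrogen counts
    are filled in from standard valences, and ring flags are recomputed from
    cycle membership.  Structures with abbreviated-residue pseudo-atoms raise
    :class:`NonConvertibleStructureError`.
    """
    lines = text.splitlines()
    if len(lines) < 4:
        raise MolParseError("MOL block shorter than 4 lines")
    counts = lines[3]
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except (ValueError, IndexError):
        raise MolParseError(f"malformed counts line (line 4): {counts!r}")

    mol = MoleculeGraph(compound_id)
    charges = {}
    # M  CHG property lines override atom-block charge column
    for ln in lines[4 + n_atoms + n_bonds:]:
        if ln.startswith("M  CHG"):
            parts = ln.split()
            n = int(parts[2])
            for k in range(n):
                charges[int(parts[3 + 2 * k])] = int(parts[4 + 2 * k])

    elements = {}
    for i in range(n_atoms):
        idx = 4 + i
        if idx >= len(lines):
            raise MolParseError(f"atom block truncated at line {idx + 1}")
        ln = lines[idx]
        try:
            sym = ln[31:34].strip()
        except IndexError:
            raise MolParseError(f"malformed atom line {idx + 1}: {ln!r}")
        if not sym:
            raise MolParseError(f"malformed atom line {idx + 1}: {ln!r}")
        if sym in _PSEUDO_ATOMS and sym != "X":
            raise NonConvertibleStructureError(
                f"pseudo-atom {sym!r} at atom {i + 1}: structure is not convertible")
        elements[i + 1] = sym

    bonds = []
    for j in range(n_bonds):
        idx = 4 + n_atoms + j
        if idx >= len(lines):
            raise MolParseError(f"bond block truncated at line {idx + 1}")
        ln = lines[idx]
        try:
            u = int(ln[0:3]); v = int(ln[3:6]); bt = int(ln[6:9])
        except (ValueError, IndexError):
            raise MolParseError(f"malformed bond line {idx + 1}: {ln!r}")
        order = {1: "single", 2: "double", 3: "triple", 4: "aromatic"}.get(bt)
        if order is None:
            raise MolParseError(f"unsupported bond type {bt} at line {idx + 1}")
        bonds.append((u, v, order))

    bond_sum = {i: 0.0 for i in elements}
    for u, v, order in bonds:
        bond_sum[u] += _ORDER_VALENCE[order]
        bond_sum[v] += _ORDER_VALENCE[order]

    for i, sym in elements.items():
        chg = charges.get(i, 0)
        loops = (f"charge:{chg:+d}",) if chg else ()
        mol.add_atom(i, sym, hcount=_implicit_hcount(sym, chg, bond_sum[i]),
                     loops=loops)
    for u, v, order in bonds:
        mol.add_bond(u, v, order=order)
    mol.recompute_ring_flags()
    return mol


# ---------------------------------------------------------------------------
# KEGG KCF
# ---------------------------------------------------------------------------

def read_kcf(text: str, compound_id: str = "") -> MoleculeGraph:
    """Parse a KEGG KCF block.  The KCF atom-type label (KEGG's 68-class
    vocabulary) is retained per vertex as an advisory ``kcf_type`` annotation.
    """
    sections = {}
    current = None
    for ln in text.splitlines():
        if not ln.strip():
            continue
        tag = ln[:12].strip()
        if tag:
            current = tag
            sections[current] = []
        body = ln[12:] if len(ln) > 12 else ""
        if current:
            sections[current].append(body)

    if "ATOM" not in sections:
        raise MolParseError("KCF block missing ATOM section")

    atom_lines = sections["ATOM"]
    try:
        n_atoms = int(atom_lines[0].strip())
    except (ValueError, IndexError):
        raise MolParseError("KCF ATOM section missing atom count")

    mol = MoleculeGraph(compound_id)
    kcf_types = {}
    for ln in atom_lines[1:1 + n_atoms]:
        parts = ln.split()
        if len(parts) < 3:
            raise MolParseError(f"malformed KCF atom line: {ln!r}")
        idx = int(parts[0])
        ktype = parts[1]
        sym = parts[2]
        kcf_types[idx] = (ktype, sym)

    bonds = []
    if n_atoms > 1 and "BOND" not in sections:
        raise MolParseError("KCF block missing BOND section")
    if "BOND" in sections:
        bond_lines = sections["BOND"]
        n_bonds = int(bond_lines[0].strip())
        for ln in bond_lines[1:1 + n_bonds]:
            parts = ln.split()
            u, v, bt = int(parts[1]), int(parts[2]), int(parts[3])
            order = {1: "single", 2: "double", 3: "triple", 4: "aromatic"}[bt]
            bonds.append((u, v, order))

    bond_sum = {i: 0.0 for i in kcf_types}
    for u, v, order in bonds:
        bond_sum[u] += _ORDER_VALENCE[order]
        bond_sum[v] += _ORDER_VALENCE[order]

    for idx, (ktype, sym) in kcf_types.items():
        if sym in ("R", "*"):
            raise NonConvertibleStructureError(
                f"KCF pseudo-atom {sym!r} at atom {idx}")
        mol.add_atom(idx, sym, hcount=_implicit_hcount(sym, 0, bond_sum[idx]),
                     kcf_type=ktype)
    for u, v, order in bonds:
        mol.add_bond(u, v, order=order)
    mol.recompute_ring_flags()
    return mol
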