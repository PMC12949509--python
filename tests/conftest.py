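import networkx as nx
import pytest
from hypothesis import settings

from rdm2dpo import MoleculeGraph, build_its, load_table

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table():
    return load_table()


def mol(atoms, bonds=(), compound_id=""):
    """Molecule from [(id, element, hcount)] and [(u, v, order)]."""
    m = MoleculeGraph(compound_id)
    for aid, el, h in atoms:
        m.add_atom(aid, el, hcount=h)
    for u, v, order in bonds:
        m.add_bond(u, v, order=order)
    m.recompute_ring_flags()
    return m


def molblock(atoms, bonds, charges=None, name="test"):
    """Minimal V2000 MOL block: atoms = [element, ...], bonds = [(u, v,
    order-number)] with 1-based indices."""
    lines = [name, "  built by tests", "",
             f"{len(atoms):3d}{len(bonds):3d}  0  0  0  0  0  0  0  0999 V2000"]
    for sym in atoms:
        lines.append(f"{0.0:10.4f}{0.0:10.4f}{0.0:10.4f} {sym:<3}0  0  0  0  0")
    for u, v, bt in bonds:
        lines.append(f"{u:3d}{v:3d}{bt:3d}  0")
    if charges:
        items = " ".join(f"{a:3d} {c:3d}" for a, c in charges.items())
        lines.append(f"M  CHG  {len(charges)} {items}")
    lines.append("M  END")
    return "\n".join(lines) + "\n"


def its_isomorphic(G1, H1, alpha1, G2, H2, alpha2):
    """Do two atom maps induce isomorphic ITS graphs?"""
    a = build_its(G1, H1, alpha1).graph
    b = build_its(G2, H2, alpha2).graph
    return nx.is_isomorphic(
        a, b,
        node_match=lambda x, y: (x["element"], x["h_g"], x["h_h"])
                                 == (y["element"], y["h_g"], y["h_h"]),
        edge_match=lambda x, y: (x["order_g"], x["order_h"])
                                 == (y["order_g"], y["order_h"]))
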