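"""The KEGG atom-type dictionary.

Each of the 68 KEGG atom classes denotes a small labelled graph fragment (a
*type graph*) rooted at the focal atom, with wildcard "R-residues" standing
for unspecified heavy neighbours.  Several codes are ambiguous: KEGG itself
documents alternatives for five of them (C2y, N1a, N1b, N1c, N2a), and a
further 20 codes need alternative readings — mostly protonation and
resonance states — to cover structures as KEGG draws them.  The richest
entry, P1a, carries four alternatives.

The dictionary is data, not code: it ships as ``data/atom_types.yaml`` and is
loaded once per process.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import yaml

from .chemgraph import MoleculeGraph
from ._match import rooted_isomorphic

ABSENT = "*"


class UnknownAtomTypeError(KeyError):
    pass


class UndefinedAtomTypeError(ValueError):
    """The code belongs to KEGG's 'undefined atom' class; downstream stages
    must treat the carrying RCLASS as non-convertible."""


@dataclass(frozen=True)
class TypeGraph:
    """One alternative local type graph for an atom-type code."""

    code: str
    alt_index: int
    focal: int
    fragment: MoleculeGraph  # node attr 'wildcard' flags R-residues
    source: str

    def is_wildcard(self, v) -> bool:
        return self.fragment.element(v) == "*"

    @property
    def n_atoms(self):
        return len(self.fragment)


class AmbiguityTable:
    """The full 68-entry dictionary, ``code -> ordered list of TypeGraph``."""

    def __init__(self, entries, sources):
        self._entries = entries    # code -> list[TypeGraph] (empty: undefined)
        self._sources = sources    # code -> source tag

    @property
    def codes(self):
        return sorted(self._entries)

    def source(self, code):
        return self._sources[code]

    def is_undefined(self, code) -> bool:
        return self._sources.get(code) == "undefined"

    def lookup(self, code):
        """All alternative type graphs for ``code`` in documented order.

        ``"*"`` (the absence marker) yields the empty list.  Undefined-class
        codes raise :class:`UndefinedAtomTypeError`; unknown codes raise
        :class:`UnknownAtomTypeError` listing the vocabulary.
        """
        if code == ABSENT:
            return []
        if code not in self._entries:
            raise UnknownAtomTypeError(
                f"unknown atom type {code!r}; valid codes: {', '.join(self.codes)}")
        if self.is_undefined(code):
            raise UndefinedAtomTypeError(
                f"atom type {code!r} is an undefined-atom class and cannot be "
                f"expanded into a local structure")
        return list(self._entries[code])

    def table_stats(self):
        """(n_codes, n_kegg_ambiguous, n_extra_ambiguous, max_alternatives)."""
        n_codes = len(self._entries)
        n_kegg = sum(1 for c in self._entries
                     if self._sources[c] == "kegg_documented"
                     and len(self._entries[c]) > 1)
        n_extra = sum(1 for c in self._entries
                      if self._sources[c] == "inferred"
                      and len(self._entries[c]) > 1)
        max_alt = max((len(v) for v in self._entries.values()), default=0)
        return (n_codes, n_kegg, n_extra, max_alt)

    def check_invariants(self):
        """Alternatives of one code are pairwise non-isomorphic as rooted
        labelled graphs; focal atoms are never wildcards."""
        for code, alts in self._entries.items():
            for tg in alts:
                if tg.is_wildcard(tg.focal):
                    raise AssertionError(f"{code}: focal vertex is a wildcard")
            for i in range(len(alts)):
                for j in range(i + 1, len(alts)):
                    if rooted_isomorphic(alts[i].fragment, alts[i].focal,
                                         alts[j].fragment, alts[j].focal,
                                         with_roles=False):
                        raise AssertionError(
                            f"{code}: alternatives {i} and {j} are isomorphic")
        return True


def _build_fragment(spec):
    frag = MoleculeGraph()
    loops = spec.get("loops", {}) or {}
    for aid, element, hcount in spec["atoms"]:
        frag.add_atom(aid, element, hcount=hcount,
                      loops=tuple(loops.get(aid, ())))
    for u, v, order, ring in spec.get("bonds", []):
        frag.add_bond(u, v, order=order, ring=ring)
    return frag


@lru_cache(maxsize=1)
def load_table() -> AmbiguityTable:
    text = (resources.files("rdm2dpo") / "data" / "atom_types.yaml").read_text()
    raw = yaml.safe_load(text)
    entries, sources = {}, {}
    for code, entry in raw.items():
        sources[code] = entry["source"]
        alts = []
        for i, spec in enumerate(entry.get("alts", [])):
            alts.append(TypeGraph(code=code, alt_index=i, focal=0,
                                  fragment=_build_fragment(spec),
                                  source=entry["source"]))
        entries[code] = alts
    return AmbiguityTable(entries, sources)


def lookup(code):
    return load_table().lookup(code)


def table_stats():
    return load_table().table_stats()
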