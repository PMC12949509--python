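"""Reconstruction of reaction rules.

The pairwise pattern graphs of all RCLASSes of one reaction are combined by
exhaustive enumeration: a combination survives when (1) the union of the
bipartite matchings is again a matching and (2) every D-atom — an atom that
leaves its molecule pair — is matched through some other pairwise pattern.
The union of the surviving embeddings defines subgraphs L ⊆ G and R ⊆ H, the
union matching defines the atom map α, and the maximal context K (all edges
on which L and R agree) completes the DPO rule L ← K → R.

Atoms may carry several role annotations from different codes; an R label
wins over everything, and atoms labelled both M and D are treated first as
M-atoms.  Mis-declared M-atoms are caught by the role/element balance test,
mis-declared D-atoms by applying the finished rule.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

from .chemgraph import MoleculeGraph, ReactionRecord
from .pairwise import PairwisePatternGraph, CombinatoricsLimitError
from .dpo import DPORule


@dataclass
class ConflictReport:
    """Names the host atoms whose partial atom maps contradict each other."""

    vertex: object
    partners: tuple

    def __str__(self):
        return (f"atom {self.vertex} is mapped in different ways: "
                f"{' vs '.join(map(str, self.partners))}")


@dataclass
class GlobalMatchState:
    """One consistent union of pairwise matchings over the whole reaction."""

    M: dict                    # V(G) -> V(H)
    roles_left: dict           # host vertex -> set of roles
    roles_right: dict
    l_nodes: set
    r_nodes: set
    l_edges: set
    r_edges: set
    pattern_images: list       # (side, frozenset(vertices), rclass_id)
    provenance: tuple = ()

    def effective_role(self, v, side="left"):
        roles = (self.roles_left if side == "left" else self.roles_right).get(v, set())
        for r in ("R", "M", "D"):
            if r in roles:
                return r
        return "context"

    def unmatched_d(self, side="left"):
        if side == "left":
            return sorted(v for v in self.l_nodes
                          if self.effective_role(v, "left") == "D"
                          and v not in self.M)
        matched = set(self.M.values())
        return sorted(v for v in self.r_nodes
                      if self.effective_role(v, "right") == "D"
                      and v not in matched)

    def is_complete(self):
        return not self.unmatched_d("left") and not self.unmatched_d("right")


def reaction_graphs(reaction: ReactionRecord, molecules: dict):
    """Instantiate the reactant graph G and product graph H as disjoint
    unions; vertices are relabelled ``(compound_id, copy, atom_id)``."""
    def build(side):
        out = MoleculeGraph(reaction.reaction_id)
        for cid, mult in side:
            mol = molecules[cid]
            for k in range(mult):
                rel = mol.relabeled({v: (cid, k, v) for v in mol.graph.nodes})
                out.graph.update(rel.graph)
        return out

    return build(reaction.reactants), build(reaction.products)


def _union_states(selections):
    """Union a tuple of pairwise pattern graphs (already on global vertex
    ids); returns a GlobalMatchState or a list of conflicts."""
    M = {}
    conflicts = []
    state = GlobalMatchState(M=M, roles_left={}, roles_right={},
                             l_nodes=set(), r_nodes=set(),
                             l_edges=set(), r_edges=set(), pattern_images=[])
    rev = {}
    for ppg in selections:
        for v, w in ppg.matching.items():
            if v in M and M[v] != w:
                conflicts.append(ConflictReport(v, (M[v], w)))
            elif w in rev and rev[w] != v:
                conflicts.append(ConflictReport(w, (rev[w], v)))
            else:
                M[v] = w
                rev[w] = v
        state.l_nodes |= set(ppg.lhat.graph.nodes)
        state.r_nodes |= set(ppg.rhat.graph.nodes)
        state.l_edges |= {tuple(sorted(e)) for e in ppg.lhat.graph.edges}
        state.r_edges |= {tuple(sorted(e)) for e in ppg.rhat.graph.edges}
        for v, roles in ppg.roles_left.items():
            state.roles_left.setdefault(v, set()).update(roles)
        for v, roles in ppg.roles_right.items():
            state.roles_right.setdefault(v, set()).update(roles)
        state.pattern_images.append(("left", frozenset(ppg.lhat.graph.nodes),
                                     ppg.rclass_id))
        state.pattern_images.append(("right", frozenset(ppg.rhat.graph.nodes),
                                     ppg.rclass_id))
        state.provenance += (ppg.rclass_id, ppg.provenance)
    if conflicts:
        return None, conflicts
    return state, []


def balance_test(state: GlobalMatchState, G: MoleculeGraph,
                 H: MoleculeGraph) -> bool:
    """Role/element balance between the two sides: R- and M-atoms must pair
    up per element, and every reactant-side D-atom needs a product-side
    D-partner of the same element (and vice versa)."""
    def counts(side, nodes, mol):
        c = Counter()
        for v in nodes:
            role = state.effective_role(v, side)
            if role in ("R", "D", "M"):
                c[(role, mol.element(v))] += 1
        return c

    return counts("left", state.l_nodes, G) == counts("right", state.r_nodes, H)


def rule_from_state(state: GlobalMatchState, G: MoleculeGraph,
                    H: MoleculeGraph, rule_id="") -> DPORule | None:
    """Build the DPO rule of a complete state.

    Pattern-image atoms that stayed unmatched and are *not* D-atoms (wildcard
    and context images that no code pins down) carry no atom-map information;
    they are dropped, which only shrinks the optional context of the rule.
    Returns None when a reaction edge would lose an endpoint (should not
    happen for complete states).
    """
    matched_l = set(state.M)
    matched_r = set(state.M.values())
    keep_l = {v for v in state.l_nodes if v in matched_l}
    keep_r = {w for w in state.r_nodes if w in matched_r}

    L = G.subgraph(sorted(keep_l),
                   [e for e in sorted(state.l_edges)
                    if e[0] in keep_l and e[1] in keep_l])
    R = H.subgraph(sorted(keep_r),
                   [e for e in sorted(state.r_edges)
                    if e[0] in keep_r and e[1] in keep_r])
    beta = {v: state.M[v] for v in keep_l}
    if set(beta.values()) != keep_r:
        return None
    for v in keep_l:
        L.graph.nodes[v]["role"] = state.effective_role(v, "left")
    for w in keep_r:
        R.graph.nodes[w]["role"] = state.effective_role(w, "right")
    rule = DPORule(L=L, R=R, beta=beta, rule_id=rule_id,
                   roles_left={v: state.roles_left.get(v, set()) for v in keep_l},
                   roles_right={w: state.roles_right.get(w, set()) for w in keep_r},
                   provenance={"patterns": state.provenance})
    rule.check_invariants()
    return rule


@dataclass
class CombineResult:
    rules: list = field(default_factory=list)          # complete candidates
    incomplete: list = field(default_factory=list)     # GlobalMatchState
    conflicts: list = field(default_factory=list)      # ConflictReport
    status: str = "ok"


def combine_reaction(reaction: ReactionRecord, pairwise_by_link: dict,
                     G: MoleculeGraph, H: MoleculeGraph,
                     max_combinations=1000) -> CombineResult:
    """Enumerate all cross-RCLASS combinations of pairwise pattern graphs.

    ``pairwise_by_link`` maps each (rclass_id, (cid_a, cid_b)) link to its
    list of pairwise pattern graphs on global vertex ids.  Complete,
    balance-passing combinations become rule candidates; combinations with
    unmatched D-atoms are returned for the missing-RCLASS stage.
    """
    result = CombineResult()
    links = sorted(pairwise_by_link, key=str)
    option_lists = []
    total = 1
    for link in links:
        opts = pairwise_by_link[link]
        if not opts:
            result.status = "cannot_embed"
            return result
        total *= len(opts)
        if total > max_combinations:
            raise CombinatoricsLimitError(
                f"{total}+ cross-RCLASS combinations exceed the cap")
        option_lists.append(opts)

    n_rules = 0
    seen = set()
    for combo in itertools.product(*option_lists):
        state, conflicts = _union_states(combo)
        if state is None:
            result.conflicts.extend(conflicts)
            continue
        # different embedding choices frequently produce the same union
        key = (tuple(sorted(state.M.items(), key=str)),
               tuple(sorted(state.l_edges)), tuple(sorted(state.r_edges)))
        if key in seen:
            continue
        seen.add(key)
        if not state.is_complete():
            result.incomplete.append(state)
            continue
        if not balance_test(state, G, H):
            continue
        rule = rule_from_state(state, G, H,
                               rule_id=f"{reaction.reaction_id}_{n_rules}")
        if rule is not None:
            result.rules.append(rule)
            n_rules += 1

    if not result.rules and not result.incomplete and result.conflicts:
        result.status = "conflict"
    return result


def filter_hydrogen_minimal(rules):
    """Among rules with the same bond-edit structure, keep only those with
    the minimum number of hydrogen exchanges."""
    if not rules:
        return []
    groups = {}
    for rule in rules:
        k = set(map(frozenset, rule.context_edges()))
        sig = []
        for (u, v) in rule.L.graph.edges:
            if frozenset((u, v)) not in k:
                sig.append(("del", tuple(sorted((rule.L.element(u), rule.L.element(v)))),
                            rule.L.order(u, v)))
        binv = {y: x for x, y in rule.beta.items()}
        for (ru, rv) in rule.R.graph.edges:
            lu, lv = binv[ru], binv[rv]
            if frozenset((lu, lv)) in k:
                continue
            sig.append(("ins", tuple(sorted((rule.R.element(ru), rule.R.element(rv)))),
                        rule.R.order(ru, rv)))
        groups.setdefault(tuple(sorted(sig)), []).append(rule)
    out = []
    for sig, grp in sorted(groups.items()):
        best = min(r.h_exchange_count() for r in grp)
        out.extend(r for r in grp if r.h_exchange_count() == best)
    return out
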