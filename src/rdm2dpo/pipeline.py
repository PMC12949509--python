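"""Five-step workflow: expand → pair → rules → completion → AAM.

Each reaction passes through the same stages the standalone subcommands
expose: RDM codes are expanded into pattern graphs, embedded pairwise into
their molecule pairs, combined across RCLASSes into rule candidates,
completed via D-subgraph matching where RCLASSes are missing, validated by
rule application, and finally turned into full atom-to-atom maps.  Every
reaction ends in exactly one status of the failure taxonomy; the pipeline
never raises on bad input data.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

from .chemgraph import ReactionRecord, NonConvertibleStructureError
from .rdm import expand_rclass, NonConvertibleCodeError, RDMParseError
from .pairwise import (assemble_pairwise, orient_sides, swap_pattern,
                       CombinatoricsLimitError)
from .assembly import (combine_reaction, reaction_graphs, rule_from_state,
                       balance_test, filter_hydrogen_minimal)
from .missing import extend_states, complete_small_molecule_rule
from .dpo import validate_rule
from .aam import (complete_via_rule_embeddings, AAMResult,
                  changing_bond_count, _dedup_by_its)
from ._match import find_monomorphisms, strict_node_pred, strict_edge_pred

#: the per-reaction outcome taxonomy
STATUSES = ("aam_complete", "aam_partial", "rule_only", "conflict",
            "combinatorics_skip", "timeout", "no_structure",
            "undefined_atoms", "no_rclass", "cannot_embed")


@dataclass
class PipelineConfig:
    max_combinations: int = 1000     # per reaction side, the combination filter
    rule_timeout: float = 7200.0     # seconds per rule application stage
    filter_hydrogens: bool = True
    max_aams: int = 200


@dataclass
class ReactionResult:
    reaction_id: str
    status: str
    rules: list = field(default_factory=list)
    aams: list = field(default_factory=list)         # AAMResult
    conflicts: list = field(default_factory=list)
    detail: str = ""

    def row(self):
        return (self.reaction_id, self.status, len(self.rules),
                len(self.aams), self.detail)


def run_reaction(reaction: ReactionRecord, molecules: dict, rdm_codes: dict,
                 config: PipelineConfig | None = None) -> ReactionResult:
    """Run one reaction through the whole pipeline.

    ``molecules`` maps compound ids to molecule graphs, ``rdm_codes`` maps
    each linked rclass id to its list of RDM code strings.
    """
    config = config or PipelineConfig()
    rid = reaction.reaction_id
    t0 = time.monotonic()

    def timed_out():
        return time.monotonic() - t0 > config.rule_timeout

    if not reaction.rclass_links:
        return ReactionResult(rid, "no_rclass")
    for cid, _ in reaction.reactants + reaction.products:
        if cid not in molecules:
            return ReactionResult(rid, "no_structure",
                                  detail=f"missing structure for {cid}")

    # step 1: expand every linked RCLASS
    patterns = {}
    for rc_id, _pair in reaction.rclass_links:
        if rc_id in patterns:
            continue
        try:
            expanded = expand_rclass(rc_id, rdm_codes.get(rc_id, []))
        except NonConvertibleCodeError as e:
            return ReactionResult(rid, "undefined_atoms", detail=str(e))
        except RDMParseError as e:
            return ReactionResult(rid, "undefined_atoms",
                                  detail=f"unparsable RDM code: {e}")
        if not expanded:
            return ReactionResult(rid, "no_rclass",
                                  detail=f"{rc_id} carries no RDM codes")
        patterns[rc_id] = [p for pats in expanded.values() for p in pats]

    G, H = reaction_graphs(reaction, molecules)

    # steps 2-3: orient and embed per link, on instance vertex ids
    pairwise_by_link = {}
    try:
        for rc_id, (cid_a, cid_b) in reaction.rclass_links:
            opts = []
            for ia in _instances(reaction.reactants, cid_a):
                for ib in _instances(reaction.products, cid_b):
                    A = _instance_graph(molecules[cid_a], cid_a, ia)
                    B = _instance_graph(molecules[cid_b], cid_b, ib)
                    orientation = orient_sides(patterns[rc_id], A, B)
                    if orientation == "neither":
                        continue
                    for orient in (("as-is", "swapped") if orientation == "both"
                                   else (orientation,)):
                        opts.extend(assemble_pairwise(
                            patterns[rc_id], A, B, orientation=orient,
                            max_combinations=config.max_combinations,
                            rclass_id=rc_id))
            if not opts:
                return ReactionResult(rid, "cannot_embed",
                                      detail=f"{rc_id} does not embed into "
                                             f"({cid_a}, {cid_b})")
            pairwise_by_link[(rc_id, (cid_a, cid_b))] = opts
    except CombinatoricsLimitError as e:
        return ReactionResult(rid, "combinatorics_skip", detail=str(e))

    # step 4: combine across RCLASSes
    try:
        combined = combine_reaction(reaction, pairwise_by_link, G, H,
                                    max_combinations=config.max_combinations)
    except CombinatoricsLimitError as e:
        return ReactionResult(rid, "combinatorics_skip", detail=str(e))

    candidates = list(combined.rules)
    # missing-RCLASS completion of incomplete states
    for state in combined.incomplete:
        extended, _report = extend_states(state, G, H)
        for k, st in enumerate(extended):
            if not st.is_complete() or not balance_test(st, G, H):
                continue
            rule = rule_from_state(st, G, H, rule_id=f"{rid}_dc{k}")
            if rule is not None:
                rule = complete_small_molecule_rule(rule, G, H)
                candidates.append(rule)

    if not candidates:
        if combined.conflicts:
            return ReactionResult(rid, "conflict",
                                  conflicts=combined.conflicts,
                                  detail="; ".join(map(str, combined.conflicts[:3])))
        return ReactionResult(rid, "rule_only",
                              detail="no complete rule candidate")

    # validation: apply each candidate at its defining match
    validated, partial = [], []
    for rule in candidates:
        if timed_out():
            return ReactionResult(rid, "timeout", rules=validated)
        reports = validate_rule(rule, G, H, limit=config.max_combinations)
        if reports:
            rule.complete = True
            validated.append((rule, reports))
        else:
            rule.complete = False
            partial.append(rule)

    if config.filter_hydrogens and validated:
        keep = set(map(id, filter_hydrogen_minimal([r for r, _ in validated])))
        validated = [(r, reps) for r, reps in validated if id(r) in keep]

    # step 5: AAMs.  A successful application yields a product graph H'
    # isomorphic to H; composing the application map with each H' -> H
    # isomorphism gives the AAMs the rule defines directly.
    result_rules = [r for r, _ in validated] or partial
    aams = []
    for rule, reports in validated:
        for rep in reports:
            isos = find_monomorphisms(
                rep.product, H,
                strict_node_pred(rep.product, H),
                strict_edge_pred(rep.product, H),
                limit=max(1, config.max_aams - len(aams)))
            for iso in isos:
                aams.append({v: iso[rep.alpha[v]] for v in rep.alpha})
        if len(aams) >= config.max_aams:
            break
    if validated:
        res = [AAMResult(alpha=a, changing_bonds=changing_bond_count(G, H, a))
               for a in aams]
        res = _dedup_by_its(G, H, res)
        for r in res:
            r.minimal = True
        return ReactionResult(rid, "aam_complete", rules=result_rules, aams=res)

    # fall back to embedding enumeration for incomplete rules
    for rule in partial:
        if timed_out():
            return ReactionResult(rid, "timeout", rules=result_rules)
        res = complete_via_rule_embeddings(rule, G, H,
                                          max_embeddings=config.max_combinations)
        best = [r for r in res if r.minimal]
        if best:
            return ReactionResult(rid, "aam_partial", rules=result_rules,
                                  aams=best,
                                  detail="AAM from embedding enumeration with "
                                         "bond-change minimisation")
    return ReactionResult(rid, "rule_only", rules=result_rules,
                          detail="no embedding combination extends to a full map")


def _instances(side, cid):
    for c, mult in side:
        if c == cid:
            return range(mult)
    return range(0)


def _instance_graph(mol, cid, k):
    g = mol.relabeled({v: (cid, k, v) for v in mol.graph.nodes})
    g.compound_id = cid
    return g


def run_pipeline(reactions, molecules, rdm_codes, config=None):
    """Run many reactions; returns ``{reaction_id: ReactionResult}`` plus a
    status TSV string."""
    results = {}
    for rxn in reactions:
        try:
            results[rxn.reaction_id] = run_reaction(rxn, molecules, rdm_codes,
                                                    config)
        except NonConvertibleStructureError as e:
            results[rxn.reaction_id] = ReactionResult(rxn.reaction_id,
                                                      "no_structure",
                                                      detail=str(e))
    header = "reaction_id\tstatus\tn_rules\tn_aams\tdetail"
    rows = [header] + ["\t".join(map(str, r.row())) for r in results.values()]
    return results, "\n".join(rows) + "\n"
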