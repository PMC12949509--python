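# rdm2dpo

Reconstruct explicit reaction rules and atom-to-atom maps from KEGG
RCLASS/RDM reaction annotations.

## The problem

The KEGG reaction database does not publish atom-to-atom maps (AAMs).
Instead, each reaction links to RCLASS entries whose *RDM codes* describe,
for one reactant/product molecule pair, the reaction-centre atom (**R**), the
difference atoms that leave or join (**D**) and the matched neighbour atoms
(**M**) — each written as a `reactant-product` pair of KEGG's 68 local
atom-type classes:

```
C1a-C1b:*-C1a:C1b-C1b        # R-section : D-section : M-section
```

This classification format is nearly unusable for atom-level modelling.
`rdm2dpo` inverts it: it converts RDM codes plus molecule structures into
double-pushout (DPO) graph transformation rules `L ← K → R` and complete
AAMs, **exhaustively enumerating every solution consistent with the data**.
Users are people building atom transition networks, isotope-tracing models
or graph-grammar models of metabolism from KEGG annotation.

## The method

A chemical reaction is a pair of labelled graphs G (reactants) and H
(products) with an element-preserving bijection α : V(G) → V(H).  The
*imaginary transition state* (ITS) graph Υ lives on V(G), has an edge
wherever a bond exists on either side, labelled with the bond-order pair
(b_G, b_H); edges with differing labels are *reaction edges*.  Any subgraph
Ψ of Υ covering all reaction edges is equivalent to a DPO rule: L takes the
first label components, R the second, and the maximal context K̂ keeps the
edges on which both sides agree.  Applying that rule to G at its defining
match regenerates H — the validity check used throughout.

The pipeline runs in five steps:

1. **expand** — parse each RDM code into two depth-1 trees rooted at the
   R-atom, replace atom types by their type graphs (with all documented
   alternative readings) and merge them branch-and-bound into connected
   *RDM pattern graphs* with a partial atom correspondence.
2. **pair** — embed every pattern variant into its molecule pair by subgraph
   monomorphism (wildcard residues match any heavy atom; O bonds do not
   distinguish single/double; ring and aromatic bonds interchange), fix the
   reactant/product orientation, and union all overlap-consistent embedding
   combinations into *pairwise pattern graphs*.
3. **rules** — combine the pairwise patterns of all RCLASSes of a reaction:
   the union of the bipartite matchings must stay a matching and every
   D-atom must be matched through some other pattern; survivors become DPO
   rule candidates with K̂ computed from L, R, α.
4. **completion** — where KEGG omits RCLASSes, connected D-subgraphs are
   matched onto the opposite reaction side (with a special case for carboxy
   groups leaving as CO2), and bond changes inside uncovered small molecules
   are patched into the rule.
5. **aam** — validated rules are applied to the reactants; each successful
   application defines a full AAM.  Incomplete rules fall back to embedding
   enumeration with exact branch-and-bound minimisation of the remaining
   changing bonds.

Everything is deterministic and exhaustive; reactions whose combinatorics
exceed a configurable cap (default 1000 per side) are skipped and reported,
never silently truncated.

## Worked example

The bundled generator produces random small reactions together with the RDM
codes KEGG would write for them, so the whole pipeline runs without any
KEGG download:

```python
import rdm2dpo as r

fx = r.make_fixture(8)           # a seeded methyl-transfer reaction
print(fx.rdm_codes)
# {'RC8_0': ['C2b-C2a:C1a-*:C2a-C2a'],
#  'RC8_1': ['C1a-C1a:C2b-C1b:*-*'],
#  'RC8_2': ['C1a-C1b:*-C1a:C5a-C5a']}

res = r.run_reaction(fx.reaction, fx.molecules, fx.rdm_codes)
print(res.status, len(res.rules), len(res.aams))
# aam_complete 4 1

print(r.write_rule_gml(res.rules[0]))
```

```
rule [
   ruleID "RF8_692944_0"
   left [
      node [ id 1 label "C" hcount 1 ]
      node [ id 5 label "C" hcount 3 ]
      edge [ source 1 target 2 label "-" ]
   ]
   context [
      node [ id 2 label "C" hcount 3 ]
      node [ id 3 label "C" hcount 2 ]
      node [ id 4 label "C" hcount 0 ]
      edge [ source 1 target 3 label "=" ]
      edge [ source 4 target 5 label "-" ]
   ]
   right [
      node [ id 1 label "C" hcount 2 ]
      node [ id 5 label "C" hcount 2 ]
      edge [ source 2 target 5 label "-" ]
   ]
]
```

The rule reads: the bond from atom 1 to the methyl carbon 2 is deleted
(`left`), a new bond from 2 to atom 5 is glued in (`right`), and the
carbonyl skeleton stays untouched (`context`); the hcount annotations track
the hydrogen bookkeeping on the two centres.  The single surviving AAM,
as mapped reaction SMILES:

```python
print(r.aam_to_reaction_smiles(fx.G, fx.H, res.aams[0].alpha))
# [C:4](=[O:5])([CH2:6][CH3:8])[CH3:7].[CH:1]([CH3:2])=[CH2:3]
#   >>[CH2:1]=[CH2:3].[CH3:2][CH2:7][C:4](=[O:5])[CH2:6][CH3:8]
```

with `res.aams[0].changing_bonds == 2` (one bond broken, one formed).

## Command line

```
rdm2dpo fixture --seed 5 --count 2 -o fx        # synthetic test data
rdm2dpo expand fx/rclasses.tsv -o run           # step 1 only
rdm2dpo run fx/reactions.json fx/structures fx/rclasses.tsv -o run
cat run/status.tsv
```

Real KEGG data is supplied the same way: MOL/KCF structure files named by
compound id, a flat `rclass_id<TAB>rdm-code` file, and a reactions JSON
(`reaction_id`, `reactants`/`products` as `[compound_id, multiplicity]`
lists, `rclass_links` as `[rclass_id, [reactant_id, product_id]]` pairs).
Every reaction ends in one status of the taxonomy `aam_complete /
aam_partial / rule_only / conflict / combinatorics_skip / timeout /
no_structure / undefined_atoms / no_rclass / cannot_embed`.

## The atom-type dictionary

`src/rdm2dpo/data/atom_types.yaml` holds all 68 KEGG atom classes as small
rooted type graphs: 5 codes carry the KEGG-documented alternative readings
(C2y, N1a, N1b, N1c, N2a), 20 more carry inferred alternatives (mostly
protonation/resonance states), with at most four alternatives (P1a).  The
table is data, not code, and every entry is tagged with its provenance.

## Acceptance script

`scripts/acceptance.py` re-runs the package's main computation from
scratch: it generates a seeded batch of synthetic reactions, pushes them
through all five pipeline steps (expansion, embedding, rule assembly,
validation by rule application, AAM completion) and writes the acceptance
JSON:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Scope and limitations

Stereochemistry, 3D coordinates and KEGG-scale batch statistics are out of
scope.  Structures with abbreviated residues (`R` pseudo-atoms) are flagged
non-convertible.  RDM codes cannot express bonds formed or broken between
two matched atoms, embeddings into 3-rings (epoxides), or 'undefined atom'
classes — the pipeline detects and reports these cases rather than guessing.
See `docs/methods.md` for the model details and design choices.
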