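# Methods

## Model

Molecules are finite labelled simple graphs: vertices carry a chemical
element, edges a bond order from {single, double, triple, aromatic}.
Charges and unpaired electrons are annotated as labelled loops so that
vertex labels never change under a transformation; implicit hydrogen counts
are carried as a per-vertex annotation and treated formally as one more
relabellable loop.  A reaction is a pair (G, H) of such graphs — disjoint
unions of the reactant and product molecules — with an element-preserving
bijection α : V(G) → V(H), the atom-to-atom map (AAM).

A chemical DPO rule is a span `L ← K → R` over a common atom set with a
bijection β : V(L) → V(R): atoms are preserved, so rules only delete,
insert or relabel edges (and adjust the hydrogen/charge annotations).  For
fixed L, R, β the context K is not unique, but there is a unique *maximal*
context K̂ — all edges on which L and R agree.  `DPORule` therefore never
stores K; it recomputes K̂, which makes every stored rule the canonical
representative of its equivalence class.

The ITS graph Υ(G, H, α) lives on V(G) with an edge wherever a bond exists
on at least one side, labelled with the ordered pair of bond orders (∅ for
absence).  Edges whose labels differ are reaction edges.  Any subgraph Ψ of
Υ containing all reaction edges (and their endpoints — the package's reading
of "reaction vertices") defines a rule that, applied at its defining match,
regenerates H exactly.  This round trip is the package's internal validity
check for every rule it emits, and the only gluing-condition failure
possible in this restricted setting — inserting an edge where the host
retains one — is detected at application time rather than encoded as a
negative application condition attached to the rule.

## Hydrogens

Hydrogens are implicit everywhere.  A rule records the hydrogen count of
each atom on both sides and application rewrites it, which is formally a
loop relabelling and hence stays inside the edge-only-changes discipline.
This deviates from materializing explicit H vertices inside rules: explicit
hydrogens multiply the automorphisms of every methyl and amino group and
blow up embedding enumeration, while carrying no information beyond the
count.  The cost is that "hydrogen exchange" becomes a vertex relabel
rather than an edge edit; the rule filter that keeps only variants with the
minimum number of hydrogen exchanges therefore minimises Σ|Δh| over the
rule's atoms.  Reactions are *not* required to conserve total hydrogen:
like the underlying database, the model lets protons exchange with the
implicit solvent, and per-atom valence consistency is the invariant that is
actually enforced and tested.

## The atom-type dictionary

`data/atom_types.yaml` maps each of the 68 KEGG atom classes to its rooted
type graph(s): a focal atom with its complete heavy-atom neighbourhood,
unspecified neighbours as wildcard "R-residues", ring bonds flagged.  Five
codes carry alternatives documented by KEGG itself (C2y, N1a, N1b, N1c,
N2a); twenty further codes carry inferred alternatives — overwhelmingly
protonation and resonance states (hydroxyl/alkoxide, carboxyl/carboxylate,
phosphoryl P=O vs P–O⁻, amine/ammonium, …) — required to cover structures
as the database draws them; P1a is the richest entry with four readings.
The table is data with per-entry provenance tags, not code.  Entries whose
local shape the source material fixes verbatim (C1a, C1b, C2b, O1c, P1b,
P1a) are transcribed exactly; the remainder is a chemically motivated
reconstruction of the vocabulary, which is the honest limit of what can be
rebuilt without the original appendix.  Three leniencies apply whenever a
type graph is compared against a molecule: bonds involving oxygen do not
distinguish single from double order, within-ring bonds interchange with
aromatic bonds, and charge loops are ignored.

## Merging type graphs

Each RDM code side becomes a depth-1 tree rooted at the R-atom.  Expansion
merges every child's type graph into the root's, preferring a shared atom
pair as the merge point (O1c's H–O–P and P1b's P–O fuse on the P–O motif)
and otherwise consuming a matched pair of wildcard residues whose bond
orders agree.  Two completeness constraints shape the search: a focal
atom's type defines its whole heavy neighbourhood, so every pre-existing
neighbour of a fused atom must be explained by the incoming type graph, and
atoms that were focals of earlier merges can never gain new neighbours.
Because a merge choice can become inextensible only at a later child, the
enumeration is branch-and-bound over all alternatives and all merge points;
shared-motif and wildcard branches are both kept where both exist, and the
embedding stage filters.  Results are deduplicated up to rooted isomorphism
(R-atom pinned) and ordered by a deterministic fragment signature.

## Embedding, consistency, combination

Pattern sides embed into molecules by subgraph monomorphism under the
leniency predicates; hydrogen counts must match exactly at R/D/M atoms and
may exceed the pattern's count elsewhere.  All embeddings are enumerated in
a deterministic order.  Within one RCLASS, overlapping embeddings of two
codes must agree: a shared atom is either a D-atom in both codes or matched
in both — and then to the same partner atom on the opposite side.  Across
RCLASSes, the union of the bipartite matchings must remain a matching and
every D-atom must be matched through some other pattern; an atom carrying
an R label anywhere is treated as R, and M wins over D.  Mis-declared
M-atoms are caught by a role/element balance count between the two sides,
mis-declared D-atoms by the rule-application check.

Pattern-image atoms that remain unmatched and are *not* D-atoms (wildcard
and context images no code pins down) are dropped from the rule.  Read
literally, the combination condition would demand every unmatched image
atom be matched elsewhere, which no single-RCLASS reaction with wildcards
could satisfy; dropping them only shrinks the optional context K̂, and the
rule-graph equivalence guarantees the rule stays valid.  Reaction edges are
unaffected — their endpoints always carry R/D/M roles and are matched.

## Missing annotation

When uncovered pairs leave D-atoms unmatched, their connected subgraphs are
matched by VF2-style search onto the opposite reaction side under four
conditions: the image must not reproduce an original pattern image; an
overlap with an integrated pattern must contain or touch one of that
pattern's R-atoms (the package's reading of an underspecified condition —
taken strictly on the overlap it would be unsatisfiable, since R-atoms are
always matched and every candidate must keep the union matching a
matching); D-atoms of other patterns may be hit only by an all-D image; and
hydrogens are excluded (trivially, being implicit).  Carboxy groups leaving
as CO2 defeat plain isomorphism because their internal bond orders change;
a shape-based special case matches C(O)(O) fragments onto O=C=O components
directly.  Finally, bond changes inside uncovered small molecules are
patched into L and R from the atom map (idempotently); changes incident to
atoms outside the map cannot be patched and leave the rule incomplete.

## AAM completion and minimisation

A complete, validated rule defines AAMs directly: each successful
application yields a product graph isomorphic to H, and composing the
application map with the product isomorphisms gives the maps.  Incomplete
rules fall back to enumerating all strict embeddings of L into G and R into
H; each combination seeds an extension search.  The strict variant admits a
pair only if every bond to previously matched atoms is preserved with its
label — a seed with no strict extension cannot belong to a correct rule,
which is the filter criterion for ambiguous candidates.  When no strict
extension exists, an exact branch-and-bound over element-preserving
bijections minimises the number of bonds changing outside the seed (the
cost of a partial map only grows, so branches exceeding the incumbent are
pruned).  This replaces an external ILP solver at desk scale with an exact
enumerative optimiser.  Resulting maps are deduplicated by induced-ITS
isomorphism and reported minimal-cost first.

## Synthetic data

The generator emits a *stated world*: two acyclic neutral reactant
molecules of 3–5 heavy atoms over C/C/C/C/N/O, grown as random trees with
valence-consistent bond orders (15% double, 3% triple), transformed by two
random bond edits (delete / insert / order-step, hydrogen bookkeeping kept
valence-consistent); inserted bonds only join separate fragments.  These
sizes match small transfer-reaction chemistry, where one or two bonds break
and form; all randomness sits behind one integer seed.  From the ground
truth the generator emits the RDM codes the database convention prescribes:
for pairs with unmatched atoms, one code per matched atom adjacent to an
unmatched one; otherwise one code per atom whose type changes; D-atoms are
the unmatched neighbours, M-atoms the neighbours adjacent on *both* sides
(the grammar has no absence marker in the M section, so one-sided adjacency
is inexpressible — such changes deliberately surface downstream as
incomplete rules).  Atom types are assigned by looking the local
neighbourhood up in the bundled table (most specific exact-order match
first), so every emitted code expands back into an embeddable pattern by
construction.

What a green end-to-end test establishes — and what it does not: the
generator's world is acyclic, neutral and ring-free, so recovery there
demonstrates the reconstruction logic (expansion, embedding, combination,
validation, completion), not coverage of aromatic systems, charges or ring
chemistry; those paths are exercised by the table, merge and embedding unit
tests instead.  Real-database pathologies (3-ring embeddings, polymer-like
combinatorial blow-ups, undefined atoms, unbalanced reactions) are covered
by dedicated negative-control tests.

## Numerical and procedural choices

- Combination cap: 1000 per reaction side (configurable); exceeding it is a
  reported skip, never a truncation.  Rule-application stage time limit:
  7200 s default.
- Determinism: embeddings and combinations enumerate in lexicographic order
  of (code index, variant id, canonical embedding key); fragment lists sort
  by a deterministic signature before isomorphism dedup; repeated runs give
  identical outputs.
- Degenerate inputs: reactions without RCLASS links, with missing or
  pseudo-atom structures, or with undefined-atom codes end in their own
  status; the pipeline never raises on data.
- Rule multiplicity: all surviving non-isomorphic rules are emitted;
  hydrogen-exchange-minimal filtering runs per bond-edit signature after
  validation; classifying residual multiplicity into symmetry vs
  tautomerism is out of scope (it needs chemical knowledge the formalism
  does not carry).
- Serialization: rules use a three-section GML dialect (left / context /
  right over shared ids) with the hydrogen count as an explicit attribute;
  AAMs are written both as atom-id pair lists (bit-exact) and mapped
  reaction SMILES via RDKit.

## Known limitations

- The inferred part of the atom-type table is a reconstruction; real KEGG
  structures may exercise readings it lacks, which surfaces as
  `cannot_embed`, never as a wrong map.
- Second-shell overlap during type-graph merging is resolved only through
  atoms adjacent to the fused focal; deeper coincidences would be caught at
  embedding time as unembeddable fragments.
- The D-subgraph matcher requires candidate images to be disjoint from the
  current matching, so annotation errors that double-book an atom are
  reported as conflicts rather than repaired — by design, the tool never
  amends its input data.
- Multiplicities > 1 in reaction records are supported by instance
  enumeration but multiply the combinatorics; large stoichiometries will
  hit the combination cap.
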