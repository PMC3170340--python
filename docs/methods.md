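# Methods

`sbmlkb` turns a MIRIAM-annotated SBML model into a description-logic
knowledge base that states, as OWL axioms, *what the model represents*: which
physical objects, which of their functions, and which processes realizing
those functions.  This note documents the formal commitment behind the
conversion, the reasoning machinery, the synthetic test material, and the
design choices made where the design was genuinely open.

## The upper-level model ontology

Two disjoint hierarchies share one ontology.  On the in-silico side, `Model
entity` has subclasses `Model` and `Model component`, extended with the
SBML-specific classes `sbml:Model`, `sbml:Species`, `sbml:Compartment`,
`sbml:Reaction`.  On the in-vivo side, `Biological entity` has the four
pairwise-disjoint subclasses `Physical object`, `Process`, `Function` and
`Quality`.  Sibling classes on each level of distinction are declared
disjoint; `Model entity` and `Biological entity` are disjoint with each
other.  The disjointness axioms are load-bearing: they are exactly what turns
a category-mixing annotation (a species annotated with a process class) into
an unsatisfiable class that a reasoner can find mechanically.

Twenty object properties connect the classes: `part-of`/`has-part` (declared
transitive), `participates-in`/`has-participant` with the sub-relations
`input-of`/`output-of`/`modifier-of` (and their inverses under
`has-participant`), `function-of`/`has-function`, `realizes`/`realized-by`,
`occurs-in`/`has-process-occuring`, `quality-of`/`has-quality` (`quality-of`
functional: a quality is a quality of exactly one individual), and the two
bridge relations `represents` (model entities to the physical objects they
represent) and `model-of` (models only), which deliberately have no inverse.
Three background constraints are asserted: model components are part of some
model; physical objects have only physical objects as parts; processes have
only processes as parts.

Reference ontologies attach beneath the four in-vivo categories by subclass
axioms on their roots: the GO biological-process root under `Process`, the GO
molecular-function root under `Function`, GO cellular components, ChEBI,
FMA and Cell Ontology roots under `Physical object`, and PATO under
`Quality`.  Categorization of an annotation class is by transitive is_a
ancestry to a mapped root only — part_of links never carry category
information; they become explicit `part-of some` axioms instead.

**Transitivity of part-of** is not forced by anything in the relation table,
but it is what lets a query phrased at organ level (`part-of some 'Endocrine
pancreas'`) retrieve entities annotated at cell level through an anatomical
partonomy chain, and it matches standard OBO Relations Ontology practice.
It is therefore asserted as a design choice.

## Conversion rules

For every SBML entity *E* (the model *M*, each compartment *C*, species *S*,
reaction *R*) two classes are emitted: the in-silico class *E* (subclass of
the matching `sbml:*` class) and the represented in-vivo class *Rep(E)*, with
`E ⊑ represents some Rep(E)`.  Models additionally get `M ⊑ model-of some
Rep(M)` so that model-level retrieval queries can use the `model-of`
relation.  *Rep(M)*, *Rep(C)* and *Rep(S)* are asserted to be physical
objects — without this, a species annotated with a process class would be
consistent and the headline violation undetectable.

Structural containment is asserted **in both directions**: `Rep(S) ⊑ part-of
some Rep(C)`, `Rep(C) ⊑ part-of some Rep(M)`, `Rep(R) ⊑ part-of some Rep(M)`
on the contained side, and `Rep(M) ⊑ has-part some Rep(C)`, `Rep(C) ⊑
has-part some Rep(S)`, `Rep(M) ⊑ has-part some Rep(R)` on the container
side.  The container-side axioms are what make "the model's world has a cell
as part" an entailment and what let model-level queries reach reaction
processes through `has-part`.  The deliberate consequence is that
unsatisfiability propagates: if one species is impossible, the compartment
that has it as part is impossible, and so is the whole world of the model.
The verifier reports the full collapsed list as ground truth and pinpoints
the offending annotations separately.  In-silico containment (`E_C/E_R ⊑
part-of some E_M`, `E_S ⊑ part-of some E_C`) supports "parts of model X"
queries.

Annotations with the five biology qualifiers are interpreted by entity kind
and by the category of the annotated class:

| entity | category | contribution to *Rep(E)* |
|---|---|---|
| model | physical object *O* | `has-part some O` |
| model | function *F* | `has-part some (has-function some F)` |
| model | process *P* | `has-part some (has-function some (realized-by only P))` |
| model | uncategorized | disjunction of the three readings (full mode); logged skip (EL mode) |
| compartment, species | any | the named class itself (strict) |
| reaction | function *F* | `has-function some F` |
| reaction | process *P* | gathered into the named process class (below) |
| reaction | other | `has-function some C` (strict fallback) |

`is`, `isVersionOf` and `hasVersion` all use this table.  `isPartOf` and
`hasPart` wrap the same interpretation in `part-of some …` / `has-part some
…`.  (For models this nests two `has-part` steps, which collapse under
transitivity.)  The strict, non-disjunctive interpretation for species,
compartments and reactions is the point of the method: a disjunctive reading
would make every annotation consistent and hide exactly the errors the
reasoner is supposed to find.  Only model annotations of unknown category get
the disjunctive reading, since models legitimately represent any of the three
readings.

**The named reaction process class.**  Every reaction receives an auxiliary
class *Proc(R)* `⊑ Process` that gathers its process annotations and its
participant axioms (`has-input some Rep(S)` per reactant, `has-output` per
product, `has-modifier` per modifier), attached via `Rep(R) ⊑ has-function
some (realized-by only Proc(R))`.  The universal quantifier keeps functions
realizable-but-not-necessarily-realized; the *named* filler is what makes an
impossible process an unsatisfiable *named* class and hence detectable — an
anonymous filler under `only` would fail silently.  When a reaction is
annotated with a function *F*, `Proc(R) ⊑ realizes some F` is also asserted,
so that queries can constrain the realizing process by its function (e.g.
"realizes some catalytic activity").  Reactions annotated with
physical-object classes go through the function rule; the range of
`has-function` (`Function`, disjoint with `Physical object`) produces the
intended contradiction.

Species initial values yield quality axioms on *Rep(S)*: `has-quality some`
Concentration (PATO:0000033) for an initial concentration, Charge
(PATO:0002193) for a charge, Mass (PATO:0000125) for an initial amount.
Only the qualified existence of the quality is asserted, not a magnitude.
`occurs-in` is declared but never asserted by the converter; localization of
reaction processes is carried by `Rep(R) ⊑ part-of some Rep(M)` instead.
SBML parameters, kinetic laws, rules, events and units are parsed for
reporting but never converted.  Annotations that do not resolve to a loaded
ontology class (including non-ontology resources such as protein-database
records) are skipped with a logged manifest record; the entity is still
converted structurally.

Every emitted axiom carries a provenance record in the conversion manifest:
scope (model), entity, qualifier/target where applicable, and a rule tag from
the documented registry (`sbmlkb.convert.RULES`), making the rule-to-axiom
mapping auditable.  Axioms are sorted canonically before serialization, so
output is byte-stable; annotations are processed in document order.

## Reasoning

No OWL reasoner is a dependency; the package ships two independent ones.

**Tableau calculus** (`sbmlkb.reasoner.tableau`).  Decides satisfiability and
subsumption for ALCH with transitive roles: lazy unfolding of named-class
axioms, internalized general inclusions (needed for constraint rules with
complex left sides), conjunction/disjunction with backtracking, existential
successors guarded by subset blocking, universal restrictions with the
standard transitivity propagation rule, domain/range firing on edge
creation, disjointness as complement pairs.  Inverse-role semantics and
number restrictions are **not** part of the calculus: no emitted axiom and no
packaged query requires them (inverses and the functionality of `quality-of`
are declared in the ontology metadata and serialized, but do not participate
in inference).  Queries are answered as satisfiable named subclasses of the
(resolved) query expression; `Nothing` returns the unsatisfiable classes.

**EL saturation** (`sbmlkb.reasoner.el`).  A polynomial-time completion
procedure for the Horn fragment the EL-mode output lives in: contexts (named
classes, and existential successors intersected with applicable role ranges)
accumulate subsumers and existential links under rules for conjunction,
existentials, role hierarchy, transitivity composition, domain/range and
disjointness-to-bottom.  It rejects any input outside the fragment.  The two
reasoners are cross-checked in the test suite on randomized Horn-EL
terminologies (seeded) and on the converted fixtures; they must agree on
every verdict.

**Numerical/procedural choices.**  Tie-breaks in the tableau (which
disjunction or existential to expand next) follow a canonical expression
ordering, so verdicts are reproducible and reports are stable under axiom
reordering.  Satisfiability results are memoized per reasoner instance.
Degenerate inputs — empty ontologies, annotation-free models, empty
constraint sets, empty corpora — are all defined identity cases and tested.

## OWL EL reduction

Full-mode output uses three constructs outside OWL EL: the universal
restriction in `realized-by only`, the disjunctive model reading, and
inverse/functional property axioms.  EL mode (a) rewrites `realized-by only
P` to `realized-by some P`, (b) drops the two universal part-of constraints
of the upper ontology (weakening them to existentials would assert parts
that need not exist), (c) skips disjunctive model annotations with a logged
record, and (d) removes inverse and functional property axioms.  Everything
dropped is recorded in the output ontology's annotations, and a syntactic
conformance scan (`el_profile_violations`) verifies the result.

The rewrite *strengthens* the realized-by axioms: in EL mode a realizing
process is asserted to exist.  Queries that traverse `realized-by`
existentially therefore gain answers in EL mode that full mode does not
entail — that is the documented trade-off of the reduction (tractability and
more liberal process queries versus fidelity to unrealized functions).
Full/EL agreement is consequently guaranteed, and tested, for EL-expressible
queries that do not traverse `realized-by`; category-mixing verdicts are
preserved exactly, since they rest on conjunction and disjointness, which the
reduction does not touch.

## Verification and violation kinds

The verifier checks satisfiability of every emitted named class, traces
failures through the manifest, and assigns kinds: `category_mixing` when the
annotation's entailed category conflicts with the entity kind's asserted one
(species/compartments must be physical objects; reactions must not be
physical objects or qualities); `language_feature_misuse` when two or more
sibling species carry process-class annotations — the signature of species
used to encode temporal stages, flagged as such rather than guessing intent;
`biological_impossibility` when the class is unsatisfiable only after
user-supplied constraint axioms are merged, in which case the entity's own
annotations *and those of its participant species* are listed as candidate
causes (it is usually a participant's annotation that is wrong).  The kind
assignment is a documented heuristic; the raw unsatisfiable-class list is
always reported as ground truth.  Justification (minimal-explanation)
extraction is deliberately omitted: at fixture scale the asserted-axiom
listing in the manifest suffices.

Constraint files supply disjointness groups, named-class definitions and
general subclass rules in the query expression syntax.  The packaged ATPase
constraint file states the enzymatic definition on the *realizing process* —
`(realizes some 'ATPase activity') ⊑ has-input some water ⊓ has-input some
ATP ⊓ has-input only (water or ATP) ⊓ has-output some ADP ⊓ has-output some
phosphate` — because `has-input`/`has-output` relate processes to their
participants; stating it on the function class would require inverse-role
reasoning to reach the process.  Together with the disjointness of water,
ATP and alpha-D-glucose 6-phosphate (absent from ChEBI itself), a reaction
whose substrate species is mis-annotated with the sugar phosphate makes its
process class unsatisfiable; re-annotating that one species restores
coherence.

## Synthetic test material

The fixture generator writes miniature OBO subsets of GO, ChEBI, FMA, PATO
and the Cell Ontology (42 classes total) and six scenario models: a clean
two-reactant binding model (F1), the same model plus a species annotated
with a process (F2), plus a reaction annotated with a cellular component
(F3), an anaerobic-glycolysis pattern with the mis-annotated ATPase
substrate and its corrected variant (F4/F4fix), four species annotated with
cell-cycle phases (F5), and a pancreatic beta-cell model whose compartment
is annotated at the islet-cell level while its sugar species feed
catalytic-activity reactions (F6, the granularity-query scenario).  Models
are SBML Level 2 Version 4 with MIRIAM RDF annotations in both the
`urn:miriam:` and identifiers.org dialects, so the reader's URI
normalization is exercised on real-looking input.

Identifiers printed in the literature (GO:0005623 cell, GO:0005525 GTP
binding, GO:0051225 spindle assembly, GO:0008233 peptidase activity,
GO:0004002 ATPase activity, CHEBI:15996 GTP, CHEBI:16646 sugar, CHEBI:17665
alpha-D-glucose 6-phosphate, CHEBI:25435 mutagen, CHEBI:35470 central
nervous system drug, FMA:71132, FMA:70586, PATO:0000033/0002193/0000125) are
kept verbatim; every scaffold class carries an id in the reserved synthetic
`FIX:` namespace so no real-looking identifier is fabricated.  One deliberate
divergence from the real GO: the miniature places *GTP binding* under
biological_process, because the scenario requires a process-category
annotation on the binding reaction (in the real GO it is a molecular
function).  Generation is fully deterministic; the seed is recorded in the
registry for provenance and two runs with the same seed are byte-identical.

**What the miniatures do not emulate** — and hence what passing tests do not
show about real corpora: real-ontology scale (tens of thousands of classes
per ontology rather than dozens), multiple annotations per entity,
annotation noise beyond the planted errors, cross-ontology logical
definitions, FMA's native frame representation (only OBO/OWL exports are
supported), and reasoning-time behaviour at repository scale.  Problem sizes
throughout (models of 1 compartment, 2–4 species, 1–4 reactions; knowledge
bases of ~70 classes) were chosen so each scenario isolates one phenomenon
and every entailment can be hand-checked.

## Known limitations

* Class-level only: the formalization has no individuals, so answers are
  classes, never instances.
* The tableau calculus covers exactly the fragment the tool emits and
  queries; it is not a general OWL DL reasoner (no inverses, no number
  restrictions, no nominals).
* Violation-kind assignment is heuristic; a wrong heuristic label never hides
  a violation, since the unsatisfiable-class list is computed independently.
* Unsatisfiability propagation means one bad annotation collapses a model's
  whole world; the offender list, not the raw list, is the diagnosis.
* `hasVersion` is treated identically to `is`/`isVersionOf`; the qualifier's
  subtler intent (the entity represents a version of the target) is not
  distinguished.
* CellML, SED-ML and kinetic semantics are out of scope.
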