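# sbmlkb

Biosimulation models in SBML are routinely annotated with terms from
biomedical ontologies (GO, ChEBI, FMA, PATO, the Cell Ontology) through
MIRIAM-style RDF cross-references — but those annotations are treated as
metadata, not as claims that can be checked or reasoned over.  `sbmlkb`
turns annotated SBML models into an OWL knowledge base in which the
annotations *are* logical axioms, so that a description-logic reasoner can

* **verify** that a model is biologically consistent — e.g. detect a species
  (a physical object) annotated with *spindle assembly* (a process), a
  reaction annotated with a protein complex, or an enzymatic reaction whose
  substrate annotation contradicts the enzyme's definition; and
* **retrieve** models and model components by what they represent, with
  queries that bridge levels of granularity ("model entities representing
  catalytic activity involving sugar in the endocrine pancreas") by walking
  partonomy chains in anatomical ontologies.

It is a library plus a command-line tool for systems biologists, model
curators and ontology engineers.

## The formalization

A small upper-level ontology separates in-silico from in-vivo entities:
`Model entity` (with `Model`, `Model component` and SBML-specific
subclasses) disjoint from `Biological entity` with its four pairwise
disjoint categories `Physical object`, `Process`, `Function`, `Quality`,
under which the reference-ontology roots are attached.  For every SBML
entity *E* the converter emits an in-silico class *E* and an in-vivo class
*Rep(E)* with

```
E       ⊑ represents some Rep(E)
Rep(S)  ⊑ O₁ ⊓ … ⊓ Oₙ ⊓ part-of some Rep(C)        (species S in compartment C,
                                                     annotated with objects Oᵢ)
Rep(R)  ⊑ has-function some (realized-by only Proc(R))
Proc(R) ⊑ Process ⊓ P ⊓ has-input some Rep(S₁) ⊓ has-output some Rep(S₂) ⊓ …
```

where the named process class *Proc(R)* gathers a reaction's process
annotations *P* and its participants.  Category mixing (say, *Rep(S)* ⊑
`Physical object` ⊓ *spindle assembly* ⊑ `Process`) makes a class
unsatisfiable; querying `Nothing` returns every such class.  An OWL EL
variant of the output (universal → existential on `realized-by`, no unions,
no inverses) supports polynomial-time reasoning via the bundled saturation
classifier.  The full machinery — conversion rules, the two reasoners, the
EL reduction and its trade-offs — is documented in
[docs/methods.md](docs/methods.md).

## Worked example

Generate the packaged miniature ontologies and scenario models, convert the
model containing a species `SPN` annotated with *spindle assembly*
(GO:0051225), and verify it:

```bash
$ sbmlkb fixtures --outdir fx --seed 1
$ sbmlkb convert --sbml fx/F2_species_process_violation.xml \
                 --registry fx/registry.yaml --out f2.owl --manifest f2.json
wrote f2.owl: 69 classes, 117 axioms, mode=full
$ sbmlkb verify --kb f2.owl --manifest f2.json
knowledge base is INCOHERENT
unsatisfiable classes: 15
  https://w3id.org/sbmlkb/model/F2_spindle#DRG  (model F2_spindle, entity DRG, insilico)
  ...
offending annotations:
  F2_spindle/SPN (species) isVersionOf GO:0051225: category_mixing
```

The reasoner finds 15 unsatisfiable classes — `Rep(SPN)` is impossible
(a physical object that is a process), and impossibility propagates to the
compartment that has it as part, to the model's world, and to everything in
it — while the offender report pinpoints the single bad annotation.  The
exit status is nonzero, so the check can gate a curation pipeline.

Granularity-bridging retrieval on the beta-cell model, whose compartment is
annotated with *Type B cell of pancreatic islet* (FMA:70586) and whose sugar
species feed catalytic-activity reactions:

```bash
$ sbmlkb convert --sbml fx/F6_granularity_query_model.xml \
                 --registry fx/registry.yaml --out f6.ofn --manifest f6.json
$ sbmlkb query --kb f6.ofn --filter model_entities_only --format tsv --query \
  "represents some (has-function some (realized-by only \
   (realizes some 'catalytic activity' and has-participant some \
    (sugar and part-of some 'Endocrine pancreas'))))"
iri	label
https://w3id.org/sbmlkb/model/F6_pancreas#GPI	GPI
https://w3id.org/sbmlkb/model/F6_pancreas#PFK	PFK
```

The query is phrased at the *endocrine pancreas* level; the model is
annotated only at the *islet beta cell* level.  The two
phosphofructokinase/isomerase reactions are retrieved because the mini-FMA
asserts beta cell `part-of` pancreatic islet `part-of` endocrine pancreas and
`part-of` is transitive.  The oxygen-binding and cell-cycle reactions in the
same model are correctly excluded.

The same pipeline is available as a library
(`parse_sbml` → `convert_model` → `classify_and_report` / `answer_query`);
constraint axioms for the biological-impossibility check are supplied as a
YAML file (see `fx/atpase_constraints.yaml`) to `sbmlkb verify
--constraints`.

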