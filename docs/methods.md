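# Methods

## The evaluation model

An annotated document is a set of *denotations* (a text span denotes an
object of some concept) and binary *relations* between denoted objects.
Event-centric standoff annotation is mapped onto this model by decomposing
each n-ary event into one event denotation (trigger span, event type) and n
relations directed participant → event; the decomposition is lossless up to
trigger-entity identity, and the inverse reassembles events grouped by the
event denotation id (grouping is never guessed from co-occurring relations).

A knowledge base is the RDF image of a document set. Per denotation three
triples are emitted — `rdf:type` to the task concept, `rdf:type` to
`tao:Context_entity`, `tao:denoted_by` to the span IRI — and one triple per
relation, so `|triples| = 3·|denotations| + |relations|`. Only
`denoted_by` is materialised; its inverse is derivable and emitting both
would double-count nothing but redundancy. Span IRIs follow the
PubAnnotation URL scheme and are the *comparable currency* between gold and
system graphs: two annotation sets over the same documents agree exactly on
span IRIs and differ on instance IRIs, which is why all queries project
spans.

Instance IRIs are not part of the span scheme and had to be invented; they
are deterministic functions `{inst_base}/{db}-{id}-{div}#{denotation-id}` so
that equal inputs give byte-equal graphs.

## Queries and transitive inference

Q1–Q3 return spans of proteins that are themes of gene-expression,
localization and binding events; Q4 returns span pairs of proteins that are
themes of one binding event; Q5/Q6 return (theme span, cause span) pairs of
a shared event, without/with transitive closure of `themeOf`; Q7/Q8 do the
same with the theme anchored in a gene-expression event and the cause
attached up a `themeOf` chain. Q5–Q8 deliberately carry no type constraint
on the regulation event and no distinctness filter — the query texts are
evaluated exactly as specified, without tightening.

The closure is the plain transitive closure (path length ≥ 1) of the
`themeOf` edge set; cycles, which can occur in corrupt submissions, are
permitted and simply put reflexive pairs in the closure. The native
evaluator computes it by breadth-first reachability per source node.

One portability note on Q4: its pair-ordering filter compares two IRIs with
`<`. Production RDF stores commonly extend `<` to IRIs as codepoint string
comparison, but a strictly conformant SPARQL engine treats it as a type
error and returns nothing. The native evaluator implements the codepoint
comparison on span IRIs directly (so pair *orientation* depends on the
configured IRI base; membership does not), and the delegation backend —
rdflib, used as an independent cross-check in the tests — evaluates the
filter through `STR()` casts, which express the same comparison
conformantly. The shipped `.rq` files keep the plain filter.

## Scoring conventions

`TP = |gold ∩ system|`; recall is 0 when the gold set is empty, precision 0
when the system set is empty, F1 is 0 when both components are 0. F1 is
computed from the unrounded recall and precision; all three are rounded
half-up to two decimals (this reproduces every published per-query table
cell, e.g. 45/56 → 80.357 → 80.36, which rounding-from-rounded would not).
Display zero-pads to two integer digits (`04.20`, `00.00`); stored values
are plain floats. Scoring two graphs whose span IRIs share no document base
raises a configuration error rather than returning vacuous zeros.

The expected pair score under independence is `100·(F/100)²` for a single
answer F-score `F` — pair retrieval requires both members, so squaring gives
the no-interaction baseline; observed pair scores fall below it because
deciding whether two co-triggered proteins share one binding event
(collective parsing) or two (distributive parsing) adds its own errors.

## GE ↔ GRO conversion

Forward (GE → GRO) replaces concepts via the equivalence table; the Genia
`Protein` maps to both GRO `Gene` and `Protein`, resolved to `Protein` by
default (configurable) since nothing in the forward data distinguishes the
two. `Deacetylation` and `Ubiquitination` have no GRO correspondent and are
dropped (counted, never an error). Backward (GRO → GE) uses
nearest-mapped-ancestor search over the is-a hierarchy: direct mapping wins,
otherwise a breadth-first search by level with lexicographic tie-break; only
is-a edges are traversed (part-of links express composition, not
subsumption, and are excluded from the default traversal). An event whose
argument is dropped loses that argument; an event whose own concept cannot
be mapped is dropped entirely. Convertibility statistics count an event as
convertible iff its own concept maps (argument loss does not reclassify it);
the policy is stamped into the report header. Percentages are rounded
half-up to one decimal.

The shipped hierarchy file is a synthetic toy: a hand-built is-a edge list
covering the concepts the converter and its tests exercise, with the same
subsumption paths as the real Gene Regulation Ontology for those concepts.
Both the mapping and the hierarchy are plain TSV data files so the full
ontology can be dropped in.

## The synthetic corpus generator

Documents are sequences of independent statements over a small protein
lexicon: a simple event (expression, transcription, localization,
phosphorylation) over one protein, optionally wrapped in a regulation chain
of depth 0–`max_nesting_depth` (default 2) with a protein cause attached at
the top with probability `cause_prob` (default 0.5); a binding event over
1–3 proteins (default mix 0.4/0.4/0.2 — collective parsing); or a direct
protein-regulates-protein event. The statement mix defaults to 30 %
expression, 20 % binding, 20 % direct regulation, 10 % each localization,
transcription, phosphorylation, roughly reflecting the dominance of
expression and regulation annotations in gene-regulation corpora; documents
spend an entity budget drawn around `mean_entities_per_doc` (default 15).
Text is space-joined tokens, so offsets are consistent by construction;
lexical realism is a non-goal and nothing downstream depends on it.

While generating, the ledger records every query-relevant fact (expressed
proteins, collectively bound pairs, causal pairs and whether the chain
passes through an expression event), giving expected result sets that are
independent of the query engine — the oracle for the query tests.

The perturbation operator models system errors: event deletion (cascading
argument removal), retyping, span shifts of protein mentions, and schematic
rewrites. A rewrite re-expresses one causal attachment: an event carrying a
cause is either wrapped in a fresh outer regulation that takes over the
cause (expansion), or — when its theme is a causeless regulation event — the
cause moves one level down and the outer event disappears (collapse). Both
directions leave the transitive queries' answers invariant while changing
the single-step ones, which is exactly the schematic variation the
KB-oriented evaluation is designed to absorb.

What passing these tests does **not** show about real data: real submissions
differ from gold in span tokenisation, trigger word choice, coreference and
cross-sentence structure, none of which the generator models; the synthetic
corpus demonstrates the correctness of the machinery, not the difficulty of
the task.

## Numerical and design choices

* Offsets are Unicode code points, end-exclusive caret positions.
* Coordination suffixes (`Theme2`, `Theme3`) are preserved verbatim for
  round-tripping and stripped to the base role for semantics.
* Duplicate annotation ids are a hard error; statements with uninterpreted
  id prefixes (`M`, `R`, `*`) are carried through opaquely with a warning.
* Reverse bridge conversion mints trigger ids above the highest existing
  `T` index (collision-free, deterministic); events reconstructed with zero
  or partial arguments are retained — representing partial information is a
  feature of the relation-centric format, not an error.
* Trigger entities consumed by events are omitted as standalone denotations
  (a flag restores them); two events sharing a trigger yield two event
  denotations over the same span.
* Graph serialization orders statements by sorted triple; graph union is a
  set union and therefore order-independent.
* Degenerate inputs: empty gold or system sets score 0 by convention; empty
  documents yield empty graphs; an all-zero statistics report carries a
  warning line.

## Problem sizes

The default test and acceptance runs use corpora of 3–100 documents
(roughly 15 entities each), 20–50 seeds for the property suites, and
30-node graphs for the closure oracle — sizes at which the brute-force
oracles (per-node BFS, exhaustive ancestor search, direct set computation
from the ledger) are exact and instantaneous, so every comparison is
against an independently computed expectation.

## Known limitations

* The official annotation-oriented matching protocol (approximate spans,
  event-equality rules) is out of scope; only KB-oriented scoring is
  implemented.
* Coreference and modification annotation are carried through opaquely, not
  interpreted; the knowledge bases therefore under-link mentions of the
  same entity.
* The TAO vocabulary is used minimally (`Context_entity`, `denoted_by`);
  no provenance vocabulary is emitted.
* The shipped GRO hierarchy is the synthetic stand-in described above, not
  the published ontology.
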