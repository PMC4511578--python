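# geniakb

Knowledge-base-oriented evaluation tooling for biomedical event annotation.

Event extraction systems for the molecular-biology literature are usually
evaluated *annotation by annotation*: each predicted event is matched against
a gold event. That view penalises purely schematic differences — whether an
annotator attached a causal protein to the outermost of a stack of regulation
events or directly to the inner one — which matter to annotation
practitioners but not to the biologists who would query the extracted
knowledge. `geniakb` implements the complementary *KB-oriented* view: gold
and system annotations are converted into RDF knowledge bases, a fixed set of
eight biologically motivated queries is run over both, and the answer sets
(text spans denoting proteins, or protein pairs) are compared.

The package is aimed at shared-task organisers and event-extraction
researchers who want to score submissions from the KB perspective, and at
anyone who needs robust tooling for the underlying formats.

## What it does

* **Formats** — read/write the BioNLP `a*` standoff format (tab/space/colon
  grammar, `Theme2`-style coordination suffixes) and the relation-centric
  JSON format (denotations + binary relations), with a lossless bridge
  between the event-centric and relation-centric views: an n-ary event
  becomes one event denotation plus n binary relations (`themeOf`,
  `causeOf`, …) and back.
* **RDF export** — each denotation yields a context entity typed with its
  concept and linked by `tao:denoted_by` to a dereferenceable span IRI
  (`…/docs/sourcedb/PMC/sourceid/1359074/divs/0/spans/0-4`); each relation
  becomes a single triple in the task namespace.
* **Queries Q1–Q8** — proteins in gene-expression / localization / binding
  contexts (Q1–Q3), binding protein pairs (Q4), regulation pairs without and
  with transitive inference on `themeOf` (Q5/Q6), and regulation of gene
  expression without and with that inference (Q7/Q8). Transitivity means:
  if A is a theme of B and B is a theme of C, then A is a theme of C — this
  is what abstracts the schematic variation away.
* **Scoring** — per query: recall `R = 100·TP/GS`, precision
  `Pr = 100·TP/P`, `F1 = 2·R·Pr/(R+Pr)`, with TP the intersection of the
  gold and system answer sets; two-decimal half-up rounding, F1 computed
  from unrounded R and Pr.
* **GE ↔ GRO conversion** — relabel a corpus between the Genia event schema
  and the Gene Regulation Ontology via an equivalence table, using
  nearest-mapped-ancestor subsumption for GRO concepts with no direct
  equivalent, and report convertibility statistics.
* **Synthetic corpora** — a seeded generator produces gold documents (nested
  regulation chains, multi-theme binding, causal attachments) together with
  a ledger of every query-relevant fact, plus a perturbation operator
  (deletions, retypings, span shifts, schematic rewrites) that fabricates
  degraded "submissions". Everything above is testable without downloading
  any corpus.

## Worked example

Score a degraded synthetic submission against its own gold corpus:

```python
from geniakb.synthcorpus import CorpusConfig, PerturbationConfig, generate_gold, perturb
from geniakb.bridge import events_to_relations
from geniakb.rdfkb import corpus_to_triples
from geniakb.kbeval import evaluate_submission, format_table

corpus = generate_gold(CorpusConfig(n_docs=20, seed=7, cause_prob=0.8))
gold = corpus_to_triples(events_to_relations(d) for d in corpus.documents)
degraded = perturb(corpus.documents,
                   PerturbationConfig(p_delete_event=0.15,
                                      p_schematic_rewrite=0.5, seed=8))
system = corpus_to_triples(events_to_relations(d) for d in degraded)
print(format_table(evaluate_submission(gold, system)))
```

prints

```
query	GS	P	TP	R	Pr	F
Q1	31	26	26	83.87	100.00	91.23
Q2	12	11	11	91.67	100.00	95.65
Q3	32	23	23	71.88	100.00	83.64
Q4	20	14	14	70.00	100.00	82.35
Q5	20	7	7	35.00	100.00	51.85
Q6	47	35	35	74.47	100.00	85.37
Q7	9	5	3	33.33	60.00	42.86
Q8	15	10	10	66.67	100.00	80.00
```

Deletions only remove answers, so precision stays at 100 while recall drops.
The schematic rewrites hit the single-step regulation query Q5 hard (F1
51.85) but are largely absorbed by its transitive counterpart Q6 (85.37):
re-expressing *how* a cause is attached does not change *what* regulates
what once `themeOf` chains are closed transitively.

The same pipeline is available from the shell:

```sh
geniakb simulate --out corpus/ --n-docs 20 --seed 7
geniakb rdf --in corpus/doc0.json --in corpus/doc1.json --out gold.nt
geniakb query --graph gold.nt --query Q6
geniakb evaluate --gold gold.nt --system sys.nt
geniakb taskconvert --direction ge2gro --text corpus/doc0.txt \
    --ann corpus/doc0.ann --out gro0.ann
```

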