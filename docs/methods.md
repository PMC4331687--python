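# Methods

## Problem setting

The package locates chemical entity mentions (CEMs) — systematic names,
formulas, trivial names, identifiers, abbreviations, family names — as
exact character spans in PubMed-style records.  Each record has a title and
an abstract with *independent* offset spaces (0-based, end-exclusive,
counted over Unicode code points).  A mention is valid only if its text
equals the section substring at its span, and scoring is strict: document,
section, start and end must all match.

## Preprocessing

**Character normalization** maps variant code points (full-width brackets,
typographic dashes and quotes, `≧/∗/≃` and similar) to canonical ones via
a strictly 1:1 table, so every character offset survives normalization.
The shipped table (`data/charmap.tsv`) contains the commonly seen
homoglyph pairs and is user-extensible.

**Sentence detection** places candidate boundaries at `.?!` followed by
whitespace, then merges adjacent sentences to a fixpoint when the left one
ends with a known abbreviation (`var.`, `sp.`, `cv.`, `syn.`, `e.g.`, …;
`data/abbreviations.txt`) or a comma, or the right one starts with a
lower-case letter.  Rule-based merging was chosen over a trained boundary
model: the failure modes in this genre are enumerable, and determinism
matters for offset bookkeeping.

**Tokenization** is deliberately finer than word level so that formula
components become separate tokens: every bracket/operator/symbol character
from a fixed inventory, every Greek letter, and every maximal digit run is
its own token; remaining maximal letter runs stay whole
(`[C(8)mim][PF(6)]` → 13 tokens).  Digit runs are kept whole (`125` is one
token) — the point of the fine split is separating numbers from letters,
not digit-by-digit atomization.  A plural upper-case abbreviation (≥ 2
uppercase letters + terminal `s`, e.g. `NPs`) splits into the run and `s`;
the length-2 minimum protects ordinary words like `As`.  Every token
records its half-open source span; offset fidelity is property-tested.

## Recognition

A linear-chain CRF over **{B, I, E, O}** with tied observation weights
(each retained observation feature × each label) plus a dense 4×4
transition matrix, which *is* the contextual label-bigram family.  The
scheme has no dedicated single-token label; a lone B encodes a
single-token mention, and the decoder also repairs orphan `I…E` blocks by
treating their first token as B.

Training minimizes the penalized negative log-likelihood
`−Σ log Pr(y|x) + ‖w‖²/(2c)` with L-BFGS from `w = 0`; the cost `c`
multiplies the data term's influence, so larger `c` fits more tightly.
Observation features occurring fewer than 2 times (configurable) are
dropped.  Convergence: relative objective change < 1e−5 or 300 iterations.
The forward–backward and Viterbi recursions are computed in log space;
both are verified against exhaustive enumeration over all `4^N` label
sequences for `N ≤ 6` (the enumeration is the independent oracle, kept
free of the recursions it checks).  Viterbi ties resolve toward the
earlier label in the fixed order (B, I, E, O), so the all-zero model
deterministically emits B.  The trainer is fully vectorized across a
padded sentence batch; one objective evaluation on ~1,400 sentences takes
tens of milliseconds, which is what keeps the end-to-end suites fast.

## Feature families

* **General linguistic** — surface uni/bi-grams and Porter-stemmed
  uni/bi/tri-grams over a ±2-token window (a conventional span for this
  task family; the window is configurable).  The Porter stemmer is
  implemented in-package from the published algorithm and checked against
  its reference examples.
* **Character** — digit/upper/lower/total counts; presence flags for the
  tokenizer's special characters, Greek letters, Roman numerals
  (`^[IVXLCDM]+$`), three-letter amino-acid codes (case-insensitive), and
  the 118 element symbols (whole token or leading capital segment).
* **Case pattern** — per-character substitution (upper→`A`, lower→`a`,
  digit→`0`, others verbatim), its run-collapsed form, and a fully generic
  letters→`a` form (`Abc123 → Aaa000 / Aa0 / a0`).
* **Contextual** — the label bigram, realized structurally as the CRF
  transition matrix rather than as an observation feature.
* **Word representation** — Brown-cluster path prefixes of lengths
  {4, 6, 10, 20} plus the full path; out-of-vocabulary tokens yield the
  sentinel `UNK`.  The prefix set is configurable.

Five presets (`run1` … `run5`) mirror the standard ablation: run 1 without
word representations, runs 2–5 adding Brown clusters at 500/1000/1500/2000
clusters.

## Brown clustering

Greedy agglomerative clustering maximizing the average mutual information
of adjacent-cluster bigrams, with the classic restricted window: the C most
frequent types seed singleton clusters; each remaining type (frequency
order) enters as a provisional (C+1)-th cluster and the AMI-optimal pair is
merged.  The final C clusters are then merged down to one root; that merge
sequence is the binary tree from which paths are read (0 = left/smaller
representative, 1 = right).  All types in a cluster share its path, the
path set is prefix-free, and everything is deterministic: types are
processed in (frequency desc, token asc) order and AMI ties break toward
the lexicographically smallest pair of representatives.  Sentence
boundaries break bigram adjacency.  Types under `min_count` map to `UNK`
before clustering.

The per-candidate merge evaluation is an O(C) update of the global AMI
(only terms touching the two rows/columns change), verified against a
recompute-from-scratch oracle.  The implementation targets the vocabulary
sizes of the bundled synthetic corpora (hundreds of types, tens of
clusters); it is not tuned for corpus-scale vocabularies with thousands of
clusters.  For the end-to-end synthetic runs the cluster count is 32 with
`min_count = 2` — scaled to a synthetic vocabulary of a few hundred types,
where 500+ clusters would degenerate to one type per cluster and the
representation would stop generalizing.

## Post-processing and confidence

Removal patterns (anchored regexes, `data/removal_patterns.txt`) drop
citation-shaped (`25(3), 186-193`) and hyphenated-enumeration (`1-D, 2-D`)
false positives; patterns match the mention text only, not its context.
The 14 span-adjustment rules are data, not code: for each of seven marker
pairs (`()`, `[]`, `{}`, `<sc></sc>`, `<i></i>`, `<sup></sup>`,
`<sub></sub>`) an end-extending rule fires when the opener outnumbers the
closer by one and the closing marker sits immediately right of the span,
and a start-extending rule mirrors it.  Rules apply in id order, repeatedly
to a fixpoint (bounded at 8 rounds; the shipped marker families converge in
≤ 4), re-extracting the mention text after every move so the span/text
invariant holds throughout.  A move that would leave the section is skipped
with a warning.

A mention's confidence is the mean forward–backward marginal of its
tokens' decoded labels — always within [min, max] of those marginals —
and predictions are ranked per document by descending confidence with
(section, start, end) as the deterministic tie-break, printed with 6
decimals.

## Evaluation and cross-validation

Precision, recall and Fβ (β = 1 by default) from exact-span confusion
counts, with p = 0 when there are no predictions, r = 0 when there is no
gold, F = 0 when p + r = 0; percentages are rounded half-up to 2 decimals.
Per-class figures are **class-conditional recall**: the tagger emits no
classes, so the fraction of each gold class recovered is the only
class-wise quantity its output supports; class-conditional precision is
not computable and is deliberately not reported.

`cv_grid_search` partitions documents (title+abstract stay together) into
k seeded near-equal folds and trains k models per grid value; the best
cost is the argmax of mean F1, ties to the smaller (less over-fitting)
value.  The fold scorer is injected as a callable so the evaluation module
stays decoupled from the tagger; `chemner.pipeline.crossval_fold_scorer`
wires in the full pipeline.

## Synthetic corpora

The fixtures module generates corpora in the exact carrier formats, with
gold offsets computed during construction (and therefore exact by
construction).  Four surface grammars mimic the look of the major mention
classes — bracketed element/digit formulas, stem+suffix trivial names,
registry-prefix identifiers, 2–4-letter uppercase abbreviations — embedded
in template sentences of lowercase filler words, with citation-shaped
distractors inserted un-annotated at a configurable rate.  Defaults: one
expected mention per sentence, mix weights (0.25, 0.35, 0.2, 0.2) echoing
the dominance of trivial names over identifiers in real chemical corpora,
10 % distractor rate.

What the generator does *not* emulate: nested gold mentions, annotation
errors, class ambiguity, long-range discourse, or the lexical diversity of
real abstracts.  Entities are drawn from grammars disjoint from the filler
vocabulary, so the learning problem is separable and near-perfect F1 on
held-out synthetic text is expected — passing the ≥ 90 % end-to-end check
demonstrates that the pipeline's stages compose correctly (offsets,
features, training, decoding, post-processing, scoring), not that
corpus-scale CHEMDNER accuracy would be reproduced.  Corpus-scale scores
require the original annotated corpus and are out of scope; the published
confusion counts are instead used as direct inputs to the metric engine.

## Problem sizes

The bundled end-to-end runs train on 240 generated documents (~1,440
sentences) and score 90 held-out documents (~550 sentences), totalling
~2,000 sentences; the CRF oracle checks use 100 random models of length
≤ 6; Brown recovery uses 6-type streams of 600 tokens where exhaustive
partition search is feasible.  These sizes were chosen so the whole suite
and the acceptance script each run comfortably on a single CPU.

## Known limitations

* The prediction file format stores no mention text; reading predictions
  back yields placeholder text of the correct length (matching is
  key-based, so evaluation is unaffected).
* The Brown trainer's windowed phase rebuilds candidate scores per merge
  (O(C³) per step); corpus-scale use would want the cached-delta variant.
* Sentence merging can absorb inter-sentence whitespace into a sentence
  span; covered non-whitespace text is never dropped.
* The abbreviation list, normalization map and removal patterns ship with
  conservative seed inventories and are meant to be extended per corpus.
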