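# chemner

Chemical entity mention (CEM) recognition for PubMed-style abstracts:
a BIEO linear-chain CRF tagger with Brown-cluster word representations,
offset-preserving preprocessing, rule-based post-processing with confidence
scoring, and entity-level evaluation with cost-parameter cross-validation.

## Who this is for

Text-mining practitioners who need to locate mentions of chemical compounds
and drugs — systematic names, formulas, trivial names, database identifiers,
abbreviations — as exact character spans in titles and abstracts, in the
tab-separated corpus format popularized by the BioCreative CHEMDNER task
(`PMID`, section `T`/`A`, start, end, text, class).

## The model

Mention extraction is cast as sequence labeling over the label set
**{B, I, E, O}** (begin / inside / end / outside of a span; a single-token
mention is a lone B).  A linear-chain conditional random field defines

```
Pr(y | x) ∝ exp( Σₙ wᵀ f(yₙ, yₙ₋₁, x) )
```

over token sequences x and label sequences y.  The weight vector w is
estimated by L-BFGS on the L2-regularized conditional log-likelihood
`Σ log Pr(y|x) − ‖w‖²/(2c)`; the **cost parameter c** trades data fit
against regularization and is selected by 10-fold document-level
cross-validation with grid search over `{2⁻³ … 2³}`.

Five feature families feed the model: surface/stemmed n-grams (an
in-package Porter stemmer), character statistics (digit/case counts and
flags for Greek letters, Roman numerals, amino-acid codes, element
symbols), case-pattern abstractions (`Abc123 → Aaa000 → Aa0 → a0`), the
label bigram (realized as the CRF's transition weights), and **Brown
clusters**: word types are agglomeratively merged to maximize the mutual
information of adjacent-cluster bigrams, and each type's path through the
merge tree (0 = left, 1 = right) yields bit-string features whose prefixes
encode distributional similarity.  Brown clusters can be induced from
un-annotated abstracts pooled with the training data — the semi-supervised
step that raises recall.

Decoded mentions pass through rule-based post-processing: removal patterns
for citation-shaped false positives (`25(3), 186-193`), and 14
marker-balancing rules that absorb a missing bracket or markup tag from the
adjacent text (`[4Fe-4S](2+` → `[4Fe-4S](2+)`).  Each mention is scored by
the mean forward–backward marginal of its tokens' labels,
`score(CEM) = (1/|CEM|) Σₜ CondProb(t)`, and ranked per document.

Evaluation is strict entity-level matching — a prediction is correct only
if document, section, start and end all agree — reported as percentage
precision, recall and F1.

## Worked example

```sh
chemner gen-fixture demo --docs 30 --seed 5         # synthetic corpus
chemner train demo.abstracts.tsv demo.gold.tsv model \
    --preset run2 --clusters 24 --cost 2
chemner tag demo.abstracts.tsv model preds.tsv
chemner eval preds.tsv demo.gold.tsv
```

prints

```
precision       100.00
recall  100.00
F1      100.00
ABBREVIATION    100.00
FORMULA 100.00
IDENTIFIER      100.00
TRIVIAL 100.00
```

— entity-level precision/recall/F1 over exact spans, then the fraction of
each gold class recovered.  The synthetic corpus embeds chemical-like
surfaces (`[C(8)mim][PF(6)]`-shaped formulas, `-ol/-ine/-ane` trivial
names, registry identifiers, uppercase abbreviations) at exactly known
offsets; on this separable benchmark the tagger is perfect.  `preds.tsv`
holds the official 4-column format: document, `section:start:end`,
per-document rank, 6-decimal confidence:

```
900500000	A:77:81	1	0.998088
900500000	A:19:29	2	0.996198
```

The same pipeline is available as a library (`chemner.TaggerPipeline`,
`chemner.LinearChainCRF`, `chemner.train_brown`, …).

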