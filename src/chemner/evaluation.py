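"""Entity-level evaluation and cost-parameter cross-validation.

A predicted mention counts as a true positive only when its (document,
section, start, end) exactly equals a gold mention's — the strict matching
of the CEM task.  From the confusion counts,

    r  = TP / (TP + FN)
    p  = TP / (TP + FP)
    Fβ = (1 + β²) p r / (β² p + r)      (β = 1 by default)

reported as percentages rounded half-up to two decimals.  Per-class numbers
are class-conditional recall: the tagger itself emits no classes, so the
fraction of each gold class recovered is the only per-class quantity
computable from its output.

The cost parameter c is selected by k-fold cross-validation at document
level: documents are randomly partitioned (seeded) into near-equal folds,
and for each candidate c the pipeline is trained k times, each time scoring
the held-out fold; the c with the best mean F1 wins (ties to the smaller c).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Sequence

import numpy as np

from .corpus import Document, Mention


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class MetricReport:
    precision: float  # percent
    recall: float     # percent
    f_score: float    # percent
    beta: float = 1.0
    per_class: dict[str, float] = field(default_factory=dict)


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"),
                                           rounding=ROUND_HALF_UP))


def match_exact(predictions: Sequence[Mention],
                gold: Sequence[Mention]) -> ConfusionCounts:
    """1:1 exact-span matching on (doc_id, section, start, end)."""
    pred_keys = [m.key for m in predictions]
    unique = set(pred_keys)
    if len(unique) < len(pred_keys):
        warnings.warn("duplicate identical predictions deduplicated")
    gold_keys = {m.key for m in gold}
    tp = len(unique & gold_keys)
    return ConfusionCounts(TP=tp, FP=len(unique) - tp,
                           FN=len(gold_keys) - tp)


def metrics(counts: ConfusionCounts, beta: float = 1.0) -> MetricReport:
    """Precision/recall/Fβ as percentages with 2-decimal half-up rounding.

    Degenerate denominators follow the usual conventions: p = 0 when no
    predictions, r = 0 when no gold, F = 0 when p + r = 0.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    tp, fp, fn = counts.TP, counts.FP, counts.FN
    p = tp / (tp + fp) if tp + fp > 0 else 0.0
    r = tp / (tp + fn) if tp + fn > 0 else 0.0
    if p + r > 0:
        f = (1 + beta ** 2) * p * r / (beta ** 2 * p + r)
    else:
        f = 0.0
    return MetricReport(precision=_round2(100 * p), recall=_round2(100 * r),
                        f_score=_round2(100 * f), beta=beta)


def per_class_breakdown(predictions: Sequence[Mention],
                        gold: Sequence[Mention]) -> dict[str, float]:
    """Class-conditional recall: percentage of each gold class whose span is
    exactly matched by some prediction.  Classes absent from the gold are
    omitted."""
    pred_keys = {m.key for m in predictions}
    totals: dict[str, int] = {}
    hits: dict[str, int] = {}
    for g in gold:
        cls = g.cem_class or "NO CLASS"
        totals[cls] = totals.get(cls, 0) + 1
        if g.key in pred_keys:
            hits[cls] = hits.get(cls, 0) + 1
    return {cls: _round2(100 * hits.get(cls, 0) / n)
            for cls, n in sorted(totals.items())}


def evaluate(predictions: Sequence[Mention], gold: Sequence[Mention],
             beta: float = 1.0) -> MetricReport:
    """match_exact + metrics + per-class recall in one call."""
    report = metrics(match_exact(predictions, gold), beta)
    return MetricReport(
        precision=report.precision, recall=report.recall,
        f_score=report.f_score, beta=beta,
        per_class=per_class_breakdown(predictions, gold),
    )


FoldScorer = Callable[
    [Sequence[Document], Sequence[Mention],
     Sequence[Document], Sequence[Mention], float],
    float,
]


def make_folds(documents: Sequence[Document], k: int,
               seed: int) -> list[list[Document]]:
    """Seeded random partition of documents into k near-equal folds."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(documents) < k:
        raise ValueError(f"{len(documents)} documents cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(documents))
    folds: list[list[Document]] = [[] for _ in range(k)]
    for i, idx in enumerate(order):
        folds[i % k].append(documents[idx])
    return folds


def cv_grid_search(
    documents: Sequence[Document],
    gold: Sequence[Mention],
    grid: Sequence[float],
    k: int,
    seed: int,
    fold_scorer: FoldScorer,
) -> tuple[float, dict[float, float]]:
    """Document-level k-fold cross-validation over the cost grid.

    ``fold_scorer(train_docs, train_gold, test_docs, test_gold, c)`` must
    return the held-out F1 (percent).  Returns the best c (ties to the
    smaller value) and the full per-c mean-F1 table.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    folds = make_folds(documents, k, seed)
    by_doc: dict[str, list[Mention]] = {}
    for m in gold:
        by_doc.setdefault(m.doc_id, []).append(m)

    def mentions_of(docs: Sequence[Document]) -> list[Mention]:
        return [m for d in docs for m in by_doc.get(d.doc_id, [])]

    table: dict[float, float] = {}
    for c in grid:
        scores = []
        for i in range(k):
            test_docs = folds[i]
            train_docs = [d for j, f in enumerate(folds) if j != i for d in f]
            scores.append(fold_scorer(
                train_docs, mentions_of(train_docs),
                test_docs, mentions_of(test_docs), c,
            ))
        table[c] = float(np.mean(scores))
    best = min(table, key=lambda c: (-table[c], c))
    return best, table
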