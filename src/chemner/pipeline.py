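"""End-to-end tagging pipeline: preprocess → features → CRF → post-process.

Wires the modules into the three-stage system: offset-preserving
preprocessing, BIEO CRF recognition with the configured feature families
(optionally Brown-cluster representations trained on the same or a larger
un-annotated pool), and rule-based post-processing with Eq.-style averaged
marginal confidence scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .brown import BrownModel, train_brown
from .corpus import Document, Mention, resolve_nested
from .crf import LinearChainCRF, decode_blocks, encode_bieo
from .evaluation import MetricReport, evaluate
from .features import FeatureConfig, assemble_features
from .postprocess import adjust_spans, confidence_score, remove_false_positives
from .preprocess import Token, tokenize_section


@dataclass
class PipelineConfig:
    features: FeatureConfig = field(default_factory=FeatureConfig)
    c: float = 1.0
    cutoff: int = 2
    max_iter: int = 300
    brown_min_count: int = 2


class TaggerPipeline:
    """Train on gold-annotated documents; tag new ones with confidences."""

    def __init__(self, config: PipelineConfig | None = None):
        self.config = config or PipelineConfig()
        self.crf: LinearChainCRF | None = None
        self.brown_model: BrownModel | None = None

    # -- helpers -----------------------------------------------------------

    @staticmethod
    def _sentences(doc: Document) -> list[tuple[str, list[Token]]]:
        out = []
        for section in ("T", "A"):
            for sent in tokenize_section(doc.section_text(section)):
                out.append((section, sent))
        return out

    def _token_stream(self, docs: Sequence[Document]) -> list[list[str]]:
        return [[t.surface for t in sent]
                for doc in docs for _, sent in self._sentences(doc)]

    # -- training ----------------------------------------------------------

    def fit(
        self,
        documents: Sequence[Document],
        gold: Sequence[Mention],
        unannotated: Sequence[Document] = (),
        brown_model: BrownModel | None = None,
    ) -> "TaggerPipeline":
        """Train the CRF (and, if configured, the Brown model).

        ``unannotated`` documents are pooled with the training documents for
        Brown clustering only — the semi-supervised trick of inducing word
        representations from cheap unlabelled abstracts.  A pre-trained
        ``brown_model`` can be supplied instead.
        """
        cfg = self.config
        if cfg.features.brown:
            if brown_model is not None:
                self.brown_model = brown_model
            else:
                stream = self._token_stream(list(documents) + list(unannotated))
                vocab = {t for s in stream for t in s}
                n_clusters = min(cfg.features.n_clusters, len(vocab))
                self.brown_model = train_brown(
                    stream, n_clusters, min_count=cfg.brown_min_count)

        gold = resolve_nested(gold)
        by_doc_section: dict[tuple[str, str], list[Mention]] = {}
        for m in gold:
            by_doc_section.setdefault((m.doc_id, m.section), []).append(m)

        X, y = [], []
        for doc in documents:
            for section, sent in self._sentences(doc):
                mentions = by_doc_section.get((doc.doc_id, section), [])
                lo, hi = sent[0].start, sent[-1].end
                spans = [(m.start, m.end) for m in mentions
                         if m.start < hi and m.end > lo]
                X.append(assemble_features(sent, cfg.features,
                                           self.brown_model))
                y.append(encode_bieo(sent, spans))
        self.crf = LinearChainCRF(
            c=cfg.c, cutoff=cfg.cutoff, max_iter=cfg.max_iter).fit(X, y)
        return self

    # -- tagging -----------------------------------------------------------

    def tag(self, documents: Sequence[Document]) -> list[Mention]:
        """Tag documents; returns scored, post-processed mentions."""
        if self.crf is None:
            raise RuntimeError("pipeline is not fitted")
        cfg = self.config
        out: list[Mention] = []
        for doc in documents:
            for section, sent in self._sentences(doc):
                feats = assemble_features(sent, cfg.features, self.brown_model)
                labels = self.crf.viterbi(feats)
                marg = self.crf.marginals(feats)
                label_idx = {lab: i for i, lab in enumerate(self.crf.labels)}
                section_text = doc.section_text(section)
                for i, j in decode_blocks(labels):
                    start, end = sent[i].start, sent[j].end
                    conf = confidence_score(
                        [marg[n, label_idx[labels[n]]]
                         for n in range(i, j + 1)])
                    mention = Mention(
                        doc.doc_id, section, start, end,
                        section_text[start:end], confidence=conf)
                    out.append(adjust_spans(mention, section_text))
        return remove_false_positives(out)

    def score(self, documents: Sequence[Document],
              gold: Sequence[Mention]) -> MetricReport:
        return evaluate(self.tag(documents), resolve_nested(gold))

    # -- persistence -------------------------------------------------------

    def save(self, prefix: str) -> None:
        """Persist as ``<prefix>.crf.json`` (+ ``<prefix>.brown.tsv``) plus a
        config sidecar."""
        import json
        from dataclasses import asdict

        if self.crf is None:
            raise RuntimeError("pipeline is not fitted")
        self.crf.save(f"{prefix}.crf.json")
        if self.brown_model is not None:
            self.brown_model.save(f"{prefix}.brown.tsv")
        cfg = asdict(self.config)
        cfg["features"]["prefix_lengths"] = list(
            self.config.features.prefix_lengths)
        with open(f"{prefix}.config.json", "w", encoding="utf-8") as fh:
            json.dump(cfg, fh)

    @classmethod
    def load(cls, prefix: str) -> "TaggerPipeline":
        import json
        import os

        with open(f"{prefix}.config.json", encoding="utf-8") as fh:
            raw = json.load(fh)
        feat = raw.pop("features")
        feat["prefix_lengths"] = tuple(feat["prefix_lengths"])
        config = PipelineConfig(features=FeatureConfig(**feat), **raw)
        pipe = cls(config)
        pipe.crf = LinearChainCRF.load(f"{prefix}.crf.json")
        if os.path.exists(f"{prefix}.brown.tsv"):
            pipe.brown_model = BrownModel.load(f"{prefix}.brown.tsv")
        return pipe


def crossval_fold_scorer(config: PipelineConfig):
    """A :func:`chemner.evaluation.cv_grid_search` fold scorer running the
    full pipeline at the given cost."""

    def scorer(train_docs, train_gold, test_docs, test_gold, c: float) -> float:
        cfg = PipelineConfig(
            features=config.features, c=c, cutoff=config.cutoff,
            max_iter=config.max_iter, brown_min_count=config.brown_min_count)
        pipe = TaggerPipeline(cfg).fit(train_docs, train_gold)
        return pipe.score(test_docs, test_gold).f_score

    return scorer
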