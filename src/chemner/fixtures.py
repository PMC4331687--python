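"""Deterministic synthetic corpora for exercising the full pipeline.

Real CHEMDNER-style corpora cannot be bundled, so this module generates
documents in the exact carrier formats of :mod:`chemner.corpus`: template
sentences of common lowercase filler words with chemical-like surfaces
embedded at exactly known offsets.  Four surface families mimic the look of
the major mention classes:

* formula-like       — element symbols, digits and brackets
  (``[C(8)mim][PF(6)]``-shaped);
* trivial-name-like  — pronounceable stems with -ol/-ine/-ane suffixes;
* identifier-like    — registry prefix plus digits (``CID73-02-9``-shaped);
* abbreviation-like  — 2–4 uppercase letters.

Surfaces are drawn from parameterized grammars, not fixed word lists, so
held-out documents contain unseen-but-patterned entities — exactly the
generalization the character/case/Brown features exist to capture.
Citation-like distractor spans (``12(3), 45-67``) are inserted un-annotated
at a configurable rate to give the false-positive removal rules something
to do.  All randomness flows from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import Document, Mention

_FILLERS = (
    "the of and in with was were is are on for effect effects cell cells "
    "activity treatment exposure study results analysis assay increased "
    "decreased observed measured induced inhibited binding receptor protein "
    "plasma serum dose response levels concentration patients mice rats "
    "samples significant role against during after before under using"
).split()

_TEMPLATES = (
    ("the effect of", "on cell viability was investigated"),
    ("treatment with", "increased receptor activity in mice"),
    ("exposure to", "decreased plasma levels significantly"),
    ("we measured the binding of", "to the purified protein"),
    ("the assay detected", "in all serum samples"),
    ("rats were injected with", "before the response was recorded"),
    ("levels of", "were elevated in treated patients"),
    ("the role of", "in dose response remains unclear"),
)

_STEM_SYLLABLES = ("meth eth prop but pent hex benz chlor fluor brom amin "
                   "carb oxal glyc phen sulf nitr acet tol xyl").split()
_SUFFIXES = ("ol ine ane ene ate ide amide").split()
_ELEMENTS = ("C H N O P S F Cl Br Na K Ca Fe Zn Cu Mg Pt").split()
_ID_PREFIXES = ("CID", "CHEMBL", "DB", "CAS")


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs of the generator; the seed fixes all randomness."""

    n_documents: int = 50
    sentences_per_abstract: int = 5
    entity_rate: float = 1.0          # expected mentions per sentence
    pattern_mix: tuple[float, float, float, float] = (0.25, 0.35, 0.2, 0.2)
    noise: float = 0.1                # probability of a distractor span
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.pattern_mix) - 1.0) > 1e-9:
            raise ValueError("pattern_mix weights must sum to 1")


def _formula_surface(rng: np.random.Generator) -> str:
    parts = []
    for _ in range(int(rng.integers(1, 3))):
        el = str(rng.choice(_ELEMENTS))
        n = int(rng.integers(1, 20))
        inner = f"{el}({n}){rng.choice(['mim', 'py', 'im', ''])}"
        parts.append(f"[{inner}]" if rng.random() < 0.7 else f"{el}{n}")
    return "".join(parts)


def _trivial_surface(rng: np.random.Generator) -> str:
    n_syl = int(rng.integers(1, 4))
    stem = "".join(rng.choice(_STEM_SYLLABLES) for _ in range(n_syl))
    return stem + str(rng.choice(_SUFFIXES))


def _identifier_surface(rng: np.random.Generator) -> str:
    prefix = str(rng.choice(_ID_PREFIXES))
    return prefix + str(int(rng.integers(100, 10 ** 6)))


def _abbrev_surface(rng: np.random.Generator) -> str:
    k = int(rng.integers(2, 5))
    return "".join(chr(ord("A") + int(rng.integers(26))) for _ in range(k))


_FAMILIES = (
    ("FORMULA", _formula_surface),
    ("TRIVIAL", _trivial_surface),
    ("IDENTIFIER", _identifier_surface),
    ("ABBREVIATION", _abbrev_surface),
)


def _distractor(rng: np.random.Generator) -> str:
    return (f"{int(rng.integers(1, 60))}({int(rng.integers(1, 13))}), "
            f"{int(rng.integers(1, 400))}-{int(rng.integers(400, 999))}")


def _make_sentence(
    rng: np.random.Generator, config: FixtureConfig
) -> tuple[str, list[tuple[int, int, str, str]]]:
    """One sentence and its (start, end, text, class) gold entities."""
    head, tail = _TEMPLATES[int(rng.integers(len(_TEMPLATES)))]
    n_entities = int(rng.random() < min(config.entity_rate, 1.0))
    if config.entity_rate > 1.0 and rng.random() < config.entity_rate - 1.0:
        n_entities += 1

    words: list[tuple[str, str | None]] = [(w, None) for w in head.split()]
    for i in range(max(n_entities, 0)):
        fam_idx = int(rng.choice(len(_FAMILIES), p=config.pattern_mix))
        cls, make = _FAMILIES[fam_idx]
        words.append((make(rng), cls))
        if i < n_entities - 1:
            words.append(("and", None))
    if n_entities == 0:
        words.append((str(rng.choice(_FILLERS)), None))
    words.extend((w, None) for w in tail.split())
    if rng.random() < config.noise:
        words.append(("see", None))
        words.append((_distractor(rng), None))
    words.append((".", None))

    text_parts: list[str] = []
    entities: list[tuple[int, int, str, str]] = []
    cursor = 0
    for i, (surface, cls) in enumerate(words):
        if i > 0:
            text_parts.append(" ")
            cursor += 1
        if cls is not None:
            entities.append((cursor, cursor + len(surface), surface, cls))
        text_parts.append(surface)
        cursor += len(surface)
    return "".join(text_parts), entities


def _make_section(rng: np.random.Generator, config: FixtureConfig,
                  n_sentences: int) -> tuple[str, list[tuple[int, int, str, str]]]:
    parts: list[str] = []
    entities: list[tuple[int, int, str, str]] = []
    cursor = 0
    for i in range(n_sentences):
        if i > 0:
            parts.append(" ")
            cursor += 1
        sent, ents = _make_sentence(rng, config)
        entities.extend((s + cursor, e + cursor, t, c) for s, e, t, c in ents)
        parts.append(sent)
        cursor += len(sent)
    return "".join(parts), entities


def generate_corpus(config: FixtureConfig) -> tuple[list[Document], list[Mention]]:
    """Generate documents and exactly-offset gold mentions."""
    rng = np.random.default_rng(config.seed)
    docs: list[Document] = []
    gold: list[Mention] = []
    for d in range(config.n_documents):
        doc_id = f"9{config.seed % 1000:03d}{d:05d}"
        title, t_ents = _make_section(rng, config, 1)
        abstract, a_ents = _make_section(
            rng, config, config.sentences_per_abstract)
        docs.append(Document(doc_id, title, abstract))
        for section, ents in (("T", t_ents), ("A", a_ents)):
            for s, e, text, cls in ents:
                gold.append(Mention(doc_id, section, s, e, text, cem_class=cls))
    return docs, gold


def generate_bigram_stream(
    n_types: int,
    n_tokens: int,
    n_blocks: int = 2,
    coupling: float = 0.95,
    seed: int = 0,
    sentence_length: int = 20,
) -> list[list[str]]:
    """Token stream with planted block structure in its bigram statistics.

    Types are split round-robin into ``n_blocks`` blocks; with probability
    ``coupling`` a token of block b is followed by one of block (b+1) mod
    ``n_blocks``, otherwise by a uniformly random type.  With strong
    coupling the planted blocks are the mutual-information-optimal
    clustering at k = ``n_blocks``.
    """
    if n_types < 2:
        raise ValueError("need at least 2 types")
    rng = np.random.default_rng(seed)
    types = [f"w{i:02d}" for i in range(n_types)]
    blocks = [[types[i] for i in range(b, n_types, n_blocks)]
              for b in range(n_blocks)]
    stream: list[list[str]] = []
    sentence: list[str] = []
    block = int(rng.integers(n_blocks))
    for _ in range(n_tokens):
        sentence.append(str(rng.choice(blocks[block])))
        if rng.random() < coupling:
            block = (block + 1) % n_blocks
        else:
            block = int(rng.integers(n_blocks))
        if len(sentence) >= sentence_length:
            stream.append(sentence)
            sentence = []
    if sentence:
        stream.append(sentence)
    return stream


def planted_blocks(n_types: int, n_blocks: int = 2) -> list[frozenset[str]]:
    """The ground-truth partition used by :func:`generate_bigram_stream`."""
    types = [f"w{i:02d}" for i in range(n_types)]
    return [frozenset(types[i] for i in range(b, n_types, n_blocks))
            for b in range(n_blocks)]
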