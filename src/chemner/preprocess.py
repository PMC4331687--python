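"""Character normalization, sentence detection with merge rules, and
fine-grained offset-preserving tokenization.

Chemical names are dense in brackets, digits and Greek letters, and gold
offsets are character-exact, so every stage here is offset-faithful: the
normalization map is strictly one-to-one per code point, sentence spans are
half-open offsets into the section, and each token records the half-open
span its surface was cut from.  The tokenizer splits at a finer grain than a
word tokenizer would — every bracket/operator character, every maximal digit
run and every Greek letter is its own token — so that a formula like
``[C(8)mim][PF(6)]`` decomposes into its 13 chemical components.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

# Bracket, operator and symbol characters always cut out as single tokens.
SPECIAL_CHARACTERS = frozenset(
    "()[]{}><≥≤,./\\'™@·©®\":=≠≡≈+-?_|"
    "↑↓←→↗↘↙↖↔⇌±~∗*%‰∘#&;!£€¥$×÷‡†⋯∞∨∧√⊥⊤∈∃⊂⊃∇■∂∫"
)

_SENTENCE_BOUNDARY = re.compile(r"[.?!](?=\s)")
_PLURAL_ABBREV = re.compile(r"^(\w\w+)s$")  # validated with isupper() below


def _data_text(name: str) -> str:
    return resources.files("chemner.data").joinpath(name).read_text("utf-8")


def load_charmap(path: str | Path | None = None) -> dict[int, int]:
    """Load the variant→canonical character map (1:1 by construction)."""
    text = Path(path).read_text("utf-8") if path else _data_text("charmap.tsv")
    table: dict[int, int] = {}
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        src, dst = line.split("\t")
        if len(src) != 1 or len(dst) != 1:
            raise ValueError(f"charmap entries must be single characters: {line!r}")
        table[ord(src)] = ord(dst)
    return table


def load_abbreviations(path: str | Path | None = None) -> frozenset[str]:
    text = Path(path).read_text("utf-8") if path else _data_text("abbreviations.txt")
    return frozenset(
        line for line in text.splitlines() if line and not line.startswith("#")
    )


_DEFAULT_CHARMAP = load_charmap()
_DEFAULT_ABBREVIATIONS = load_abbreviations()


def normalize_characters(text: str, charmap: dict[int, int] | None = None) -> str:
    """Replace variant characters with their canonical form.

    The map is 1:1 per code point, so ``len`` and all offsets are preserved;
    idempotent as long as the map's value set is disjoint from its key set.
    """
    return text.translate(_DEFAULT_CHARMAP if charmap is None else charmap)


@dataclass(frozen=True)
class SentenceSpan:
    """Half-open character span of one sentence within a section."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid sentence span [{self.start}, {self.end})")


@dataclass(frozen=True)
class Token:
    surface: str
    start: int
    end: int
    sentence_index: int = 0


def detect_sentences(text: str) -> list[SentenceSpan]:
    """Candidate sentence spans: split after ``.``, ``?`` or ``!`` followed by
    whitespace; spans are trimmed to exclude leading/trailing whitespace."""
    spans: list[SentenceSpan] = []
    cursor = 0
    boundaries = [m.end() for m in _SENTENCE_BOUNDARY.finditer(text)]
    for boundary in boundaries + [len(text)]:
        chunk = text[cursor:boundary]
        stripped = chunk.strip()
        if stripped:
            lead = len(chunk) - len(chunk.lstrip())
            spans.append(SentenceSpan(cursor + lead, cursor + lead + len(stripped)))
        cursor = boundary
    return spans


def merge_sentences(
    spans: Sequence[SentenceSpan],
    text: str,
    abbreviations: Iterable[str] | None = None,
) -> list[SentenceSpan]:
    """Undo over-eager sentence splits, repeatedly until a fixpoint.

    Two adjacent sentences are merged when the left one ends with a known
    abbreviation (``var.``, ``sp.``, ``cv.``, ``syn.`` …) or a comma, or the
    right one starts with a lower-case letter — both strong signals that the
    detected period was sentence-internal.
    """
    abbrevs = (_DEFAULT_ABBREVIATIONS if abbreviations is None
               else frozenset(abbreviations))
    merged = list(spans)
    changed = True
    while changed:
        changed = False
        out: list[SentenceSpan] = []
        i = 0
        while i < len(merged):
            span = merged[i]
            while i + 1 < len(merged):
                left = text[span.start:span.end]
                nxt = merged[i + 1]
                first = text[nxt.start]
                if (
                    any(left.endswith(a) for a in abbrevs)
                    or left.endswith(",")
                    or first.islower()
                ):
                    span = SentenceSpan(span.start, nxt.end)
                    i += 1
                    changed = True
                else:
                    break
            out.append(span)
            i += 1
        merged = out
    return merged


def split_sentences(text: str,
                    abbreviations: Iterable[str] | None = None
                    ) -> list[SentenceSpan]:
    """Detect then merge; the usual entry point."""
    spans = detect_sentences(text)
    return merge_sentences(spans, text, abbreviations)


def _is_greek(ch: str) -> bool:
    # Greek and Coptic block.
    return "Ͱ" <= ch <= "Ͽ"


def tokenize(text: str, offset: int = 0, sentence_index: int = 0) -> list[Token]:
    """Fine-grained tokenization of one (already normalized) sentence.

    Cut points: every character in :data:`SPECIAL_CHARACTERS`, every maximal
    digit run, every single Greek letter; remaining maximal letter runs stay
    whole.  A plural upper-case abbreviation (an all-uppercase run of length
    ≥ 2 with a final ``s``, e.g. ``NPs``) is split into the run and ``s``.
    ``offset`` shifts the recorded spans into section coordinates;
    concatenating surfaces with the original gaps reconstructs the sentence.
    """
    raw: list[tuple[str, int, int]] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
        elif ch in SPECIAL_CHARACTERS or _is_greek(ch):
            raw.append((ch, i, i + 1))
            i += 1
        elif ch.isdigit():
            j = i + 1
            while j < n and text[j].isdigit():
                j += 1
            raw.append((text[i:j], i, j))
            i = j
        else:
            j = i + 1
            while j < n:
                c = text[j]
                if (c.isspace() or c in SPECIAL_CHARACTERS or c.isdigit()
                        or _is_greek(c)):
                    break
                j += 1
            raw.append((text[i:j], i, j))
            i = j

    tokens: list[Token] = []
    for surface, start, end in raw:
        m = _PLURAL_ABBREV.match(surface)
        if m and m.group(1).isupper() and m.group(1).isalpha():
            head = m.group(1)
            tokens.append(Token(head, offset + start, offset + start + len(head),
                                sentence_index))
            tokens.append(Token("s", offset + end - 1, offset + end,
                                sentence_index))
        else:
            tokens.append(Token(surface, offset + start, offset + end,
                                sentence_index))
    return tokens


def tokenize_section(text: str,
                     abbreviations: Iterable[str] | None = None
                     ) -> list[list[Token]]:
    """Normalize, sentence-split, and tokenize a whole section.

    Returns one token list per sentence; token offsets are absolute within
    the section.
    """
    norm = normalize_characters(text)
    sentences: list[list[Token]] = []
    for idx, span in enumerate(split_sentences(norm, abbreviations)):
        toks = tokenize(norm[span.start:span.end], offset=span.start,
                        sentence_index=idx)
        if toks:
            sentences.append(toks)
    return sentences
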