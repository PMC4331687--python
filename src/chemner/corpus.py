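"""CHEMDNER-style corpus I/O.

Three tab-separated carrier formats:

* abstracts — ``doc_id<TAB>title<TAB>abstract``, one PubMed-style record per line;
* annotations — ``doc_id<TAB>section<TAB>start<TAB>end<TAB>text<TAB>class``,
  character offsets 0-based and end-exclusive, counted separately for the
  title (section ``T``) and the abstract (section ``A``);
* predictions — ``doc_id<TAB>section:start:end<TAB>rank<TAB>confidence``.

Offsets are over Unicode code points.  A mention's ``text`` must equal the
section substring at ``[start, end)``; :func:`read_annotations` enforces the
cheap half of that invariant (``end - start == len(text)``) per record, and
:func:`lint_annotations` checks the full substring match when the abstracts
are at hand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

CEM_CLASSES = frozenset({
    "SYSTEMATIC", "IDENTIFIER", "FORMULA", "TRIVIAL",
    "ABBREVIATION", "FAMILY", "MULTIPLE", "NO CLASS",
})


class CorpusParseError(ValueError):
    """A line of a corpus file does not match the carrier format."""


class MentionValidationError(ValueError):
    """A mention record violates a span invariant."""


@dataclass(frozen=True)
class Document:
    """One PubMed-style record with two independent offset spaces."""

    doc_id: str
    title: str
    abstract: str

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")

    def section_text(self, section: str) -> str:
        if section == "T":
            return self.title
        if section == "A":
            return self.abstract
        raise ValueError(f"unknown section {section!r} (expected 'T' or 'A')")


@dataclass(frozen=True, order=True)
class Mention:
    """A chemical entity mention span within one section of one document."""

    doc_id: str
    section: str
    start: int
    end: int
    text: str = field(compare=False)
    cem_class: str | None = field(default=None, compare=False)
    confidence: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.section not in ("T", "A"):
            raise ValueError(f"section must be 'T' or 'A', got {self.section!r}")
        if not (0 <= self.start < self.end):
            raise MentionValidationError(
                f"invalid span [{self.start}, {self.end}) for {self.doc_id}"
            )
        if self.end - self.start != len(self.text):
            raise MentionValidationError(
                f"span length {self.end - self.start} != text length "
                f"{len(self.text)} for {self.doc_id} {self.section} "
                f"{self.start}:{self.end} {self.text!r}"
            )
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")

    @property
    def key(self) -> tuple[str, str, int, int]:
        """Identity used for exact-span matching."""
        return (self.doc_id, self.section, self.start, self.end)


def read_abstracts(path: str | Path) -> list[Document]:
    """Read a 3-column abstracts file; one :class:`Document` per line."""
    docs: list[Document] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise CorpusParseError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            docs.append(Document(fields[0], fields[1], fields[2]))
    return docs


def write_abstracts(docs: Iterable[Document], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in docs:
            fh.write(f"{d.doc_id}\t{d.title}\t{d.abstract}\n")


def read_annotations(path: str | Path, drop_invalid: bool = False) -> list[Mention]:
    """Read a 6-column gold-annotation file.

    Each record is validated (``end - start == len(text)``, non-empty span).
    With ``drop_invalid`` offending records are discarded with a warning
    instead of raising.
    """
    mentions: list[Mention] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise CorpusParseError(
                    f"{path}:{lineno}: expected 6 tab-separated fields, "
                    f"got {len(fields)}"
                )
            doc_id, section, start_s, end_s, text, cem_class = fields
            try:
                mention = Mention(
                    doc_id=doc_id, section=section,
                    start=int(start_s), end=int(end_s),
                    text=text, cem_class=cem_class or None,
                )
            except (ValueError, MentionValidationError) as exc:
                if drop_invalid:
                    warnings.warn(f"{path}:{lineno}: dropping invalid record: {exc}")
                    continue
                raise MentionValidationError(f"{path}:{lineno}: {exc}") from exc
            mentions.append(mention)
    return mentions


def write_annotations(mentions: Iterable[Mention], path: str | Path) -> None:
    """Write mentions in the 6-column gold format (round-trips with
    :func:`read_annotations`)."""
    with open(path, "w", encoding="utf-8") as fh:
        for m in mentions:
            fh.write(
                f"{m.doc_id}\t{m.section}\t{m.start}\t{m.end}\t{m.text}\t"
                f"{m.cem_class or ''}\n"
            )


def lint_annotations(
    mentions: Sequence[Mention], documents: Sequence[Document]
) -> list[str]:
    """Report mentions whose text does not match the document substring.

    Returns human-readable issue strings; does not modify anything.  Typical
    findings are off-by-one spans in hand-curated gold files.
    """
    by_id = {d.doc_id: d for d in documents}
    issues: list[str] = []
    for m in mentions:
        doc = by_id.get(m.doc_id)
        if doc is None:
            issues.append(f"{m.doc_id}: no such document")
            continue
        section = doc.section_text(m.section)
        if m.end > len(section):
            issues.append(
                f"{m.doc_id} {m.section} {m.start}:{m.end}: span exceeds "
                f"section length {len(section)}"
            )
        elif section[m.start:m.end] != m.text:
            issues.append(
                f"{m.doc_id} {m.section} {m.start}:{m.end}: text "
                f"{m.text!r} != substring {section[m.start:m.end]!r}"
            )
    return issues


def resolve_nested(mentions: Sequence[Mention]) -> list[Mention]:
    """Drop mentions strictly contained in a wider mention of the same
    document section, keeping the larger span.

    A linear-chain tagger cannot emit nested spans, so nested gold pairs are
    reduced to their outermost member before training.  Partial (non-nested)
    overlaps are both kept.  Idempotent; order of survivors preserved.
    """
    keep: list[Mention] = []
    for m in mentions:
        contained = any(
            o.doc_id == m.doc_id and o.section == m.section
            and o.start <= m.start and m.end <= o.end
            and (o.start, o.end) != (m.start, m.end)
            for o in mentions
        )
        if not contained:
            keep.append(m)
    return keep


def rank_mentions(mentions: Sequence[Mention]) -> list[tuple[Mention, int]]:
    """Per-document 1-based ranks by descending confidence.

    Ties are broken by (section, start, end) so output is deterministic.
    """
    for m in mentions:
        if m.confidence is None:
            raise ValueError(f"mention {m.key} has no confidence")
    ranked: list[tuple[Mention, int]] = []
    by_doc: dict[str, list[Mention]] = {}
    for m in mentions:
        by_doc.setdefault(m.doc_id, []).append(m)
    for doc_id in sorted(by_doc):
        ordered = sorted(
            by_doc[doc_id],
            key=lambda m: (-m.confidence, m.section, m.start, m.end),
        )
        ranked.extend((m, rank) for rank, m in enumerate(ordered, start=1))
    return ranked


def write_predictions(mentions: Sequence[Mention], path: str | Path) -> None:
    """Write the 4-column official-format prediction file.

    Columns: doc_id, ``section:start:end``, per-document rank (1-based, by
    descending confidence), confidence printed with 6 decimals.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for m, rank in rank_mentions(mentions):
            fh.write(
                f"{m.doc_id}\t{m.section}:{m.start}:{m.end}\t{rank}\t"
                f"{m.confidence:.6f}\n"
            )


def read_predictions(path: str | Path) -> list[Mention]:
    """Read a 4-column prediction file back into offset-only mentions.

    The mention ``text`` is not stored in the prediction format, so the
    returned mentions carry a placeholder of the correct length.
    """
    mentions: list[Mention] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise CorpusParseError(
                    f"{path}:{lineno}: expected 4 tab-separated fields, "
                    f"got {len(fields)}"
                )
            doc_id, locator, _rank, conf = fields
            section, start_s, end_s = locator.split(":")
            start, end = int(start_s), int(end_s)
            mentions.append(
                Mention(doc_id, section, start, end, "\x00" * (end - start),
                        confidence=float(conf))
            )
    return mentions
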