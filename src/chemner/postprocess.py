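"""Rule-based post-processing and confidence scoring.

Three steps follow the CRF decoder:

1. false-positive removal — mentions whose text matches a shipped (and
   user-extensible) pattern, e.g. citation fragments like ``25(3), 186-193``
   or enumerations like ``1-D, 2-D``, are dropped;
2. span adjustment — when a mention contains an unbalanced marker pair and
   the adjacent text supplies the missing half, the span absorbs it, e.g.
   ``[4Fe-4S](2+`` followed by ``)`` becomes ``[4Fe-4S](2+)``.  The 14 rules
   are encoded as data (marker pair, direction, shift) so the table can be
   audited line by line; they are applied in id order, to a fixpoint;
3. confidence scoring — a mention's score is the mean forward–backward
   marginal of its tokens' decoded labels,

       score(CEM) = (1/|CEM|) Σ_t CondProb(t),

   which is then used to rank predictions per document.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus import Mention, rank_mentions


@dataclass(frozen=True)
class AdjustmentRule:
    """One marker-balancing rule.

    ``extend_end`` rules fire when the opening marker outnumbers the closing
    one by exactly one inside the mention and the text immediately right of
    the mention is the closing marker; the end offset then grows by
    ``len(close_marker)``.  ``extend_start`` rules are the mirror image.
    """

    id: int
    open_marker: str
    close_marker: str
    direction: str  # "extend_end" | "extend_start"

    @property
    def shift(self) -> int:
        return (len(self.close_marker) if self.direction == "extend_end"
                else len(self.open_marker))


#: The 14 shipped rules: three bracket pairs and four markup tag pairs,
#: each with an end-extending and a start-extending variant.
ADJUSTMENT_RULES: tuple[AdjustmentRule, ...] = tuple(
    AdjustmentRule(i + 1, o, c, d)
    for i, (o, c, d) in enumerate([
        ("(", ")", "extend_end"),
        ("(", ")", "extend_start"),
        ("[", "]", "extend_end"),
        ("[", "]", "extend_start"),
        ("{", "}", "extend_end"),
        ("{", "}", "extend_start"),
        ("<sc>", "</sc>", "extend_end"),
        ("<sc>", "</sc>", "extend_start"),
        ("<i>", "</i>", "extend_end"),
        ("<i>", "</i>", "extend_start"),
        ("<sup>", "</sup>", "extend_end"),
        ("<sup>", "</sup>", "extend_start"),
        ("<sub>", "</sub>", "extend_end"),
        ("<sub>", "</sub>", "extend_start"),
    ])
)


def load_removal_patterns(path: str | Path | None = None) -> list[re.Pattern]:
    """Load anchored removal regexes (one per line, ``#`` comments)."""
    if path is None:
        text = resources.files("chemner.data").joinpath(
            "removal_patterns.txt").read_text("utf-8")
    else:
        text = Path(path).read_text("utf-8")
    patterns = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            patterns.append(re.compile(line))
    return patterns


_DEFAULT_PATTERNS = load_removal_patterns()


def remove_false_positives(
    mentions: Sequence[Mention],
    patterns: Sequence[re.Pattern] | None = None,
) -> list[Mention]:
    """Drop mentions whose full text matches any removal pattern."""
    pats = _DEFAULT_PATTERNS if patterns is None else patterns
    return [m for m in mentions
            if not any(p.fullmatch(m.text) for p in pats)]


def _count(text: str, marker: str) -> int:
    return text.count(marker)


def adjust_spans(mention: Mention, section_text: str,
                 max_rounds: int = 8) -> Mention:
    """Apply the marker-balancing rules in id order until a fixpoint.

    The mention text is re-extracted from the section after every move, so
    the span/text invariant is maintained throughout.  A move that would
    leave the section bounds is skipped with a warning.
    """
    start, end = mention.start, mention.end
    for _ in range(max_rounds):
        moved = False
        for rule in ADJUSTMENT_RULES:
            text = section_text[start:end]
            n_open = _count(text, rule.open_marker)
            n_close = _count(text, rule.close_marker)
            if rule.direction == "extend_end":
                marker = rule.close_marker
                if (n_open == n_close + 1
                        and section_text[end:end + len(marker)] == marker):
                    if end + len(marker) > len(section_text):
                        warnings.warn(f"rule {rule.id}: span exceeds section")
                        continue
                    end += len(marker)
                    moved = True
            else:
                marker = rule.open_marker
                if (n_open == n_close - 1
                        and start >= len(marker)
                        and section_text[start - len(marker):start] == marker):
                    start -= len(marker)
                    moved = True
        if not moved:
            break
    return replace(mention, start=start, end=end,
                   text=section_text[start:end])


def confidence_score(label_marginals: Sequence[float]) -> float:
    """Mean per-token conditional probability of a mention's decoded labels."""
    if len(label_marginals) == 0:
        raise ValueError("mention has no tokens")
    return float(np.mean(np.asarray(label_marginals, dtype=float)))


def finalize(mentions: Sequence[Mention]) -> list[tuple[Mention, int]]:
    """Rank scored mentions per document for official-format output.

    Descending confidence, ties by (section, start, end).  Raises if any
    mention lacks a confidence or carries one outside [0, 1] (the Mention
    constructor enforces the range; absence is checked here).
    """
    return rank_mentions(mentions)
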