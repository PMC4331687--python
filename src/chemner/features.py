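"""Feature extraction for the CRF tagger.

Five feature families, each namespaced in the emitted map:

* ``lin:``   — surface uni/bi-grams and Porter-stemmed uni/bi/tri-grams in a
  ±window around the position;
* ``chr:``   — character statistics (digit/upper/lower/total counts) and
  presence flags for special characters, Greek letters, Roman numerals,
  amino-acid codes and chemical element symbols;
* ``case:``  — case-pattern abstractions (A/a/0 substitution, run-collapsed,
  and fully generic);
* ``brown:`` — bit-string path prefixes from a Brown clustering model;
* contextual — the label bigram; realized structurally as the CRF's
  transition weights rather than as an observation feature.

All extractors are pure functions of the sentence and configuration; no
feature ever looks at gold labels.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

from .brown import UNK, BrownModel, cluster_prefix
from .preprocess import SPECIAL_CHARACTERS, Token, _is_greek
from .stem import porter_stem

BOS = "<S>"
EOS = "</S>"

#: The 118 IUPAC element symbols.
CHEMICAL_ELEMENTS = frozenset((
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co "
    "Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb "
    "Te I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re "
    "Os Ir Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es "
    "Fm Md No Lr Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og"
).split())

#: Three-letter amino-acid codes (matched case-insensitively).
AMINO_ACIDS = frozenset((
    "Ala Arg Asn Asp Cys Gln Glu Gly His Ile Leu Lys Met Phe Pro Ser Thr "
    "Trp Tyr Val"
).split())

_ROMAN = re.compile(r"^[IVXLCDM]+$")
_ELEMENT_PREFIX = re.compile(r"^([A-Z][a-z]?)")


def linguistic_features(tokens: Sequence[str], position: int,
                        window: int = 2) -> dict[str, str]:
    """Surface uni/bi-grams and stemmed uni/bi/tri-grams around ``position``.

    Out-of-range slots use the boundary symbols ``<S>``/``</S>``.
    """

    def tok(i: int) -> str:
        if i < 0:
            return BOS
        if i >= len(tokens):
            return EOS
        return tokens[i]

    def stem(i: int) -> str:
        if i < 0:
            return BOS
        if i >= len(tokens):
            return EOS
        return porter_stem(tokens[i])

    feats: dict[str, str] = {}
    for off in range(-window, window + 1):
        feats[f"lin:uni[{off}]"] = tok(position + off)
        feats[f"lin:stem_uni[{off}]"] = stem(position + off)
    for off in range(-window, window):
        feats[f"lin:bi[{off}]"] = f"{tok(position + off)}|{tok(position + off + 1)}"
        feats[f"lin:stem_bi[{off}]"] = (
            f"{stem(position + off)}|{stem(position + off + 1)}"
        )
    for off in range(-window, window - 1):
        feats[f"lin:stem_tri[{off}]"] = (
            f"{stem(position + off)}|{stem(position + off + 1)}"
            f"|{stem(position + off + 2)}"
        )
    return feats


def _has_chemical_element(token: str) -> bool:
    if token in CHEMICAL_ELEMENTS:
        return True
    m = _ELEMENT_PREFIX.match(token)
    return bool(m and m.group(1) in CHEMICAL_ELEMENTS)


def character_features(token: str) -> dict[str, object]:
    """Character statistics and chemistry-flavoured presence flags."""
    return {
        "chr:digits": sum(c.isdigit() for c in token),
        "chr:upper": sum(c.isupper() for c in token),
        "chr:lower": sum(c.islower() for c in token),
        "chr:total": len(token),
        "chr:has_special": any(c in SPECIAL_CHARACTERS for c in token),
        "chr:has_greek": any(_is_greek(c) for c in token),
        "chr:has_roman": bool(_ROMAN.match(token)),
        "chr:has_amino_acid": token.capitalize() in {a.capitalize()
                                                     for a in AMINO_ACIDS},
        "chr:has_chem_element": _has_chemical_element(token),
    }


def case_pattern(token: str) -> str:
    """Per-character substitution: upper→A, lower→a, digit→0, rest verbatim."""
    out = []
    for c in token:
        if c.isdigit():
            out.append("0")
        elif c.isupper():
            out.append("A")
        elif c.islower():
            out.append("a")
        else:
            out.append(c)
    return "".join(out)


def _collapse_runs(pattern: str) -> str:
    out = []
    for c in pattern:
        if not out or out[-1] != c:
            out.append(c)
    return "".join(out)


def case_pattern_features(token: str) -> dict[str, str]:
    """Full, run-collapsed, and fully generic (a/0) case patterns."""
    full = case_pattern(token)
    collapsed = _collapse_runs(full)
    generic = _collapse_runs(
        "".join("a" if c in "Aa" else c for c in full)
    )
    return {
        "case:full": full,
        "case:collapsed": collapsed,
        "case:generic": generic,
    }


def brown_features(model: BrownModel, token: str,
                   prefix_lengths: Sequence[int]) -> dict[str, str]:
    """Path-prefix features; out-of-vocabulary tokens map to ``UNK``."""
    feats: dict[str, str] = {}
    for n in prefix_lengths:
        feats[f"brown:p{n}"] = cluster_prefix(model, token, n)
    if prefix_lengths:
        path = model.path_of(token)
        feats["brown:path"] = path if path is not None else UNK
    return feats


@dataclass(frozen=True)
class FeatureConfig:
    """Which families are active and how they are parameterized.

    The shipped presets mirror the five post-challenge feature combinations:
    run 1 uses the four supervised families only; runs 2–5 add Brown-cluster
    word representations trained with 500/1000/1500/2000 clusters.
    """

    linguistic: bool = True
    character: bool = True
    case: bool = True
    contextual: bool = True
    brown: bool = False
    window: int = 2
    prefix_lengths: tuple[int, ...] = (4, 6, 10, 20)
    n_clusters: int = 1000

    @classmethod
    def preset(cls, name: str) -> "FeatureConfig":
        presets = {
            "run1": cls(brown=False),
            "run2": cls(brown=True, n_clusters=500),
            "run3": cls(brown=True, n_clusters=1000),
            "run4": cls(brown=True, n_clusters=1500),
            "run5": cls(brown=True, n_clusters=2000),
        }
        try:
            return presets[name]
        except KeyError:
            raise ValueError(
                f"unknown preset {name!r}; expected one of {sorted(presets)}"
            ) from None


def assemble_features(
    tokens: Sequence[Token] | Sequence[str],
    config: FeatureConfig,
    model: BrownModel | None = None,
) -> list[dict[str, object]]:
    """Per-position union of the active feature families for one sentence."""
    if config.brown and model is None:
        raise ValueError("brown features requested but no BrownModel given")
    surfaces = [t.surface if isinstance(t, Token) else t for t in tokens]
    maps: list[dict[str, object]] = []
    for pos, surface in enumerate(surfaces):
        feats: dict[str, object] = {}
        if config.linguistic:
            feats.update(linguistic_features(surfaces, pos, config.window))
        if config.character:
            feats.update(character_features(surface))
        if config.case:
            feats.update(case_pattern_features(surface))
        if config.brown:
            feats.update(brown_features(model, surface, config.prefix_lengths))
        maps.append(feats)
    return maps
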