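"""Surface rewrite rules applied between raw concatenation and normalization.

The grammar's output is not plain concatenation: a handful of euphonic and
clinical-usage rules fire on the token stream before joining.  Rules are
token-level so they can still see grammatical categories; fusion would erase
those boundaries.  Fixed stage order: cell-line leukemia rewrite, the
hypo/deficiency fusion swap, slit/cavity reordering, euphonic a/an, then
join and whitespace normalization.  The pipeline is idempotent.
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass, replace
from importlib import resources
from typing import Sequence

#: ASCII vowels only; Greek letters such as 'β' do not trigger the a/an rule.
VOWELS = "aeiou"


@dataclass(frozen=True)
class Token:
    """A surface plus enough type information for the rewrite rules."""

    surface: str
    join: str = "SPACE"            # SPACE | FUSE_PREV | FUSE_NEXT
    category: str | None = None
    subcategory: str = ""
    flags: frozenset[str] = frozenset()


def _load_config() -> dict:
    with resources.files("uds.data").joinpath("rewrite_config.json").open(
        "r", encoding="utf-8"
    ) as fh:
        return json.load(fh)


_CONFIG = _load_config()

#: cell (line) names whose neoplasia renders as '<cell> leukemia'
HEMATOPOIETIC_CELLS = frozenset(_CONFIG["hematopoietic_cells"])


def cellline_neoplasia(tokens: Sequence[Token],
                       cells: frozenset[str] = HEMATOPOIETIC_CELLS) -> list[Token]:
    """Rewrite <hematopoietic cell> + 'neo' + 'plasia' to '<cell> leukemia'.

    Clinical usage names these disorders leukemias; the rule is restricted to
    a configurable hematopoietic cell set, so 'thyroid neoplasia' is left
    untouched.
    """
    out: list[Token] = []
    i = 0
    while i < len(tokens):
        t = tokens[i]
        if (
            t.category == "BODYPART"
            and t.subcategory in ("C", "L")
            and t.surface in cells
            and i + 2 < len(tokens)
            and tokens[i + 1].category == "DIR"
            and tokens[i + 1].surface == "neo"
            and tokens[i + 2].surface == "plasia"
        ):
            out.append(t)
            out.append(Token("leukemia", "SPACE", "MORPH", "C"))
            i += 3
            continue
        out.append(t)
        i += 1
    return out


def fusion_swap(tokens: Sequence[Token]) -> list[Token]:
    """Swap 'hypo' with 'deficiency' before a FUSION_SWAP-flagged term.

    'hypo' + 'immuno' renders as 'immunodeficiency'; any other direction
    prefix concatenates plainly ('hyperimmuno').
    """
    out: list[Token] = []
    i = 0
    while i < len(tokens):
        t = tokens[i]
        if (
            t.category == "DIR"
            and t.surface == "hypo"
            and i + 1 < len(tokens)
            and "FUSION_SWAP" in tokens[i + 1].flags
        ):
            nxt = tokens[i + 1]
            out.append(Token(nxt.surface + "deficiency", nxt.join,
                             nxt.category, nxt.subcategory))
            i += 2
            continue
        out.append(t)
        i += 1
    return out


def reorder_slit(tokens: Sequence[Token]) -> list[Token]:
    """Move a slit/cavity morphology term in front of its body part, fused.

    Raw formula order gives 'thorax hydro'; clinical names are of the form
    'hydrothorax', so the pair is swapped and the morphology term fuses
    forwards.
    """
    out: list[Token] = []
    i = 0
    while i < len(tokens):
        t = tokens[i]
        if (
            t.category == "BODYPART"
            and t.subcategory == "S"
            and i + 1 < len(tokens)
            and tokens[i + 1].category == "MORPH"
            and tokens[i + 1].subcategory == "S"
        ):
            morph = tokens[i + 1]
            out.append(replace(morph, join="FUSE_NEXT"))
            out.append(t)
            i += 2
            continue
        out.append(t)
        i += 1
    return out


def euphonic_an(tokens: Sequence[Token]) -> list[Token]:
    """Replace the direction prefix 'a' with 'an' before a vowel-initial term."""
    out = list(tokens)
    for i, t in enumerate(out[:-1]):
        if (
            t.category == "DIR"
            and t.surface == "a"
            and out[i + 1].surface[:1].lower() in VOWELS
        ):
            out[i] = replace(t, surface="an")
    return out


def join_tokens(tokens: Sequence[Token]) -> str:
    """Render a token stream honoring the fusion/spacing convention.

    A junction fuses when the left token carries FUSE_NEXT or the right one
    FUSE_PREV; otherwise the tokens are separated by a single space.
    """
    parts: list[str] = []
    prev: Token | None = None
    for t in tokens:
        if not t.surface:
            continue
        if prev is not None:
            fused = prev.join == "FUSE_NEXT" or t.join == "FUSE_PREV"
            if not fused:
                parts.append(" ")
        parts.append(t.surface)
        prev = t
    return "".join(parts)


_WS = re.compile(r"\s+")


def normalize(text: str) -> str:
    """NFC-normalize, collapse runs of (any) whitespace, trim; idempotent."""
    return _WS.sub(" ", unicodedata.normalize("NFC", text)).strip()


def rewrite_tokens(tokens: Sequence[Token]) -> list[Token]:
    """Apply all token-level rules in their fixed stage order."""
    return euphonic_an(reorder_slit(fusion_swap(cellline_neoplasia(tokens))))


def render(tokens: Sequence[Token]) -> str:
    """Full pipeline: token rewrites, join, whitespace normalization."""
    return normalize(join_tokens(rewrite_tokens(tokens)))
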