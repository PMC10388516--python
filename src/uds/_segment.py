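"""Dynamic-programming morpheme segmentation over a lexicon.

Splits a normalized diagnosis string into lexicon surfaces, allowing
multiword surfaces ('Staphylococcus aureus'), fused morphemes
('cystitis' -> 'cyst'+'itis', 'myelodysplasia' -> 'myelo'+'dys'+'plasia')
and unknown whole words.  Returns all segmentations that maximize matched
characters and, among those, minimize token count.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .lexicon import Lexicon


@dataclass(frozen=True)
class Piece:
    """One segment of the input: a surface and its half-open char span."""

    surface: str
    start: int
    end: int
    known: bool = True


def _word_end(text: str, i: int) -> int:
    j = text.find(" ", i)
    return len(text) if j == -1 else j


def best_segmentations(
    text: str, lex: "Lexicon", cap: int = 32
) -> list[list[Piece]]:
    """All optimal segmentations of ``text``, up to ``cap`` alternatives.

    Optimality is lexicographic: most characters covered by known surfaces,
    then fewest tokens.  Unknown words (no surface matches anywhere inside
    them that extend to a valid continuation) are skipped whole.
    """
    n = len(text)
    if n == 0:
        return [[]]

    @lru_cache(maxsize=None)
    def options(i: int) -> list[tuple[Piece | None, int]]:
        """Transitions from position i: (piece or None for a space, next_pos)."""
        opts: list[tuple[Piece | None, int]] = []
        if i < n and text[i] == " ":
            return [(None, i + 1)]
        for entry_surface in {e.surface for e in lex.matches_at(text, i)}:
            opts.append((Piece(entry_surface, i, i + len(entry_surface)), i + len(entry_surface)))
        at_word_start = i == 0 or text[i - 1] == " "
        if at_word_start:
            we = _word_end(text, i)
            opts.append((Piece(text[i:we], i, we, known=False), we))
        return opts

    NEG = (-1, 0)

    @lru_cache(maxsize=None)
    def score(i: int) -> tuple[int, int]:
        """Best (covered_chars, -token_count) from i to the end."""
        if i >= n:
            return (0, 0)
        best = NEG
        for piece, nxt in options(i):
            tail = score(nxt)
            if tail == NEG:
                continue
            cov = tail[0] + (len(piece.surface) if piece and piece.known else 0)
            tok = tail[1] - (1 if piece else 0)
            cand = (cov, tok)
            if cand > best:
                best = cand
        return best

    if score(0) == NEG:  # pragma: no cover - unknown-skip always offers a path
        return []

    results: list[list[Piece]] = []

    def walk(i: int, acc: list[Piece]) -> None:
        if len(results) >= cap:
            return
        if i >= n:
            results.append(list(acc))
            return
        target = score(i)
        for piece, nxt in options(i):
            tail = score(nxt)
            if tail == NEG:
                continue
            cov = tail[0] + (len(piece.surface) if piece and piece.known else 0)
            tok = tail[1] - (1 if piece else 0)
            if (cov, tok) != target:
                continue
            if piece:
                acc.append(piece)
            walk(nxt, acc)
            if piece:
                acc.pop()

    walk(0, [])
    return results
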