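"""Parsing: invert generation by segmenting and categorizing a diagnosis.

Analysis divides a diagnosis into lexicon morphemes (undoing fusion);
parsing assigns each morpheme a category and checks that the category
sequence fits the single admissible component order

    Dur Seg Reg Site Prog e (disorder chain) S (pathogenesis) Deg

Only this order is derivable: of the six permutations of etiology,
disorder and pathogenesis exactly etiology-disorder-pathogenesis passes.
Unknown words never abort a parse; they surface as unknown spans so batch
validation can report per line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from . import rewrite
from ._segment import Piece, best_segmentations
from .lexicon import Lexicon, TermEntry
from .rewrite import Token as JoinToken

# component order template: index = stage
STAGES = (
    "dur", "seg", "reg", "site", "prog", "etiology",
    "disorder", "suffix", "pathogenesis", "degree",
)

_CAT_STAGE = {
    "TIME": 0, "SCOPE_SEG": 1, "SCOPE_REG": 2, "SCOPE_SITE": 3, "PROG": 4,
    "ETIOLOGY": 5, "DEG": 9,
}


@dataclass(frozen=True)
class Token:
    """An input segment with its character span and lexicon candidates."""

    surface: str
    start: int
    end: int
    candidates: tuple[TermEntry, ...] = ()

    @property
    def known(self) -> bool:
        return bool(self.candidates)


@dataclass
class DiagnosisComponents:
    """The ordered decomposition of one diagnosis.

    ``tokens`` holds every segment with the label chosen by the order
    template; the named fields are convenience views onto it.
    """

    dur: str = ""
    seg: str = ""
    reg: str = ""
    site: list[str] = field(default_factory=list)
    prog: str = ""
    etiology: str = ""
    disorder: list[str] = field(default_factory=list)
    suffix: str = ""
    pathogenesis: list[str] = field(default_factory=list)
    degree: str = ""
    kindhint: str = ""
    tokens: list[tuple[Token, TermEntry | None, int]] = field(default_factory=list)


@dataclass
class ParseResult:
    """Best decomposition plus alternatives and failure information."""

    best: DiagnosisComponents | None = None
    alternatives: list[DiagnosisComponents] = field(default_factory=list)
    unknown: list[tuple[int, int]] = field(default_factory=list)
    violations: list[str] = field(default_factory=list)
    ambiguous: bool = False


def segment(d: str, lex: Lexicon, cap: int = 32) -> list[list[Token]]:
    """All maximal-coverage segmentations of ``d`` into lexicon morphemes."""
    norm = rewrite.normalize(d)
    out: list[list[Token]] = []
    for pieces in best_segmentations(norm, lex, cap=cap):
        out.append(categorize(pieces, lex))
    return out


def categorize(pieces: Sequence[Piece], lex: Lexicon) -> list[Token]:
    """Attach every candidate (category, subcategory) label to each piece."""
    toks = []
    for p in pieces:
        cands = tuple(lex.lookup_surface(p.surface)) if p.known else ()
        toks.append(Token(p.surface, p.start, p.end, cands))
    return toks


def _transitions(entry: TermEntry, stage: int, sub: int,
                 postlink: bool) -> list[tuple[int, int, bool]]:
    """Possible (stage, substate, postlink) states after reading ``entry``."""
    cat = entry.category
    out: list[tuple[int, int, bool]] = []
    if cat in _CAT_STAGE:
        s = _CAT_STAGE[cat]
        if s > stage or (s == stage and cat in ("SCOPE_SITE", "ETIOLOGY")):
            out.append((s, 0, postlink if s >= 8 else False))
    elif cat == "DIR":
        if entry.has_flag("WORD") and stage <= 5:
            out.append((5, 0, False))
        if stage <= 6:
            out.append((6, 2, False))
        if stage <= 8:
            out.append((8, 0, postlink))
    elif cat == "SUBSTANCE":
        if stage <= 5:
            out.append((5, 0, False))
        if stage <= 6 and (stage < 6 or sub <= 2):
            out.append((6, 1 if sub <= 1 else sub, False))
        if stage <= 8:
            out.append((8, 0, postlink))
    elif cat == "REGULATOR":
        if stage <= 6 and (stage < 6 or sub <= 2):
            out.append((6, 1 if sub <= 1 else sub, False))
        if stage <= 8:
            out.append((8, 0, postlink))
    elif cat == "SUFFIX":
        if entry.has_flag("NUT"):
            if stage <= 5:
                out.append((5, 0, False))
        elif stage <= 7:
            out.append((7, 0, False))
    elif cat in ("BODYPART", "MORPH", "FUNC"):
        if stage <= 6:
            # a body part starts a new disorder part; outcomes extend one
            out.append((6, 0 if cat == "BODYPART" else 3, False))
        if stage == 8 and postlink:
            out.append((8, 0, True))
    elif cat in ("PATHOGENESIS", "LINK", "NEURAL"):
        if stage <= 8:
            out.append((8, 0, True))
    elif cat == "LOCALIZER":
        if stage <= 8:
            out.append((8, 0, postlink))
    return out


def _assign(tokens: Sequence[Token]) -> list[tuple[TermEntry | None, int]] | None:
    """Choose one label per token satisfying the order template, or None.

    A LINK connective may also reset the machine (a chained diagnosis:
    'diagnosis 1 causes diagnosis 2').  Unknown tokens are accepted at any
    stage.  Deterministic: candidates are tried in a fixed order.
    """
    n = len(tokens)
    dead: set[tuple[int, int, int, bool]] = set()

    def dfs(i: int, stage: int, sub: int, postlink: bool
            ) -> list[tuple[TermEntry | None, int]] | None:
        if i == n:
            return []
        key = (i, stage, sub, postlink)
        if key in dead:
            return None
        tok = tokens[i]
        if not tok.known:
            tail = dfs(i + 1, stage, sub, postlink)
            if tail is not None:
                return [(None, stage)] + tail
            dead.add(key)
            return None
        cands = sorted(
            tok.candidates,
            key=lambda e: (e.category, e.subcategory),
        )
        moves: list[tuple[TermEntry, tuple[int, int, bool]]] = []
        for entry in cands:
            for state in _transitions(entry, stage, sub, postlink):
                moves.append((entry, state))
            if entry.category == "LINK" and entry.surface in ("causes", "and"):
                moves.append((entry, (-1, 0, False)))  # reset: new sub-diagnosis
        moves.sort(
            key=lambda m: (99 if m[1][0] < 0 else m[1][0],
                           m[0].category, m[0].subcategory)
        )
        for entry, (s, su, pl) in moves:
            tail = dfs(i + 1, s, su, pl)
            if tail is not None:
                return [(entry, s if s >= 0 else 8)] + tail
        dead.add(key)
        return None

    return dfs(0, -1, 0, False)


def check_template(tokens: Sequence[Token]) -> list[str]:
    """Order violations for a categorized token sequence; [] iff valid.

    Valid means one label per token can be chosen so the category sequence
    follows the component order template.
    """
    if not tokens:
        return ["empty"]
    if _assign(tokens) is not None:
        return []
    # locate the longest assignable prefix for a useful message
    for k in range(len(tokens), 0, -1):
        if _assign(tokens[:k]) is not None:
            if k < len(tokens):
                return [
                    f"component {tokens[k].surface!r} out of order after "
                    f"{tokens[k - 1].surface!r}"
                ]
    return [f"component {tokens[0].surface!r} cannot start a diagnosis"]


def _components(tokens: Sequence[Token],
                assignment: Sequence[tuple[TermEntry | None, int]]
                ) -> DiagnosisComponents:
    c = DiagnosisComponents()
    first_reset_seen = False
    for tok, (entry, stage) in zip(tokens, assignment):
        c.tokens.append((tok, entry, stage))
        if first_reset_seen:
            continue
        if entry is not None and entry.category == "LINK" and entry.surface == "causes":
            first_reset_seen = True
            continue
        if stage == 0:
            c.dur = tok.surface
        elif stage == 1:
            c.seg = tok.surface
        elif stage == 2:
            c.reg = tok.surface
        elif stage == 3:
            c.site.append(tok.surface)
        elif stage == 4:
            c.prog = tok.surface
        elif stage == 5:
            c.etiology = (c.etiology + " " + tok.surface).strip()
        elif stage == 6:
            c.disorder.append(tok.surface)
        elif stage == 7:
            c.suffix = tok.surface
        elif stage == 8:
            c.pathogenesis.append(tok.surface)
        elif stage == 9:
            c.degree = tok.surface
    return c


def regenerate(c: DiagnosisComponents) -> str:
    """Re-emit the diagnosis from parsed components.

    Rejoins the labeled tokens with their lexicon join behaviour and runs
    the rewrite pipeline; for a violation-free parse this reproduces the
    normalized input.
    """
    join_toks = []
    for tok, entry, _stage in c.tokens:
        if entry is None:
            join_toks.append(JoinToken(tok.surface, "SPACE"))
        else:
            join_toks.append(
                JoinToken(entry.surface, entry.join, entry.category,
                          entry.subcategory, entry.flags)
            )
    return rewrite.render(join_toks)


def parse(d: str, lex: Lexicon, cap: int = 32) -> ParseResult:
    """Full parse: segmentation, categorization, order check, components."""
    norm = rewrite.normalize(d)
    if not norm:
        return ParseResult(violations=["empty"])
    seg_alternatives = segment(norm, lex, cap=cap)
    parsed: list[DiagnosisComponents] = []
    failed: list[list[Token]] = []
    for tokens in seg_alternatives:
        assignment = _assign(tokens)
        if assignment is None:
            failed.append(tokens)
            continue
        parsed.append(_components(tokens, assignment))
    if not parsed:
        tokens = failed[0] if failed else []
        res = ParseResult(violations=check_template(tokens))
        res.unknown = [(t.start, t.end) for t in tokens if not t.known]
        return res
    from .validate import classify  # local import avoids a module cycle

    for c in parsed:
        c.kindhint = classify(c)
    best = parsed[0]
    res = ParseResult(
        best=best,
        alternatives=parsed[1:],
        unknown=[(t.start, t.end) for t, _e, _s in best.tokens if not t.known],
        ambiguous=len(parsed) > 1,
    )
    return res
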