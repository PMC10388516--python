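"""Diagnosis generation from typed bindings.

A diagnosis is the concatenation, in one fixed order, of a time course,
anatomical scope (segment, region, site), prognosis, etiology, one or more
disorder parts, a suffix, a pathogenesis, and a degree:

    d := Dur Seg Reg Site Prog e o S p Deg

The disorder ``o`` is itself built per body-part level (parenchyma, tube,
slit/cavity, tissue, cell line, cell, organelle) as

    O_X^Y := N_X S_V K L Dir_X^Y Y_X^Z

with a morphology series followed by a function series, optionally linked
by 'causing' for compound cause/effect disorders.  Empty slots contribute
nothing; generation is a pure function of the binding and lexicon, so the
order in which slots were bound never matters.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from . import rewrite
from ._segment import best_segmentations
from .errors import (
    CategoryError,
    ChainError,
    EmptyDiagnosisError,
    InvalidDiagnosisError,
    TemplateError,
    UnknownSlotError,
)
from .lexicon import Lexicon, TermEntry
from .rewrite import Token

PART_KINDS = "PTSILCO"

PATHOGENESIS_TEMPLATES = (
    "plain", "localized", "metabolic", "spread",
    "metastasis", "embolism", "causal-target", "neural",
)

#: maximum recursion depth for relative site descriptions
MAX_SITE_DEPTH = 5

# slot -> (category, subcategory or None) for single-term slots
_SIMPLE_SLOTS: dict[str, tuple[str, str | None]] = {
    "S": ("SUFFIX", None),
    "S_V": ("SUFFIX", None),
    "Dur": ("TIME", None),
    "Seg": ("SCOPE_SEG", None),
    "Reg": ("SCOPE_REG", None),
    "Site": ("SCOPE_SITE", None),
    "Prog": ("PROG", None),
    "Deg": ("DEG", None),
    "Dir_E": ("DIR", None),
    "Dir_P": ("DIR", None),
    "K_Dir": ("DIR", None),
    "K_N": ("SUBSTANCE", None),
    "Dir_H": ("DIR", None),
    "N_B": ("SUBSTANCE", None),
    "N_H": ("REGULATOR", None),
    "L_H": ("LOCALIZER", None),
    "Eff": ("NEURAL", "EFF"),
    "Aff": ("NEURAL", "AFF"),
}

# free-composite slots checked by segmentation; value = categories the
# composite may draw on (at least one core category must occur)
_AGGREGATE_SLOTS: dict[str, tuple[frozenset[str], frozenset[str]]] = {
    "e": (
        frozenset({"ETIOLOGY"}),
        frozenset({"ETIOLOGY", "DIR", "SUBSTANCE", "SUFFIX"}),
    ),
    "o": (
        frozenset({"BODYPART", "MORPH", "FUNC"}),
        frozenset({"BODYPART", "MORPH", "FUNC", "DIR", "SUFFIX",
                   "SUBSTANCE", "REGULATOR", "PATHOGENESIS"}),
    ),
    "p": (
        frozenset({"PATHOGENESIS", "LOCALIZER", "SUFFIX", "ETIOLOGY",
                   "BODYPART", "FUNC", "MORPH"}),
        frozenset({"PATHOGENESIS", "LOCALIZER", "DIR", "SUBSTANCE",
                   "REGULATOR", "LINK", "SUFFIX", "ETIOLOGY", "NEURAL",
                   "BODYPART", "MORPH", "FUNC", "SCOPE_REG", "SCOPE_SITE"}),
    ),
    "target": (
        frozenset({"BODYPART", "MORPH", "FUNC", "PATHOGENESIS"}),
        frozenset({"BODYPART", "MORPH", "FUNC", "DIR", "PATHOGENESIS",
                   "SCOPE_REG", "SCOPE_SITE", "SUFFIX"}),
    ),
}

_PART_SLOT = re.compile(
    r"^(?P<field>N|M|F|Dir|SV)_(?P<kind>[PTSILCO])(?:_(?P<z>[A-Z]))?$"
)


@dataclass(frozen=True)
class DisorderPart:
    """Slots of one body-part disorder O_X^Y (morphology and/or function)."""

    kind: str                 # P, T, S, I, L, C or O
    n: str = ""               # body-part name N_X
    suffix: str = ""          # per-part suffix S_V
    k_dir: str = ""           # metabolite direction (K)
    k_sub: str = ""           # metabolite name (K)
    l_dir: str = ""           # regulator direction (L)
    l_sub: str = ""           # regulator name (L)
    dir_m: str = ""           # Dir_X^M
    dir_f: str = ""           # Dir_X^F
    outcome_m: str = ""       # morphology term M_X
    outcome_f: str = ""       # function term F_X^Z
    z: str = ""               # function type code

    def is_empty(self) -> bool:
        return not any(
            (self.n, self.suffix, self.k_dir, self.k_sub, self.l_dir,
             self.l_sub, self.dir_m, self.dir_f, self.outcome_m, self.outcome_f)
        )


@dataclass(frozen=True)
class Binding:
    """An assignment of lexicon surfaces to grammar variables.

    Immutable; :func:`bind` returns an updated copy, so any bind order
    produces the same binding and hence the same diagnosis.
    """

    slots: Mapping[str, str] = field(default_factory=dict)
    parts: Mapping[str, DisorderPart] = field(default_factory=dict)
    sites: tuple[str, ...] = ()
    causal: bool = False

    def get(self, slot: str, default: str = "") -> str:
        return self.slots.get(slot, default)

    def part(self, kind: str) -> DisorderPart:
        return self.parts.get(kind, DisorderPart(kind))

    def ordered_parts(self) -> list[DisorderPart]:
        return [self.parts[k] for k in PART_KINDS if k in self.parts]

    def with_causal(self, causal: bool = True) -> "Binding":
        return replace(self, causal=causal)


@dataclass(frozen=True)
class DiagnosisString:
    """A generated diagnosis; whitespace-normalized surface text."""

    text: str

    def __str__(self) -> str:
        return self.text


def concat(a: str, b: str) -> str:
    """String concatenation, the grammar's only combining operation.

    No implicit space is inserted ('abc' & 'abc' -> 'abcabc'); spacing must
    be part of the operands or of the join convention.  Non-commutative.
    """
    return a + b


def join_terms(parts: Sequence[tuple[str, str]]) -> str:
    """Join (surface, join) pairs per the fusion/spacing convention."""
    tokens = [Token(surface, join) for surface, join in parts if surface]
    if not tokens:
        raise EmptyDiagnosisError("all parts empty")
    return rewrite.normalize(rewrite.join_tokens(tokens))


def apply_dir_scope(direction: str, parts: Sequence[str]) -> list[tuple[str, str]]:
    """Distribute a direction prefix over several outcome terms.

    A parenthesized direction ranges over all its arguments:
    Dir(M F) = Dir&M Dir&F.
    """
    out: list[tuple[str, str]] = []
    for p in parts:
        if not p:
            continue
        if direction:
            out.append((direction, "FUSE_NEXT"))
        out.append((p, "SPACE"))
    return out


def _entry_for(lex: Lexicon, surface: str, category: str,
               subcategory: str | None = None) -> TermEntry | None:
    for e in lex.lookup_surface(surface):
        if e.category == category and (subcategory is None or e.subcategory == subcategory):
            return e
    return None


def _token(lex: Lexicon, surface: str, category: str | None = None,
           subcategory: str | None = None) -> Token:
    """Token for a surface, taking join/type from the lexicon when known."""
    entry = None
    if category is not None:
        entry = _entry_for(lex, surface, category, subcategory)
    if entry is None:
        entries = lex.lookup_surface(surface)
        entry = entries[0] if entries else None
    if entry is None:
        return Token(surface, "SPACE")
    return Token(entry.surface, entry.join, entry.category,
                 entry.subcategory, entry.flags)


def _check_simple(lex: Lexicon, slot: str, surface: str,
                  category: str, subcategory: str | None) -> None:
    if _entry_for(lex, surface, category, subcategory) is None:
        raise CategoryError(
            f"{surface!r} is not a {category}"
            f"{'' if subcategory is None else '/' + subcategory} term"
            f" (slot {slot})"
        )


def _check_aggregate(lex: Lexicon, slot: str, surface: str) -> None:
    core, allowed = _AGGREGATE_SLOTS[slot]
    segs = best_segmentations(surface, lex, cap=8)
    ok_reasons: list[str] = []
    for seg in segs:
        cats_per_piece = []
        for piece in seg:
            if not piece.known:
                cats_per_piece = None
                break
            cats = {e.category for e in lex.lookup_surface(piece.surface)}
            cats_per_piece.append(cats)
        if cats_per_piece is None:
            continue
        if any(not (cats & allowed) for cats in cats_per_piece):
            ok_reasons.append("category outside slot")
            continue
        if any(cats & core for cats in cats_per_piece):
            return
        ok_reasons.append("no core category")
    raise CategoryError(
        f"{surface!r} cannot instantiate slot {slot!r}: "
        + (ok_reasons[0] if ok_reasons else "contains unknown terms")
    )


def bind(b: Binding, var: str, surface: str, lex: Lexicon) -> Binding:
    """Return a new binding with ``var`` set to ``surface``, type-checked.

    The variables restrict the types of terms assignable to them: a term
    must exist in the lexicon under the category its slot requires
    ('Staphylococcus aureus' is an etiological agent, not a tissue, so it
    cannot be bound to the disorder).
    """
    surface = rewrite.normalize(surface)
    if var == "p_template":
        if surface and surface not in PATHOGENESIS_TEMPLATES:
            raise CategoryError(f"unknown pathogenesis template {surface!r}")
        return replace(b, slots={**b.slots, var: surface})
    if var == "Site":
        if surface:
            _check_simple(lex, var, surface, "SCOPE_SITE", None)
            if len(b.sites) >= MAX_SITE_DEPTH:
                raise CategoryError(f"site recursion deeper than {MAX_SITE_DEPTH}")
            return replace(b, sites=b.sites + (surface,))
        return b
    if var in _SIMPLE_SLOTS:
        if surface:
            cat, sub = _SIMPLE_SLOTS[var]
            _check_simple(lex, var, surface, cat, sub)
        return replace(b, slots={**b.slots, var: surface})
    if var in _AGGREGATE_SLOTS:
        if surface:
            _check_aggregate(lex, var, surface)
        return replace(b, slots={**b.slots, var: surface})
    m = _PART_SLOT.match(var)
    if m:
        kind = m.group("kind")
        fieldname = m.group("field")
        z = m.group("z") or ""
        part = b.part(kind)
        if fieldname == "N":
            if surface:
                _check_simple(lex, var, surface, "BODYPART", kind)
            part = replace(part, n=surface)
        elif fieldname == "M":
            if surface:
                _check_simple(lex, var, surface, "MORPH", None)
            part = replace(part, outcome_m=surface)
        elif fieldname == "F":
            if surface:
                _check_simple(lex, var, surface, "FUNC", z or None)
            part = replace(part, outcome_f=surface, z=z)
        elif fieldname == "SV":
            if surface:
                _check_simple(lex, var, surface, "SUFFIX", None)
            part = replace(part, suffix=surface)
        else:  # Dir
            if surface:
                _check_simple(lex, var, surface, "DIR", None)
            if z == "F":
                part = replace(part, dir_f=surface)
            elif z == "M":
                part = replace(part, dir_m=surface)
            else:
                part = replace(part, dir_m=surface, dir_f=surface)
        return replace(b, parts={**b.parts, kind: part})
    raise UnknownSlotError(f"unrecognized variable {var!r}")


def bind_all(b: Binding, assignments: Mapping[str, object], lex: Lexicon) -> Binding:
    """Bind several slots; list values repeat the bind (site recursion)."""
    for var, value in assignments.items():
        if var == "causal":
            b = b.with_causal(bool(value))
        elif isinstance(value, (list, tuple)):
            for v in value:
                b = bind(b, var, str(v), lex)
        else:
            b = bind(b, var, str(value), lex)
    return b


def _part_tokens(b: Binding, part: DisorderPart, lex: Lexicon,
                 series: str) -> list[Token]:
    """Token stream of O_X^Y for one series (Y = 'M' or 'F').

    Order N_X S_V K L Dir Y: body part, per-part suffix, metabolite
    (direction + name), regulator name, direction, outcome.  The regulator's
    own direction merges into the direction slot when the part has none.
    """
    outcome = part.outcome_m if series == "M" else part.outcome_f
    direction = part.dir_m if series == "M" else part.dir_f
    if series == "F" and not outcome:
        return []
    if series == "M" and not outcome and (
        part.outcome_f or not (part.n or part.suffix)
    ):
        # bare body part (no outcome at all) renders once, in the morphology
        # series; a function-only part renders only in the function series
        return []
    toks: list[Token] = []
    if part.n:
        toks.append(_token(lex, part.n, "BODYPART", part.kind))
    if part.suffix:
        toks.append(_token(lex, part.suffix, "SUFFIX"))
    if part.k_sub:
        if part.k_dir:
            toks.append(_token(lex, part.k_dir, "DIR"))
        toks.append(_token(lex, part.k_sub, "SUBSTANCE"))
    if part.l_sub:
        toks.append(_token(lex, part.l_sub, "REGULATOR"))
    if not direction and part.l_sub and part.l_dir:
        direction = part.l_dir
    if direction:
        toks.append(_token(lex, direction, "DIR"))
    if outcome:
        cat = "MORPH" if series == "M" else "FUNC"
        toks.append(_token(lex, outcome, cat, part.z or None))
    return toks


def _attach_regulator(b: Binding, parts: list[DisorderPart]) -> list[DisorderPart]:
    """Route the global metabolite/regulator slots into the first part."""
    if not parts:
        return parts
    first = parts[0]
    first = replace(
        first,
        k_dir=first.k_dir or b.get("K_Dir"),
        k_sub=first.k_sub or b.get("K_N"),
        l_dir=first.l_dir or b.get("Dir_H"),
        l_sub=first.l_sub or b.get("N_H"),
    )
    return [first] + parts[1:]


def _disorder_tokens(b: Binding, lex: Lexicon) -> list[Token]:
    """Tokens of the full disorder: morphology series then function series.

    With ``causal`` set, the two series express cause and effect and are
    linked by 'causing'; a one-sided compound omits the connector.
    """
    if b.get("o"):
        return [Token(b.get("o"), "SPACE")]
    parts = _attach_regulator(b, b.ordered_parts())
    morph: list[Token] = []
    func: list[Token] = []
    for part in parts:
        morph.extend(_part_tokens(b, part, lex, "M"))
    for part in parts:
        func.extend(_part_tokens(b, part, lex, "F"))
    if b.causal and morph and func:
        return morph + [_token(lex, "causing", "LINK")] + func
    return morph + func


def build_disorder(b: Binding, kind: str, lex: Lexicon) -> str:
    """Render the disorder of one body-part level as text."""
    part = b.part(kind)
    if part.is_empty():
        raise EmptyDiagnosisError(f"disorder part {kind} is empty")
    parts = _attach_regulator(b, [part])
    toks = _part_tokens(b, parts[0], lex, "M") + _part_tokens(b, parts[0], lex, "F")
    if not toks:
        raise EmptyDiagnosisError(f"disorder part {kind} renders empty")
    return rewrite.render(toks)


def compose_disorders(b: Binding, lex: Lexicon) -> str:
    """Render the whole disorder chain (all non-empty parts, fixed order)."""
    toks = _disorder_tokens(b, lex)
    if not toks:
        raise EmptyDiagnosisError("no disorder part is set")
    return rewrite.render(toks)


def build_compound(o_m: str, o_f: str) -> str:
    """Compound disorder: morphology causing function.

    One empty side yields the other unchanged; the connector is never left
    dangling.
    """
    if not o_m and not o_f:
        raise EmptyDiagnosisError("both compound sides empty")
    if o_m and o_f:
        return f"{o_m} causing {o_f}"
    return o_m or o_f


def _etiology_tokens(b: Binding, lex: Lexicon) -> list[Token]:
    if b.get("e"):
        return [_token(lex, b.get("e"), "ETIOLOGY")]
    if b.get("N_B") and b.get("Dir_E"):
        return [
            _token(lex, b.get("Dir_E"), "DIR"),
            _token(lex, b.get("N_B"), "SUBSTANCE"),
            _token(lex, "intake", "SUFFIX", "E"),
        ]
    return []


def build_etiology(b: Binding, lex: Lexicon) -> str:
    """Render the etiology segment: agent name, or direction-substance-intake.

    An unassigned etiology renders as '' (idiopathic).
    """
    toks = _etiology_tokens(b, lex)
    return rewrite.render(toks) if toks else ""


def _require(b: Binding, template: str, *slot_names: str) -> None:
    for s in slot_names:
        if not b.get(s):
            raise TemplateError(f"template {template!r} requires slot {s!r}")


def _pathogenesis_tokens(b: Binding, lex: Lexicon,
                         template: str | None = None) -> list[Token]:
    template = template or b.get("p_template")
    if not template:
        if b.get("p") and b.get("L_H"):
            template = "localized"
        elif b.get("Dir_P") and b.get("N_B") and b.get("L_H"):
            template = "metabolic"
        elif b.get("p"):
            template = "plain"
        else:
            return []
    if template not in PATHOGENESIS_TEMPLATES:
        raise TemplateError(f"unknown template {template!r}")
    raw = lambda s: Token(b.get(s), "SPACE")  # noqa: E731 - free composites
    link = lambda s: _token(lex, s, "LINK")  # noqa: E731
    if template == "plain":
        _require(b, template, "p")
        return [_token(lex, b.get("p"))]
    if template == "localized":
        _require(b, template, "p", "L_H")
        return [_token(lex, b.get("p")), _token(lex, b.get("L_H"), "LOCALIZER")]
    if template == "metabolic":
        _require(b, template, "Dir_P", "N_B", "L_H")
        return [
            _token(lex, b.get("Dir_P"), "DIR"),
            _token(lex, b.get("N_B"), "SUBSTANCE"),
            _token(lex, b.get("L_H"), "LOCALIZER"),
        ]
    if template == "spread":
        _require(b, template, "p", "L_H")
        return [raw("p"), _token(lex, b.get("L_H"), "LOCALIZER")]
    if template == "metastasis":
        _require(b, template, "target")
        return [link("with"), raw("target"), _token(lex, "metastasis", "PATHOGENESIS")]
    if template == "embolism":
        _require(b, template, "target")
        return [
            link("with"), _token(lex, "embolus", "PATHOGENESIS"), link("to"),
            raw("target"), link("and"), raw("target"),
            _token(lex, "infarction", "PATHOGENESIS"),
        ]
    if template == "causal-target":
        _require(b, template, "target")
        return [link("causing"), raw("target")]
    # neural: efferent/afferent pathway to a secondary affected function
    _require(b, template, "target")
    nerve = b.get("Eff") or b.get("Aff")
    if not nerve:
        raise TemplateError("template 'neural' requires slot 'Eff' or 'Aff'")
    sub = "EFF" if b.get("Eff") else "AFF"
    return [link("causing"), _token(lex, nerve, "NEURAL", sub), raw("target")]


def build_pathogenesis(b: Binding, lex: Lexicon,
                       template: str | None = None) -> str:
    """Render the pathogenesis segment for one of the named templates."""
    toks = _pathogenesis_tokens(b, lex, template)
    if not toks:
        raise TemplateError("no pathogenesis slots set")
    return rewrite.render(toks)


def generate(b: Binding, lex: Lexicon) -> DiagnosisString:
    """Emit the diagnosis for a binding, components in the fixed order.

    Raises InvalidDiagnosisError when only the etiology is set (agents
    alone do not give rise to diagnoses) and EmptyDiagnosisError when
    everything is empty.
    """
    toks: list[Token] = []
    for slot, cat in (("Dur", "TIME"), ("Seg", "SCOPE_SEG"), ("Reg", "SCOPE_REG")):
        if b.get(slot):
            toks.append(_token(lex, b.get(slot), cat))
    for site in b.sites:
        toks.append(_token(lex, site, "SCOPE_SITE"))
    if b.get("Prog"):
        toks.append(_token(lex, b.get("Prog"), "PROG"))
    e_toks = _etiology_tokens(b, lex)
    o_toks = _disorder_tokens(b, lex)
    s_tok = [_token(lex, b.get("S"), "SUFFIX")] if b.get("S") else []
    p_toks = _pathogenesis_tokens(b, lex)
    if not (o_toks or s_tok or p_toks):
        if e_toks:
            raise InvalidDiagnosisError(
                "etiological agents alone do not give rise to diagnoses"
            )
        raise EmptyDiagnosisError("binding has no components")
    toks.extend(e_toks)
    toks.extend(o_toks)
    toks.extend(s_tok)
    toks.extend(p_toks)
    if b.get("Deg"):
        toks.append(_token(lex, b.get("Deg"), "DEG"))
    return DiagnosisString(rewrite.render(toks))


def chain_diagnoses(cause: DiagnosisString | str,
                    effects: Iterable[DiagnosisString | str]) -> str:
    """One diagnosis causing others: 'D1 causes D2 and D3'."""
    cause_text = str(cause).strip()
    effect_texts = [str(e).strip() for e in effects if str(e).strip()]
    if not cause_text:
        raise ChainError("empty cause diagnosis")
    if not effect_texts:
        raise ChainError("chain requires at least one effect diagnosis")
    return cause_text + " causes " + " and ".join(effect_texts)
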