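"""Completeness classification and consistency checks for diagnoses.

A diagnosis is classified by which of its three core components are
present: a complete etiology + disorder + pathogenesis is a disease; a
bare disorder is a disorder; disorder + pathogenesis is a syndrome;
etiology + pathogenesis or pathogenesis alone leave the anatomical
localization unknown; an etiology alone is not a valid diagnosis.

Suffix agreement: the etiology class and the pathogenesis class each
demand particular suffixes (an infectious agent demands 'itis', radiation
demands 'osis'); when the two demands are disjoint the etiology conflicts
with the pathogenesis and the clinical problem should be split into
several diagnoses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .lexicon import Lexicon
from .parser import DiagnosisComponents, parse

CLASSIFICATIONS = (
    "disease", "disorder", "syndrome",
    "etiology-pathogenesis", "pathogenesis-only", "invalid",
)

#: suffixes demanded by each etiology class
SUFFIX_BY_ETIOLOGY_CLASS: dict[str, frozenset[str]] = {
    "HER": frozenset({"pathy", "osis"}),
    "TRA": frozenset({"vulnus", "fracture"}),
    "NUT": frozenset({"intake"}),
    "INF": frozenset({"itis"}),
    "ALL": frozenset({"itis"}),
    "THE": frozenset({"itis"}),
    "RAD": frozenset({"osis"}),
    "SOC": frozenset({"pathy"}),
    "IDI": frozenset({"", "osis"}),
}

#: suffixes demanded by each pathogenesis class
SUFFIX_BY_PATHOGENESIS_CLASS: dict[str, frozenset[str]] = {
    "ECS": frozenset({"", "osis"}),
    "HEM": frozenset({"oma"}),
    "CIR": frozenset({"", "ial", "al"}),
    "IR": frozenset({"itis"}),
    "MET": frozenset({"osis", "lithiasis"}),
    "REG": frozenset({"", "osis"}),
    "NEU": frozenset({"osis"}),
}


@dataclass
class ValidationReport:
    classification: str = "invalid"
    conflicts: list[dict] = field(default_factory=list)
    missing: list[str] = field(default_factory=list)
    reasons: list[str] = field(default_factory=list)


def _nonempty(value) -> bool:
    if isinstance(value, (list, tuple)):
        return any(str(v).strip() for v in value)
    return bool(str(value).strip())


def classify(c: DiagnosisComponents) -> str:
    """Completeness class of a decomposition.

    The suffix counts towards the pathogenesis ('cystitis' is a well-formed
    disorder + pathogenesis-suffix combination, a syndrome-form).
    """
    has_e = _nonempty(c.etiology)
    has_o = _nonempty(c.disorder)
    has_p = _nonempty(c.pathogenesis) or _nonempty(c.suffix)
    if has_e and has_o and has_p:
        return "disease"
    if has_o and has_p:
        return "syndrome"
    if has_o:
        return "disorder"
    if has_e and has_p:
        return "etiology-pathogenesis"
    if has_p:
        return "pathogenesis-only"
    return "invalid"


def _etiology_classes(c: DiagnosisComponents, lex: Lexicon) -> set[str]:
    classes: set[str] = set()
    for word in ([c.etiology] + c.etiology.split() if c.etiology else []):
        for e in lex.lookup_surface(word):
            if e.category == "ETIOLOGY" and e.term_class:
                classes.add(e.term_class)
    return classes


def _pathogenesis_classes(c: DiagnosisComponents, lex: Lexicon) -> set[str]:
    classes: set[str] = set()
    for surf in c.pathogenesis:
        for e in lex.lookup_surface(surf):
            if e.category == "PATHOGENESIS" and e.term_class:
                classes.add(e.term_class)
    return classes


def detect_conflicts(c: DiagnosisComponents, lex: Lexicon) -> list[dict]:
    """Suffix-agreement conflicts and completeness warnings.

    Emits a ``conflict`` when the suffixes demanded by the etiology class
    and by the pathogenesis class share no member, and a ``warning`` when
    the suffix 'itis' is not followed by an immune reaction type.
    """
    findings: list[dict] = []
    e_classes = _etiology_classes(c, lex)
    p_classes = _pathogenesis_classes(c, lex)
    if e_classes and p_classes:
        s_e: frozenset[str] = frozenset()
        for ec in e_classes:
            s_e |= SUFFIX_BY_ETIOLOGY_CLASS.get(ec, frozenset())
        s_p: frozenset[str] = frozenset()
        for pc in p_classes:
            s_p |= SUFFIX_BY_PATHOGENESIS_CLASS.get(pc, frozenset())
        if s_e and s_p and not (s_e & s_p):
            findings.append({
                "kind": "conflict",
                "detail": "etiology suffix demand conflicts with pathogenesis",
                "etiology_suffixes": sorted(s_e),
                "pathogenesis_suffixes": sorted(s_p),
            })
    if c.suffix == "itis" and "IR" not in p_classes:
        findings.append({
            "kind": "warning",
            "detail": "suffix 'itis' not followed by an immune reaction type",
            "surfaces": ["itis"],
        })
    return findings


def validate_components(c: DiagnosisComponents, lex: Lexicon) -> ValidationReport:
    """Full report: classification, conflicts, missing core slots."""
    report = ValidationReport(classification=classify(c))
    report.conflicts = detect_conflicts(c, lex)
    for name, value in (
        ("e", c.etiology),
        ("o", c.disorder),
        ("p", c.pathogenesis or c.suffix),
    ):
        if not _nonempty(value):
            report.missing.append(name)
    if report.classification == "invalid":
        report.reasons.append(
            "etiological agents alone do not give rise to diagnoses"
            if _nonempty(c.etiology) else "no components present"
        )
    return report


def is_well_formed(d: str, lex: Lexicon) -> tuple[bool, list[str]]:
    """Whether a string is derivable by the grammar, with reasons if not.

    Requires a violation-free parse, no unknown spans, and a classification
    other than invalid.  Misnomers ('itiscys') and symptom terms are
    rejected here because their morphemes or orderings are underivable.
    """
    result = parse(d, lex)
    reasons: list[str] = list(result.violations)
    for start, end in result.unknown:
        reasons.append(f"unknown term at {start}:{end}")
    if result.best is not None:
        cls = classify(result.best)
        if cls == "invalid":
            reasons.append("components do not form a valid diagnosis")
    return (not reasons, reasons)
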