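"""Typed morpheme lexicon: the terminal alphabet of the diagnosis grammar.

Every variable of the grammar (etiology, direction of change, body part,
morphology/function outcome, suffix, localizer, scope, ...) draws its
surface forms from this lexicon.  Entries are typed by category and an
optional subcategory (body-part level P/T/S/I/L/C/O, function type
M/E/B/H/G/O/R/I/N, suffix family E/O/P), and carry a join behaviour that
the generator uses to decide between fusion and space-joining.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Iterator

from .errors import DuplicateEntryError, LexiconError

CATEGORIES = frozenset({
    "ETIOLOGY", "DIR", "BODYPART", "MORPH", "FUNC", "SUFFIX", "LOCALIZER",
    "SUBSTANCE", "REGULATOR", "PATHOGENESIS", "LINK", "SCOPE_SEG",
    "SCOPE_REG", "SCOPE_SITE", "TIME", "PROG", "DEG", "NEURAL",
})

#: body-part levels: parenchyma, tube, slit/cavity, tissue, cell line, cell, organelle
BODYPART_SUBCATS = frozenset("PTSILCO")
FUNC_SUBCATS = frozenset("MEBHGORIN")
SUFFIX_SUBCATS = frozenset("EOP")
NEURAL_SUBCATS = frozenset({"EFF", "AFF"})

JOINS = frozenset({"FUSE_PREV", "FUSE_NEXT", "SPACE"})

_COLUMNS = ("surface", "category", "subcategory", "join", "flags")


@dataclass(frozen=True)
class TermEntry:
    """One morpheme: a surface form plus its grammatical type and join rule.

    Flags carry orthogonal markers: FUSION_SWAP for the hypo/deficiency swap,
    WORD for free-standing words exempt from the category join convention,
    NUT for the nutrition-intake suffix, and CLASS:<code> for the etiology or
    pathogenesis class driving suffix-agreement checks.
    """

    surface: str
    category: str
    subcategory: str = ""
    join: str = "SPACE"
    flags: frozenset[str] = frozenset()

    def has_flag(self, flag: str) -> bool:
        return flag in self.flags

    @property
    def term_class(self) -> str:
        """Etiology/pathogenesis class code from a CLASS:<code> flag, or ''."""
        for f in self.flags:
            if f.startswith("CLASS:"):
                return f[6:]
        return ""


class Lexicon:
    """Indexed collection of :class:`TermEntry`.

    A surface may be multi-categorial ('itis' is both an etiology-driven and
    a pathogenesis-driven suffix); lookups return every entry sharing the
    surface.  A prefix index supports morpheme segmentation.
    """

    def __init__(self, entries: Iterable[TermEntry] = ()):
        self.entries: list[TermEntry] = []
        self._by_surface: dict[str, list[TermEntry]] = {}
        self._by_cat: dict[tuple[str, str], list[TermEntry]] = {}
        self._prefixes: set[str] = set()
        self._keys: set[tuple[str, str, str]] = set()
        for e in entries:
            self.add(e)

    def add(self, entry: TermEntry) -> None:
        key = (entry.surface, entry.category, entry.subcategory)
        if key in self._keys:
            raise DuplicateEntryError(f"duplicate entry {key}")
        self._keys.add(key)
        self.entries.append(entry)
        self._by_surface.setdefault(entry.surface, []).append(entry)
        self._by_cat.setdefault((entry.category, entry.subcategory), []).append(entry)
        for i in range(1, len(entry.surface) + 1):
            self._prefixes.add(entry.surface[:i])

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[TermEntry]:
        return iter(self.entries)

    def lookup_surface(self, surface: str) -> list[TermEntry]:
        """All entries with exactly this surface (case-sensitive)."""
        return list(self._by_surface.get(surface, ()))

    def by_category(self, category: str, subcategory: str | None = None) -> list[TermEntry]:
        if subcategory is not None:
            return list(self._by_cat.get((category, subcategory), ()))
        return [e for e in self.entries if e.category == category]

    def surfaces(self, category: str, subcategory: str | None = None) -> list[str]:
        return sorted({e.surface for e in self.by_category(category, subcategory)})

    def has_prefix(self, prefix: str) -> bool:
        """True iff some stored surface starts with ``prefix``."""
        return prefix in self._prefixes

    def matches_at(self, text: str, start: int) -> list[TermEntry]:
        """Entries whose surface occurs in ``text`` starting at ``start``.

        Matches may span spaces (multiword surfaces); longest first.
        """
        found: list[TermEntry] = []
        end = start + 1
        n = len(text)
        while end <= n and self.has_prefix(text[start:end]):
            chunk = text[start:end]
            found.extend(self._by_surface.get(chunk, ()))
            end += 1
        found.sort(key=lambda e: -len(e.surface))
        return found


def _parse_flags(raw: str) -> frozenset[str]:
    return frozenset(f for f in raw.split(";") if f)


def load_lexicon(source: str | Path | IO[str]) -> Lexicon:
    """Load a lexicon from tab-separated UTF-8 text.

    Expected header: surface, category, subcategory, join, flags.  Lines
    starting with '#' are comments.  Surfaces are NFC-normalized and
    trimmed; join/flags encode any leading/trailing-space fusion convention.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text(encoding="utf-8").splitlines()
    lex = Lexicon()
    header_seen = False
    for lineno, raw in enumerate(lines, start=1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        cells = raw.split("\t")
        if not header_seen:
            got = tuple(c.strip() for c in cells)
            if got != _COLUMNS:
                raise LexiconError(f"bad header {got!r}, expected {_COLUMNS!r}", lineno)
            header_seen = True
            continue
        if len(cells) < 4 or len(cells) > 5:
            raise LexiconError(f"expected 4-5 columns, got {len(cells)}", lineno)
        surface = unicodedata.normalize("NFC", cells[0].strip())
        category = cells[1].strip()
        subcategory = cells[2].strip()
        join = cells[3].strip()
        flags = _parse_flags(cells[4].strip()) if len(cells) == 5 else frozenset()
        if not surface:
            raise LexiconError("empty surface", lineno)
        if category not in CATEGORIES:
            raise LexiconError(f"unknown category {category!r}", lineno)
        if join not in JOINS:
            raise LexiconError(f"unknown join {join!r}", lineno)
        try:
            lex.add(TermEntry(surface, category, subcategory, join, flags))
        except DuplicateEntryError as err:
            raise DuplicateEntryError(str(err), lineno) from None
    if not header_seen:
        raise LexiconError("missing header row")
    return lex


def save_lexicon(lex: Lexicon, dest: IO[str]) -> None:
    """Write a canonical TSV: sorted rows, normalized whitespace."""
    dest.write("\t".join(_COLUMNS) + "\n")
    for e in sorted(lex.entries, key=lambda e: (e.surface, e.category, e.subcategory)):
        dest.write(
            "\t".join([e.surface, e.category, e.subcategory, e.join,
                       ";".join(sorted(e.flags))]) + "\n"
        )


def validate_lexicon(lex: Lexicon) -> list[str]:
    """Report invariant violations; an empty list means the lexicon is sound.

    Checked: non-empty trimmed surfaces, valid category/subcategory/join
    codes, and the join conventions (suffixes fuse backwards, direction
    prefixes fuse forwards) for entries not flagged as free-standing WORDs.
    """
    problems: list[str] = []
    for e in lex.entries:
        if not e.surface.strip():
            problems.append(f"empty surface in {e}")
        elif e.surface != e.surface.strip():
            problems.append(f"untrimmed surface {e.surface!r}")
        if e.category not in CATEGORIES:
            problems.append(f"unknown category {e.category!r} ({e.surface})")
        if e.join not in JOINS:
            problems.append(f"unknown join {e.join!r} ({e.surface})")
        sub_ok = {
            "BODYPART": BODYPART_SUBCATS,
            "FUNC": FUNC_SUBCATS,
            "SUFFIX": SUFFIX_SUBCATS,
            "NEURAL": NEURAL_SUBCATS,
        }.get(e.category)
        if sub_ok is not None and e.subcategory not in sub_ok:
            problems.append(f"bad subcategory {e.subcategory!r} for {e.category} {e.surface!r}")
        if e.category == "SUFFIX" and e.join != "FUSE_PREV" and not e.has_flag("WORD"):
            problems.append(f"SUFFIX {e.surface!r} must fuse to the previous term")
        if e.category == "DIR" and e.join != "FUSE_NEXT" and not e.has_flag("WORD"):
            problems.append(f"DIR {e.surface!r} must fuse to the next term")
    return problems


def packaged_lexicon_path() -> Path:
    """Filesystem path of the bundled lexicon TSV."""
    return Path(str(resources.files("uds.data").joinpath("uds_lexicon.tsv")))


def load_packaged_lexicon() -> Lexicon:
    """The lexicon shipped with the package (compiled term tables)."""
    return load_lexicon(packaged_lexicon_path())
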