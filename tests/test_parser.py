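"""Parsing: segmentation, categorization, order template, round trips."""

import itertools
import random

import pytest

import uds
from uds._segment import Piece
from uds.lexicon import Lexicon, TermEntry
from uds.parser import categorize, check_template, parse, regenerate, segment


def label_tokens(lex, *surfaces):
    pieces, pos = [], 0
    for s in surfaces:
        pieces.append(Piece(s, pos, pos + len(s)))
        pos += len(s) + 1
    return categorize(pieces, lex)


class TestSegment:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("cystitis", ["cyst", "itis"]),
            ("myelodysplasia", ["myelo", "dys", "plasia"]),
            ("hypotension", ["hypo", "tension"]),
            ("E.coli cystitis", ["E.coli", "cyst", "itis"]),
        ],
    )
    def test_fused_morphemes_recovered(self, lex, text, expected):
        surfaces = [[t.surface for t in seg] for seg in segment(text, lex)]
        assert expected in surfaces

    def test_unsegmentable_string_becomes_unknown(self, lex):
        segs = segment("itiscys", lex)
        assert all(any(not t.known for t in seg) for seg in segs)

    def test_completeness_against_fusion_oracle(self):
        """Strings fused from <=4 morphemes are segmented back exactly."""
        terms = [
            "cyst", "itis", "hypo", "tension", "myelo", "dys", "plasia",
            "hepat", "osis", "thyroid", "ism", "hyper", "glyc", "aemia",
            "neur", "trophy", "brady", "cardia", "nephr", "uria", "emesis",
            "hemat", "tachy", "osmia", "thermia", "pyelo", "fibro", "oma",
            "lith", "metropia",
        ]
        sub = Lexicon([TermEntry(t, "BODYPART", "P", "SPACE") for t in terms])
        rng = random.Random(7)
        for _ in range(250):
            combo = [rng.choice(terms) for _ in range(rng.randint(1, 4))]
            fused = "".join(combo)
            surfaces = [
                [t.surface for t in seg] for seg in segment(fused, sub, cap=64)
            ]
            assert combo in surfaces, (combo, surfaces)


class TestCategorize:
    def test_multicategorial_suffix_keeps_all_labels(self, lex):
        (tok,) = label_tokens(lex, "itis")
        assert {(e.category, e.subcategory) for e in tok.candidates} == {
            ("SUFFIX", "E"), ("SUFFIX", "P")
        }

    def test_direction_and_etiology(self, lex):
        toks = label_tokens(lex, "hypo", "E.coli")
        assert {e.category for e in toks[0].candidates} == {"DIR"}
        assert {e.category for e in toks[1].candidates} == {"ETIOLOGY"}


class TestCheckTemplate:
    def test_only_eop_order_accepted(self, lex):
        comp = {"e": "E.coli", "o": "cyst", "p": "itis"}
        verdicts = {}
        for perm in itertools.permutations("eop"):
            toks = label_tokens(lex, *[comp[k] for k in perm])
            verdicts[perm] = check_template(toks) == []
        assert verdicts[("e", "o", "p")] is True
        assert sum(verdicts.values()) == 1

    def test_empty_token_list(self):
        assert check_template([]) == ["empty"]

    def test_violation_names_offending_pair(self, lex):
        toks = label_tokens(lex, "cyst", "itis", "E.coli")
        (violation,) = check_template(toks)
        assert "E.coli" in violation


class TestParse:
    def test_worked_example_components(self, lex):
        res = parse("bacterial conjunctivitis", lex)
        assert res.best is not None and not res.violations
        assert res.best.etiology == "bacterial"
        assert res.best.disorder == ["conjunctiv"]
        assert res.best.suffix == "itis"

    def test_pseudocode_example(self, lex):
        res = parse("E.coli cystitis", lex)
        assert res.best.etiology == "E.coli"
        assert res.best.disorder == ["cyst"]
        assert res.best.suffix == "itis"

    def test_unknown_words_do_not_abort(self, lex):
        res = parse("flibbertigibbet cystitis", lex)
        assert res.unknown and res.best is not None

    def test_empty_input(self, lex):
        assert parse("", lex).violations == ["empty"]

    def test_scope_and_degree_fields(self, lex):
        res = parse("acute frontal cortical atrophy degree 3", lex)
        c = res.best
        assert (c.dur, c.reg, c.degree) == ("acute", "frontal", "degree 3")


def test_roundtrip_over_random_bindings(lex):
    """parse(generate(b)) has no violations and regenerates the string."""
    for seed in range(200):
        b = uds.random_binding(lex, seed)
        text = uds.generate(b, lex).text
        res = parse(text, lex)
        assert res.best is not None, (seed, text, res.violations)
        assert not res.violations and not res.unknown, (seed, text)
        assert regenerate(res.best) == text, (seed, text)


def test_roundtrip_recovers_bound_surfaces(lex):
    """Every bound surface reappears in the parse (modulo euphonic a->an)."""
    for seed in range(100):
        b = uds.random_binding(lex, seed)
        text = uds.generate(b, lex).text
        res = parse(text, lex)
        got = {t.surface for t, _e, _s in res.best.tokens}
        bound = [s for s in b.slots.values() if s and s != "plain"]
        for part in b.parts.values():
            bound.extend(
                v for v in (part.n, part.dir_m, part.dir_f,
                            part.outcome_m, part.outcome_f, part.suffix) if v
            )
        for surface in bound:
            recovered = (
                surface in got
                or (surface == "a" and "an" in got)          # euphonic rewrite
                or any(surface in g for g in got)            # fusion-swap output
            )
            assert recovered, (seed, surface, text, got)
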