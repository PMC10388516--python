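"""Fixture corpus, seeded random bindings, and exhaustive enumeration.

The fixture corpus pins the engine to worked clinical examples: every
fixture stores a binding and the exact diagnosis string it must produce.
Random bindings drive the property tests (bind-order invariance,
parse/generate round trips); enumeration realizes the combinatorial-
classification view of the grammar, whose counts are checked against a
brute-force product oracle.
"""

from __future__ import annotations

import itertools
import json
import random
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping, Sequence

from . import generator
from .errors import UDSError
from .generator import Binding, DiagnosisString, bind_all, generate
from .lexicon import Lexicon, load_packaged_lexicon

DEFAULT_SEED = 1729


@dataclass(frozen=True)
class Fixture:
    """One pinned example: a binding record and its expected surface string."""

    id: str
    op: str                      # generate|etiology|disorder|pathogenesis|compound|chain
    binding: Mapping[str, object]
    expected: str
    source: str = ""


@dataclass
class FixtureResult:
    id: str
    ok: bool
    expected: str
    actual: str


def load_fixtures() -> list[Fixture]:
    """The packaged fixture corpus."""
    with resources.files("uds.data").joinpath("fixtures.json").open(
        "r", encoding="utf-8"
    ) as fh:
        raw = json.load(fh)
    return [Fixture(**rec) for rec in raw]


def evaluate_fixture(fx: Fixture, lex: Lexicon) -> str:
    """Run the operation a fixture pins and return the produced string."""
    rec = dict(fx.binding)
    if fx.op == "chain":
        return generator.chain_diagnoses(rec["cause"], rec["effects"])
    if fx.op == "compound":
        return generator.build_compound(rec.get("o_m", ""), rec.get("o_f", ""))
    b = bind_all(Binding(), rec, lex)
    if fx.op == "generate":
        return generate(b, lex).text
    if fx.op == "etiology":
        return generator.build_etiology(b, lex)
    if fx.op == "disorder":
        return generator.compose_disorders(b, lex)
    if fx.op == "pathogenesis":
        return generator.build_pathogenesis(b, lex)
    raise UDSError(f"unknown fixture op {fx.op!r}")


def run_fixtures(lex: Lexicon | None = None,
                 fixtures: Sequence[Fixture] | None = None) -> list[FixtureResult]:
    """Evaluate every fixture; failures carry expected vs actual."""
    lex = lex or load_packaged_lexicon()
    fixtures = fixtures if fixtures is not None else load_fixtures()
    results = []
    for fx in fixtures:
        try:
            actual = evaluate_fixture(fx, lex)
        except UDSError as err:
            actual = f"<error: {err}>"
        results.append(FixtureResult(fx.id, actual == fx.expected, fx.expected, actual))
    return results


# slot pools for random bindings; kinds restricted to levels whose surfaces
# round-trip unambiguously in both fused and spaced positions
_RANDOM_KINDS = "PTC"
_RANDOM_DIRS = ["hypo", "hyper", "dys", "a", "brady", "tachy"]
_RANDOM_SUFFIXES = ["itis", "osis", "ism"]


def random_binding(lex: Lexicon, seed: int,
                   constraints: str | None = None) -> Binding:
    """A reproducible, type-checked random binding.

    ``constraints``: 'disease' forces etiology + disorder + pathogenesis,
    'disorder' a bare disorder, 'syndrome' disorder + pathogenesis; None
    draws the class at random.
    """
    rng = random.Random(seed)
    want = constraints or rng.choice(["disease", "disorder", "syndrome"])
    if want not in ("disease", "disorder", "syndrome"):
        raise UDSError(f"unknown constraint {want!r}")
    kind = rng.choice(_RANDOM_KINDS)
    n_pool = lex.surfaces("BODYPART", kind)
    if not n_pool:
        raise UDSError(f"no body-part surfaces of level {kind}")
    slots: dict[str, object] = {f"N_{kind}": rng.choice(n_pool)}
    with_suffix = want != "disorder" and rng.random() < 0.5
    if with_suffix:
        slots["S"] = rng.choice(_RANDOM_SUFFIXES)
    else:
        series = rng.choice("MF")
        if series == "M":
            pool = lex.surfaces("MORPH")
            slots[f"M_{kind}"] = rng.choice(pool)
        else:
            pool = lex.surfaces("FUNC")
            slots[f"F_{kind}"] = rng.choice(pool)
        if rng.random() < 0.6:
            slots[f"Dir_{kind}_{series}"] = rng.choice(_RANDOM_DIRS)
        if want != "disorder":
            slots["p"] = rng.choice(
                [s for s in lex.surfaces("PATHOGENESIS") if " " not in s]
            )
    if want == "disease":
        slots["e"] = rng.choice(lex.surfaces("ETIOLOGY"))
    return bind_all(Binding(), slots, lex)


def enumerate_diagnoses(lex: Lexicon, constraints: str | None = None,
                        limit: int | None = None) -> Iterator[DiagnosisString]:
    """Exhaustive, lexicographically ordered enumeration of diagnoses.

    The e pool is the etiology surfaces, the o pool the body-part surfaces,
    the p pool the suffix and pathogenesis surfaces; the number of emitted
    diagnoses equals the product of the participating pool sizes.
    """
    want = constraints or "disease"
    e_pool = lex.surfaces("ETIOLOGY")
    o_pool = lex.surfaces("BODYPART")
    p_pool = sorted(set(lex.surfaces("SUFFIX")) | set(lex.surfaces("PATHOGENESIS")))
    suffixes = set(lex.surfaces("SUFFIX"))
    if want == "disease":
        combos = itertools.product(e_pool, o_pool, p_pool)
    elif want == "syndrome":
        combos = (("", o, p) for o, p in itertools.product(o_pool, p_pool))
    elif want == "disorder":
        combos = ((("", o, "")) for o in o_pool)
    else:
        raise UDSError(f"unknown constraint {want!r}")
    count = 0
    for e, o, p in combos:
        if limit is not None and count >= limit:
            return
        slots: dict[str, object] = {"o": o}
        if e:
            slots["e"] = e
        if p:
            slots["S" if p in suffixes else "p"] = p
        yield generate(bind_all(Binding(), slots, lex), lex)
        count += 1
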