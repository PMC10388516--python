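"""Generation: concatenation, joins, disorder assembly, templates, errors."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import uds
from uds.errors import (
    CategoryError,
    ChainError,
    EmptyDiagnosisError,
    InvalidDiagnosisError,
    TemplateError,
    UnknownSlotError,
)
from uds.generator import (
    Binding,
    apply_dir_scope,
    bind,
    bind_all,
    build_compound,
    build_disorder,
    build_etiology,
    build_pathogenesis,
    chain_diagnoses,
    compose_disorders,
    concat,
    generate,
    join_terms,
)


@pytest.mark.parametrize(
    "a, b, expected",
    [("abc", "abc", "abcabc"), ("abc ", "abc", "abc abc"), ("", "x", "x")],
)
def test_concat(a, b, expected):
    assert concat(a, b) == expected


def test_concat_not_commutative():
    assert concat("ab", "c") != concat("c", "ab")


@pytest.mark.parametrize(
    "parts, expected",
    [
        ([("E.coli", "SPACE"), ("cyst", "SPACE"), ("itis", "FUSE_PREV")],
         "E.coli cystitis"),
        ([("arterial", "SPACE"), ("hypo", "FUSE_NEXT"), ("tension", "SPACE")],
         "arterial hypotension"),
        ([("myelo", "FUSE_NEXT"), ("dys", "FUSE_NEXT"), ("plasia", "FUSE_PREV")],
         "myelodysplasia"),
    ],
)
def test_join_terms(parts, expected):
    assert join_terms(parts) == expected


def test_join_terms_all_empty_signals():
    with pytest.raises(EmptyDiagnosisError):
        join_terms([("", "SPACE"), ("", "SPACE")])


@pytest.mark.parametrize(
    "direction, parts, expected",
    [
        ("hypo", ["trophy", "function"],
         [("hypo", "FUSE_NEXT"), ("trophy", "SPACE"),
          ("hypo", "FUSE_NEXT"), ("function", "SPACE")]),
        ("hypo", ["trophy"], [("hypo", "FUSE_NEXT"), ("trophy", "SPACE")]),
        ("", ["trophy"], [("trophy", "SPACE")]),
    ],
)
def test_apply_dir_scope_distributes(direction, parts, expected):
    assert apply_dir_scope(direction, parts) == expected


def test_dir_scope_renders_to_prefixed_terms():
    assert join_terms(apply_dir_scope("hypo", ["trophy", "function"])) == \
        "hypotrophy hypofunction"


class TestBind:
    def test_wrong_category_rejected(self, lex):
        with pytest.raises(CategoryError):
            bind(Binding(), "o", "Staphylococcus aureus", lex)

    def test_unknown_identifier_rejected(self, lex):
        with pytest.raises(UnknownSlotError):
            bind(Binding(), "q", "x", lex)

    def test_unknown_surface_rejected(self, lex):
        with pytest.raises(CategoryError):
            bind(Binding(), "N_P", "flux capacitor", lex)

    def test_empty_bind_is_neutral(self, lex):
        b = bind_all(Binding(), {"N_P": "thyroid", "M_P": "tumor"}, lex)
        b2 = bind(bind(b, "e", "", lex), "Dur", "", lex)
        assert generate(b, lex) == generate(b2, lex)

    def test_site_recursion_capped(self, lex):
        b = Binding()
        for _ in range(5):
            b = bind(b, "Site", "above", lex)
        with pytest.raises(CategoryError):
            bind(b, "Site", "left", lex)


class TestDisorder:
    def test_morphology_part(self, lex):
        b = bind_all(Binding(), {"N_P": "thyroid", "M_P": "tumor"}, lex)
        assert build_disorder(b, "P", lex) == "thyroid tumor"

    def test_regulator_part(self, lex):
        b = bind_all(Binding(), {"N_C": "β-cell", "N_H": "insulin",
                                 "Dir_H": "hypo", "F_C_B": "secretion"}, lex)
        assert build_disorder(b, "C", lex) == "β-cell insulin hyposecretion"

    def test_empty_part_signals(self, lex):
        with pytest.raises(EmptyDiagnosisError):
            build_disorder(Binding(), "P", lex)

    def test_single_part_chain_equals_part(self, lex):
        b = bind_all(Binding(), {"N_T": "arterial", "Dir_T_F": "hyper",
                                 "F_T": "tension"}, lex)
        assert compose_disorders(b, lex) == build_disorder(b, "T", lex) \
            == "arterial hypertension"

    def test_two_morphology_parts_keep_level_order(self, lex):
        b = bind_all(Binding(), {"N_T": "coronary", "M_T": "stenosis",
                                 "N_P": "thyroid", "M_P": "tumor"}, lex)
        # parenchyma precedes tube in the fixed part order
        left = build_disorder(b, "P", lex)
        right = build_disorder(b, "T", lex)
        assert compose_disorders(b, lex) == f"{left} {right}"


@pytest.mark.parametrize(
    "o_m, o_f, expected",
    [
        ("hepatic carcinoma", "hepatic hypofunction",
         "hepatic carcinoma causing hepatic hypofunction"),
        ("lung fibrosis", "lung hypofunction",
         "lung fibrosis causing lung hypofunction"),
        ("coronary thrombosis", "myocardial infarction",
         "coronary thrombosis causing myocardial infarction"),
        ("lung fibrosis", "", "lung fibrosis"),
        ("", "lung hypofunction", "lung hypofunction"),
    ],
)
def test_build_compound(o_m, o_f, expected):
    assert build_compound(o_m, o_f) == expected


def test_build_compound_empty_signals():
    with pytest.raises(EmptyDiagnosisError):
        build_compound("", "")


class TestEtiology:
    def test_nutrition_template(self, lex):
        b = bind_all(Binding(), {"Dir_E": "Elevated", "N_B": "glucose"}, lex)
        assert build_etiology(b, lex) == "Elevated glucose intake"

    def test_agent_name_verbatim(self, lex):
        b = bind(Binding(), "e", "Staphylococcus aureus", lex)
        assert build_etiology(b, lex) == "Staphylococcus aureus"

    def test_unassigned_is_idiopathic(self, lex):
        assert build_etiology(Binding(), lex) == ""


class TestPathogenesisTemplates:
    def test_metabolic(self, lex):
        b = bind_all(Binding(), {"Dir_P": "hyper", "N_B": "glyc",
                                 "L_H": "aemia"}, lex)
        assert build_pathogenesis(b, lex, "metabolic") == "hyperglycaemia"

    def test_localized(self, lex):
        b = bind_all(Binding(), {"p": "hemat", "L_H": "emesis"}, lex)
        assert build_pathogenesis(b, lex, "localized") == "hematemesis"
        b2 = bind_all(Binding(), {"p": "hemat", "L_H": "uria"}, lex)
        assert build_pathogenesis(b2, lex, "localized") == "hematuria"

    def test_metastasis(self, lex):
        b = bind_all(Binding(), {"target": "pulmonary"}, lex)
        assert build_pathogenesis(b, lex, "metastasis") == \
            "with pulmonary metastasis"

    def test_missing_slot_raises(self, lex):
        with pytest.raises(TemplateError):
            build_pathogenesis(bind_all(Binding(), {"p": "hemat"}, lex),
                               lex, "localized")


class TestGenerate:
    def test_etiology_alone_invalid(self, lex):
        b = bind(Binding(), "e", "Staphylococcus aureus", lex)
        with pytest.raises(InvalidDiagnosisError):
            generate(b, lex)

    def test_all_empty_raises(self, lex):
        with pytest.raises(EmptyDiagnosisError):
            generate(Binding(), lex)

    def test_deterministic(self, lex):
        b = bind_all(Binding(), {"e": "E.coli", "N_S": "cyst", "S": "itis"}, lex)
        assert generate(b, lex).text == generate(b, lex).text == "E.coli cystitis"

    def test_component_order_is_fixed(self, lex):
        b = bind_all(
            Binding(),
            {"Dur": "acute", "Prog": "malignant", "e": "hereditary",
             "o": "thyroid neoplasm", "Deg": "degree 3"},
            lex,
        )
        assert generate(b, lex).text == \
            "acute malignant hereditary thyroid neoplasm degree 3"


@settings(max_examples=50, derandomize=True)
@given(seed=st.integers(min_value=0, max_value=10_000),
       shuffle=st.randoms(use_true_random=False))
def test_bind_order_invariance(seed, shuffle):
    """Any permutation of bind calls yields the identical diagnosis."""
    lex = uds.load_packaged_lexicon()
    b = uds.random_binding(lex, seed)
    ref = generate(b, lex).text
    items = _flatten(b)
    shuffle.shuffle(items)
    b2 = Binding()
    for var, value in items:
        b2 = bind(b2, var, value, lex)
    assert generate(b2, lex).text == ref


def _flatten(b: Binding) -> list[tuple[str, str]]:
    items = list(b.slots.items())
    for kind, part in b.parts.items():
        if part.n:
            items.append((f"N_{kind}", part.n))
        if part.outcome_m:
            items.append((f"M_{kind}", part.outcome_m))
        if part.outcome_f:
            suffix = f"_{part.z}" if part.z else ""
            items.append((f"F_{kind}{suffix}", part.outcome_f))
        if part.dir_m and part.dir_m == part.dir_f:
            items.append((f"Dir_{kind}", part.dir_m))
        else:
            if part.dir_m:
                items.append((f"Dir_{kind}_M", part.dir_m))
            if part.dir_f:
                items.append((f"Dir_{kind}_F", part.dir_f))
    return items


@pytest.mark.parametrize(
    "effects, expected",
    [
        (["D2"], "D1 causes D2"),
        (["D2", "D3"], "D1 causes D2 and D3"),
        (["D2", "D3", "D4"], "D1 causes D2 and D3 and D4"),
    ],
)
def test_chain_diagnoses(effects, expected):
    assert chain_diagnoses("D1", effects) == expected


def test_chain_requires_effects():
    with pytest.raises(ChainError):
        chain_diagnoses("D1", [])
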