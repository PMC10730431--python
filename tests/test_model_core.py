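"""The multivalued rule formalism: parsing, validation, perturbation."""

import random

import pytest

from malatnet.model import (
    LogicalModel,
    ModelSyntaxError,
    Perturbation,
    apply_perturbation,
    parse_model,
    serialize_model,
    validate_model,
)
from malatnet.dynamics import image
from malatnet.synthetic import RandomModelConfig, random_model
from tests.conftest import TOY_CASCADE


def test_toy_cascade_structure(toy_cascade):
    # counted by hand from the three-line fixture: A->B, B->C, A-|C
    assert len(toy_cascade.nodes) == 3
    assert len(toy_cascade.edges) == 3
    signs = {(e.source, e.target): e.sign for e in toy_cascade.edges}
    assert signs == {("A", "B"): 1, ("B", "C"): 1, ("A", "C"): -1}


def test_serialize_parse_round_trip(toy_cascade, nsclc):
    for model in (toy_cascade, nsclc):
        text = serialize_model(model)
        again = parse_model(text)
        assert serialize_model(again) == text
        assert again.names == model.names
        assert {(e.source, e.target, e.sign, e.threshold) for e in again.edges} == {
            (e.source, e.target, e.sign, e.threshold) for e in model.edges
        }


@pytest.mark.parametrize(
    "bad, message",
    [
        ("A, 1, input : B\nB, 1 : A", "must not carry a rule"),
        ("A, 1 : Bogus", "undeclared node"),
        ("A, 1 : {3 if A; else 0}", "out of range"),
        ("A, 0 : A", "cannot parse|max_level"),
        ("A, 1 : B &\nB, 1 : A", "unexpected|bad token"),
        ("A, 2 : A:3", "exceeds max level"),
    ],
)
def test_parse_errors(bad, message):
    import re

    with pytest.raises(ModelSyntaxError) as exc:
        parse_model(bad)
    assert re.search(message, str(exc.value))


def test_guarded_rule_levels_and_thresholds():
    model = parse_model(
        "X, 1, input\n"
        "Y, 1, input\n"
        "P, 2 : {2 if X & Y; 1 if X | Y; else 0}\n"
    )
    assert image(model, (0, 0, 0))[2] == 0
    assert image(model, (1, 0, 0))[2] == 1
    assert image(model, (1, 1, 0))[2] == 2
    # both inputs act positively, from their first level
    for e in model.edges:
        assert e.sign == 1 and e.threshold == 1


def test_validate_reports_declared_sign_mismatch():
    model = parse_model("A, 1, input\nC, 1 : !A")
    report = validate_model(model, declared_edges=[("A", "C", +1)])
    assert len(report.sign_consistency_errors) == 1
    assert "declared sign" in report.sign_consistency_errors[0]


def test_validate_reports_vacuous_regulator():
    model = parse_model("A, 1, input\nC, 1 : A | !A")
    report = validate_model(model)
    assert any("vacuous" in e for e in report.sign_consistency_errors)


def test_validate_counts_exclude_inputs(toy_cascade):
    report = validate_model(toy_cascade)
    assert report.n_components == 2
    assert report.n_edges == 3
    assert report.ok


def test_apply_perturbation_identity_and_clamps(nsclc):
    same = apply_perturbation(nsclc, Perturbation())
    assert same.clamps == nsclc.clamps

    p = Perturbation.from_spec(nsclc, {"MALAT1": "E1", "miR-145": "KO"})
    clamped = apply_perturbation(nsclc, p)
    assert clamped.clamps["MALAT1"] == 1 and clamped.clamps["miR-145"] == 0

    with pytest.raises(KeyError):
        Perturbation.from_spec(nsclc, {"NoSuchNode": "E1"})
    with pytest.raises(ValueError):
        Perturbation.from_spec(nsclc, {"MALAT1": 5})


def test_clamp_dominance_on_random_states(nsclc):
    """After clamping, the clamped node's image equals the clamp in every
    sampled state."""
    rng = random.Random(42)
    p = Perturbation.from_spec(nsclc, {"p53": 2, "Sp1": "KO"})
    clamped = apply_perturbation(nsclc, p)
    i_p53, i_sp1 = nsclc.index("p53"), nsclc.index("Sp1")
    for _ in range(100):
        s = tuple(rng.randrange(n.max_level + 1) for n in clamped.nodes)
        img = image(clamped, s)
        assert img[i_p53] == 2 and img[i_sp1] == 0


def test_sign_consistency_exhaustive_on_random_models():
    """Every inferred edge's sign agrees with an exhaustive monotonicity
    scan, and generated models are sign-consistent by construction."""
    for seed in range(25):
        model = random_model(RandomModelConfig(n_nodes=6, max_inputs=3, seed=seed,
                                               fraction_multivalued=0.3))
        report = validate_model(model)
        assert report.ok, report.sign_consistency_errors
        for e in model.edges:
            sign, thr = model.regulator_effect(e.source, e.target)
            assert sign == e.sign and thr == e.threshold


def test_output_nodes_must_be_terminal():
    with pytest.raises(ModelSyntaxError):
        parse_model("A, 1, output : B\nB, 1 : A")
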