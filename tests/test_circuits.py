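"""Elementary circuits, signs, and functionality contexts."""

import pytest

from malatnet.circuits import (
    Circuit,
    circuit_sign,
    enumerate_circuits,
    functional_circuit_census,
    functionality_context,
)
from malatnet.model import Perturbation, apply_perturbation, parse_model
from malatnet.synthetic import (
    RandomModelConfig,
    brute_force_functional_circuits,
    random_model,
)

COMPLETE3 = """\
A, 1 : B | C
B, 1 : A | C
C, 1 : A | B
"""


def canon(nodes):
    return min(tuple(nodes[i:] + nodes[:i]) for i in range(len(nodes)))


def test_complete_digraph_circuit_count():
    # brute force over node subsets and rotations gives 3 two-cycles and
    # 2 three-cycles for the complete 3-node digraph without self-loops
    model = parse_model(COMPLETE3)
    circuits = enumerate_circuits(model)
    by_len = {}
    for c in circuits:
        by_len[c.length] = by_len.get(c.length, 0) + 1
    assert by_len == {2: 3, 3: 2}
    assert len(circuits) == 5


def test_acyclic_graph_has_no_circuits(toy_cascade):
    assert enumerate_circuits(toy_cascade) == []


def test_self_loop_is_a_length_one_positive_circuit():
    model = parse_model("A, 1 : A\n")
    (c,) = enumerate_circuits(model)
    assert c.length == 1 and c.sign == "positive"
    assert functionality_context(model, c).is_functional


def test_sign_parity_and_rotation_invariance(nsclc):
    for c in enumerate_circuits(nsclc, max_len=4):
        neg = sum(1 for e in c.edges if e.sign < 0)
        assert c.sign == ("positive" if neg % 2 == 0 else "negative")
        for k in range(c.length):
            rotated = Circuit.from_nodes(nsclc, c.nodes[k:] + c.nodes[:k])
            assert rotated == c and circuit_sign(rotated) == c.sign


def test_published_circuit_signs(nsclc):
    mir_sp1_malat1 = Circuit.from_nodes(nsclc, ("miR-145", "Sp1", "MALAT1"))
    assert mir_sp1_malat1.sign == "positive"  # two inhibitions, one activation
    p53_wip1_p38 = Circuit.from_nodes(nsclc, ("p53", "Wip1", "p38MAPK"))
    assert p53_wip1_p38.sign == "negative"  # single inhibition


def test_edge_without_witnessing_context_is_nonfunctional():
    # clamping X at 0 leaves A unable to ever alter B's image, so the
    # A/B loop has an empty context even though both edges exist
    model = parse_model("X, 1, input\nA, 1 : B\nB, 1 : A & X\n")
    c = Circuit.from_nodes(model, ("A", "B"))
    assert functionality_context(model, c).is_functional  # X free: witness X=1
    clamped = apply_perturbation(model, Perturbation.from_spec(model, {"X": 0}))
    ctx = functionality_context(clamped, c)
    assert not ctx.is_functional and ctx.witness is None


def test_functionality_context_matches_exhaustive_scan():
    """The witness-join equals a brute-force scan over all full states on a
    toy model small enough to enumerate (<= 64 states)."""
    model = parse_model(
        "A, 1 : !B & C\nB, 1 : A\nC, 1 : A | C\nD, 1 : A & !D\n"
    )
    expected = brute_force_functional_circuits(model)
    got = {
        ctx.circuit
        for ctx in (
            functionality_context(model, c) for c in enumerate_circuits(model)
        )
        if ctx.is_functional
    }
    assert got == expected


@pytest.mark.parametrize("seed", range(100))
def test_functional_circuits_match_brute_force_oracle(seed):
    cfg = RandomModelConfig(n_nodes=6, max_inputs=3, seed=seed, fraction_negative=0.5)
    model = random_model(cfg)
    engine = {
        ctx.circuit
        for ctx in (
            functionality_context(model, c) for c in enumerate_circuits(model)
        )
        if ctx.is_functional
    }
    assert engine == brute_force_functional_circuits(model)


def test_census_counts_stable_under_node_reordering(nsclc):
    from malatnet.model import serialize_model

    lines = serialize_model(nsclc).strip().split("\n")
    reordered = "\n".join(reversed(lines)) + "\n"
    model2 = parse_model(reordered)
    c1 = functional_circuit_census(nsclc)
    c2 = functional_circuit_census(model2)
    assert c1.total_functional == c2.total_functional
    assert c1.n_functional_short == c2.n_functional_short
    assert {c.nodes for c in c1.functional_short} == {c.nodes for c in c2.functional_short}


def test_clamping_a_circuit_node_disables_it(nsclc):
    c = Circuit.from_nodes(nsclc, ("miR-145", "Sp1", "MALAT1"))
    assert functionality_context(nsclc, c).is_functional
    clamped = apply_perturbation(nsclc, Perturbation.from_spec(nsclc, {"Sp1": "KO"}))
    assert not functionality_context(clamped, c).is_functional


def test_census_shape(nsclc):
    census = functional_circuit_census(nsclc)
    assert census.total_functional == sum(census.functional_by_length.values())
    assert census.total_functional == sum(census.functional_by_sign.values())
    assert census.n_functional_short == sum(
        v for k, v in census.functional_by_length.items() if k <= 4
    )
    tab = census.table()
    assert len(tab) == census.total_circuits
    assert tab["functional"].sum() == census.total_functional
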