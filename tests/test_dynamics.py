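"""Asynchronous semantics: images, successors, stable states, attractors."""

import pytest

from malatnet.dynamics import (
    Attractor,
    async_successors,
    attractors,
    bounded_attractors,
    image,
    reachable_stg,
    stable_states,
)
from malatnet.model import parse_model
from malatnet.synthetic import (
    RandomModelConfig,
    brute_force_attractors,
    random_model,
)


def test_image_fixed_point_definition(toy_switch):
    assert image(toy_switch, (1, 0)) == (1, 0)
    assert image(toy_switch, (0, 0)) == (1, 1)


def test_image_respects_documented_mir145_regulation(nsclc):
    i = nsclc.index
    base = [0] * len(nsclc.nodes)
    # arrester p53 with both sponges off drives miR-145
    s = list(base)
    s[i("p53")] = 1
    assert image(nsclc, tuple(s))[i("miR-145")] == 1
    # BMI1 sponging silences it at the arrester level
    s[i("BMI1")] = 1
    assert image(nsclc, tuple(s))[i("miR-145")] == 0
    # as does MALAT1
    s[i("BMI1")] = 0
    s[i("MALAT1")] = 1
    assert image(nsclc, tuple(s))[i("miR-145")] == 0


def test_async_successors_unitary(toy_switch):
    # from (0,0) the image is (1,1): exactly two unitary successors
    assert async_successors(toy_switch, (0, 0)) == {(1, 0), (0, 1)}
    # stable states have none
    assert async_successors(toy_switch, (1, 0)) == set()


def test_async_successor_moves_one_level_for_ternary_nodes():
    model = parse_model("A, 1, input\nP, 2 : {2 if A; else 0}\n")
    succ = async_successors(model, (1, 0))
    assert succ == {(1, 1)}  # toward level 2 via level 1, never jumping


def test_stable_states_constant_model():
    model = parse_model("A, 1 : 0\nB, 1 : 0\n")
    assert stable_states(model) == {(0, 0)}


def test_stable_states_cover_all_input_levels(toy_cascade):
    # input A is a free variable for the sweep
    ss = stable_states(toy_cascade)
    assert ss == {(0, 0, 0), (1, 1, 0)}


def test_negative_loop_single_cyclic_attractor(toy_negloop):
    ats = attractors(toy_negloop)
    assert len(ats) == 1
    (a,) = ats
    assert a.kind == "cyclic"
    assert a.states == {(0, 0), (1, 0), (1, 1), (0, 1)}


def test_attractors_equal_stable_states_when_no_cycles(toy_switch):
    ats = attractors(toy_switch)
    assert {a.state for a in ats} == stable_states(toy_switch)
    assert all(a.kind == "stable" for a in ats)


def test_reachable_stg_toy_cascade(toy_cascade):
    # from (A=1, 0, 0): B may rise, C may rise (A holds it back after B=1)
    stg = reachable_stg(toy_cascade, [(1, 0, 0)])
    assert not stg.truncated
    assert stg.states == {(1, 0, 0), (1, 1, 0)}
    assert stg.transitions == {((1, 0, 0), (1, 1, 0))}


def test_reachable_stg_from_stable_state(toy_switch):
    stg = reachable_stg(toy_switch, [(1, 0)])
    assert stg.states == {(1, 0)} and not stg.transitions


def test_reachable_stg_truncation_flagged(nsclc):
    init = [tuple(1 if n.name == "DNA_damage" else 0 for n in nsclc.nodes)]
    stg = reachable_stg(nsclc, init, max_states=50)
    assert stg.truncated and len(stg.states) <= 51


def test_bounded_attractors_find_genuine_terminal_sets(toy_negloop):
    found, complete = bounded_attractors(toy_negloop, [(0, 0)], max_states=16)
    assert complete
    assert {a.kind for a in found} == {"cyclic"}


@pytest.mark.parametrize("seed", range(0, 100, 1))
def test_attractors_match_brute_force_oracle(seed):
    """Engine attractors equal the explicit-STG terminal SCCs on random
    models (exact set equality, mixed Boolean/ternary)."""
    cfg = RandomModelConfig(
        n_nodes=8, max_inputs=2, fraction_multivalued=0.25, seed=seed
    )
    model = random_model(cfg)
    assert attractors(model) == brute_force_attractors(model)


def test_stable_state_scheme_independence():
    """Fixed points via the pruned sweep equal states with empty
    asynchronous successor sets (checked exhaustively on small models)."""
    for seed in range(20):
        model = random_model(RandomModelConfig(n_nodes=7, max_inputs=3, seed=seed))
        swept = stable_states(model)
        exhaustive = {
            model.unpack(i)
            for i in range(model.n_states)
            if not async_successors(model, model.unpack(i))
        }
        assert swept == exhaustive


def test_attractor_states_closed_under_successors():
    for seed in range(20):
        model = random_model(RandomModelConfig(n_nodes=7, max_inputs=2, seed=seed + 500))
        for a in attractors(model):
            for s in a.states:
                assert async_successors(model, s) <= a.states


def test_attractor_invariants():
    with pytest.raises(ValueError):
        Attractor("stable", frozenset([(0,), (1,)]))
    with pytest.raises(ValueError):
        Attractor("cyclic", frozenset([(0,)]))
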