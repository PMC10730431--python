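"""Random asynchronous trajectory sampling and the bistability rule."""

import math
import random

import numpy as np
import pytest

from malatnet.model import parse_model
from malatnet.montecarlo import (
    PhenotypeDistribution,
    classify_bistability,
    damaged_proliferation_state,
    phenotype_probabilities,
    sample_trajectory,
)

# mutual inhibition: from the symmetric state the walk falls into one of the
# two stable states in exactly one step, each with probability 1/2
SWITCH = "A, 1 : !B\nB, 1 : !A\n"
SWITCH_MARKERS = {"Left": {"A": 1, "B": 0}, "Right": {"A": 0, "B": 1}}

CHAIN = "A, 1 : 1\nB, 1 : A\nC, 1 : B\n"


def test_stable_initial_state_absorbs_immediately(toy_switch):
    res = sample_trajectory(toy_switch, (1, 0), rng=0)
    assert res.absorbed and res.steps == 0
    assert res.attractor.kind == "stable" and res.attractor.state == (1, 0)


def test_deterministic_chain_is_seed_independent():
    model = parse_model(CHAIN)
    finals = {sample_trajectory(model, (0, 0, 0), rng=seed).final for seed in range(10)}
    assert finals == {(1, 1, 1)}


def test_symmetric_switch_absorbs_in_one_step():
    model = parse_model(SWITCH)
    for seed in range(20):
        res = sample_trajectory(model, (0, 0), rng=seed)
        assert res.absorbed and res.steps == 1
        assert res.final in {(1, 0), (0, 1)}


def test_switch_probabilities_within_binomial_bound():
    """Exact absorption probability is 1/2 by symmetry; the estimate must
    fall within 4 binomial standard deviations at n = 10,000."""
    model = parse_model(SWITCH)
    n = 10_000
    dist = phenotype_probabilities(
        model, SWITCH_MARKERS, n_runs=n, seed=7, initial=(0, 0)
    )
    sigma = math.sqrt(0.25 / n)
    assert abs(dist.probability("Left") - 0.5) <= 4 * sigma
    assert abs(sum(dist.probabilities.values()) - 1.0) < 1e-12


def test_seed_determinism_and_probability_normalization(nsclc, markers):
    d1 = phenotype_probabilities(nsclc, markers, {"miR-145": "E1"}, n_runs=300, seed=11)
    d2 = phenotype_probabilities(nsclc, markers, {"miR-145": "E1"}, n_runs=300, seed=11)
    assert d1.counts == d2.counts
    assert abs(sum(d1.probabilities.values()) - 1.0) < 1e-12
    d3 = phenotype_probabilities(nsclc, markers, {"miR-145": "E1"}, n_runs=300, seed=12)
    assert d3.counts != d1.counts or d3.seed != d1.seed


def test_nonzero_mass_only_on_reachable_phenotypes(nsclc, markers):
    # the damaged proliferating cell keeps its MALAT1/BMI1 shield intact,
    # so every wild-type trajectory is absorbed by the resistant state
    d = phenotype_probabilities(nsclc, markers, n_runs=200, seed=3)
    assert d.probabilities == {"DrugResistance": 1.0}


def test_convergence_rate_is_square_root():
    """Mean absolute error against the exact absorption probability decays
    as n^(-1/2) on the analytically solvable switch."""
    model = parse_model(SWITCH)
    sizes = [100, 400, 1600, 6400]
    mean_abs_err = []
    for k, n in enumerate(sizes):
        errs = []
        for rep in range(40):
            d = phenotype_probabilities(
                model, SWITCH_MARKERS, n_runs=n, seed=1000 * k + rep, initial=(0, 0)
            )
            errs.append(abs(d.probability("Left") - 0.5))
        mean_abs_err.append(np.mean(errs))
    slope = np.polyfit(np.log(sizes), np.log(mean_abs_err), 1)[0]
    assert -0.6 <= slope <= -0.4


def test_default_run_count_is_ten_thousand(nsclc):
    import inspect

    sig = inspect.signature(phenotype_probabilities)
    assert sig.parameters["n_runs"].default == 10_000


def test_damaged_proliferation_initial_condition(nsclc):
    s = damaged_proliferation_state(nsclc)
    d = nsclc.state_dict(s)
    assert d["DNA_damage"] == 1 and d["Myc"] == 1 and d["CyclinD"] == 1


@pytest.mark.parametrize(
    "p_apoptosis, expected",
    [
        (0.75, "reduces_resistance"),
        (1.0, "reduces_resistance"),
        (0.70, "supports_resistance"),  # strict inequality: 'exceeds'
        (0.10, "supports_resistance"),
    ],
)
def test_bistability_rule_is_strict(p_apoptosis, expected):
    n = 10_000
    k = round(p_apoptosis * n)
    d = PhenotypeDistribution(
        {"Apoptosis": k, "Senescence": n - k}, n_runs=n, seed=0, max_steps=10
    )
    assert classify_bistability(d) == expected


def test_all_censored_raises():
    model = parse_model("A, 1 : !B\nB, 1 : !A\nC, 1 : !C\n")  # C oscillates
    with pytest.raises(RuntimeError):
        phenotype_probabilities(
            model,
            SWITCH_MARKERS,
            n_runs=5,
            seed=0,
            initial=(0, 0, 0),
            max_steps=1,
        )
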