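"""Sugeno inference core: memberships, firing, forward pass, encoding."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thyrocad.fis_core import (
    SIGMA_FLOOR,
    AnfisModel,
    GaussianMF,
    SugenoRule,
    apply_scaling,
    classify,
    decode,
    encode,
    firing_strengths,
    fit_scaling,
    forward,
    forward_batch,
    load_model,
    membership,
    parameter_count,
    save_model,
)

from conftest import random_model


@pytest.mark.parametrize(
    "c, sigma, x, expected",
    [
        (0.5, 0.1, 0.5, 1.0),                    # at the center
        (0.0, 1.0, 1.0, math.exp(-0.5)),         # one sigma out
        (0.3, 0.2, 0.7, math.exp(-2.0)),         # exp(-(0.4)^2 / (2*0.04))
    ],
)
def test_membership_closed_form(c, sigma, x, expected):
    assert membership(GaussianMF(center=c, sigma=sigma), x) == pytest.approx(
        expected, rel=1e-12
    )


def test_membership_rejects_non_positive_sigma():
    with pytest.raises(ValueError):
        GaussianMF(center=0.0, sigma=0.0)
    with pytest.raises(ValueError):
        GaussianMF(center=0.0, sigma=-0.3)


def _two_rule_model():
    r1 = SugenoRule(
        premises=(GaussianMF(0.2, 0.3), GaussianMF(0.4, 0.2)),
        consequent_coeffs=(1.0, -0.5),
        consequent_bias=0.3,
    )
    r2 = SugenoRule(
        premises=(GaussianMF(0.8, 0.25), GaussianMF(0.6, 0.4)),
        consequent_coeffs=(-1.2, 2.0),
        consequent_bias=-0.1,
    )
    return AnfisModel(rules=(r1, r2), input_scaling=((0, 1), (0, 1)))


def test_firing_strengths_singleton_and_symmetry():
    single = AnfisModel(
        rules=(_two_rule_model().rules[0],), input_scaling=((0, 1), (0, 1))
    )
    assert firing_strengths(single, [0.9, 0.1]) == pytest.approx([1.0])

    twin = AnfisModel(
        rules=(_two_rule_model().rules[0],) * 2, input_scaling=((0, 1), (0, 1))
    )
    assert firing_strengths(twin, [0.3, 0.7]) == pytest.approx([0.5, 0.5])


def test_firing_strengths_against_product_oracle():
    """Brute-force product/normalize of memberships on a 2x2 instance."""
    model = _two_rule_model()
    x = np.array([0.35, 0.55])
    raw = []
    for rule in model.rules:
        w = 1.0
        for mf, xi in zip(rule.premises, x):
            w *= membership(mf, xi)
        raw.append(w)
    expected = np.array(raw) / sum(raw)
    assert firing_strengths(model, x) == pytest.approx(expected, rel=1e-12)


def test_forward_against_layer_oracle():
    """Layers 4-5 by hand: weighted linear consequents, summed."""
    model = _two_rule_model()
    x = np.array([0.35, 0.55])
    wbar = firing_strengths(model, x)
    expected = sum(
        w * (np.dot(rule.consequent_coeffs, x) + rule.consequent_bias)
        for w, rule in zip(wbar, model.rules)
    )
    assert forward(model, x) == pytest.approx(expected, rel=1e-12)


def test_single_rule_model_is_exactly_linear():
    rng = np.random.default_rng(7)
    rule = SugenoRule(
        premises=(GaussianMF(0.3, 0.2), GaussianMF(0.9, 0.5), GaussianMF(0.1, 0.1)),
        consequent_coeffs=(1.5, -2.0, 0.25),
        consequent_bias=0.75,
    )
    model = AnfisModel(rules=(rule,), input_scaling=((0, 1),) * 3)
    X = rng.uniform(-1, 2, size=(1000, 3))
    expected = X @ np.array(rule.consequent_coeffs) + rule.consequent_bias
    np.testing.assert_array_equal(forward(model, X), expected)


def test_zero_consequents_give_zero_output():
    rng = np.random.default_rng(3)
    model = random_model(rng, 4, 5)
    zero = decode(
        np.concatenate([encode(model).values[: 2 * 4 * 5], np.zeros(5 * 5)]),
        4, 5, model.input_scaling,
    )
    assert forward(zero, rng.uniform(0, 1, size=(50, 4))) == pytest.approx(0.0)


@settings(max_examples=50, deadline=None)
@given(st.integers(0, 2**32 - 1), st.integers(1, 6), st.integers(1, 8))
def test_normalization_sums_to_one(seed, n_inputs, n_rules):
    rng = np.random.default_rng(seed)
    model = random_model(rng, n_inputs, n_rules)
    x = rng.uniform(-0.5, 1.5, size=n_inputs)
    w = firing_strengths(model, x)
    assert np.all(w >= 0)
    assert abs(w.sum() - 1.0) < 1e-9


@pytest.mark.parametrize(
    "n_inputs, n_rules, expected",
    [(27, 10, 820), (13, 10, 400), (8, 10, 250), (1, 1, 4)],
)
def test_parameter_count(n_inputs, n_rules, expected):
    assert parameter_count(n_inputs, n_rules) == expected


def test_parameter_count_rejects_non_positive():
    with pytest.raises(ValueError):
        parameter_count(0, 10)


def test_encode_decode_round_trip_many_models():
    rng = np.random.default_rng(11)
    for _ in range(100):
        n_inputs = int(rng.integers(1, 8))
        n_rules = int(rng.integers(1, 6))
        model = random_model(rng, n_inputs, n_rules)
        back = decode(encode(model).values, n_inputs, n_rules, model.input_scaling)
        assert back == model


def test_encode_vector_length_matches_parameter_count():
    rng = np.random.default_rng(1)
    model = random_model(rng, 27, 10)
    assert encode(model).values.shape == (820,)


def test_decode_clamps_negative_sigma_to_floor():
    vec = np.ones(parameter_count(2, 1))
    vec[1] = -0.5  # first rule, first input sigma gene
    model = decode(vec, 2, 1, ((0, 1), (0, 1)))
    assert model.rules[0].premises[0].sigma == SIGMA_FLOOR


def test_decode_rejects_wrong_length():
    with pytest.raises(ValueError):
        decode(np.zeros(10), 2, 2, ((0, 1), (0, 1)))


def test_classify_threshold_convention():
    # one rule with zero slopes: output == bias for every input
    def const_model(bias):
        rule = SugenoRule(
            premises=(GaussianMF(0.5, 0.2),),
            consequent_coeffs=(0.0,),
            consequent_bias=bias,
        )
        return AnfisModel(rules=(rule,), input_scaling=((0, 1),))

    x = np.array([[0.4]])
    assert classify(const_model(0.5), x) == 1   # boundary -> malignant
    assert classify(const_model(0.0), x) == 0
    assert classify(const_model(0.93), x) == 1


def test_forward_batch_matches_per_model_forward():
    rng = np.random.default_rng(5)
    X = rng.uniform(0, 1, size=(40, 3))
    pop = []
    expected = []
    for _ in range(6):
        m = random_model(rng, 3, 4)
        pop.append(encode(m).values)
        expected.append(forward(m, X))
    got = forward_batch(np.array(pop), 3, 4, X)
    np.testing.assert_allclose(got, np.array(expected), rtol=1e-12)


def test_scaling_maps_training_extrema_to_unit_interval():
    X = np.array([[1.0, 5.0], [3.0, 5.0], [2.0, 5.0]])
    scaling = fit_scaling(X)
    S = apply_scaling(scaling, X)
    assert S[:, 0].min() == 0.0 and S[:, 0].max() == 1.0
    # constant column maps to the middle of the axis
    assert np.all(S[:, 1] == 0.5)


def test_model_serialization_is_bit_exact(tmp_path):
    rng = np.random.default_rng(17)
    model = random_model(rng, 5, 3)
    path = tmp_path / "model.json"
    save_model(model, path)
    assert load_model(path) == model
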