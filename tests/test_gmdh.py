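"""GMDH core: quadratic neurons, layer selection, end-to-end fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegmdh.complexity import count_parameters
from eegmdh.gmdh import (DEFAULT_SCHEDULE, FitConfig, PolynomialNeuron,
                         build_layer, fit_gmdh, fit_neuron, load_model,
                         neuron_forward, predict, save_model, score_neuron,
                         validate_model)


def make_neuron(coeffs, a=0, b=1):
    return PolynomialNeuron(a, b, np.asarray(coeffs, dtype=float))


class TestNeuronForward:
    @pytest.mark.parametrize("coeffs,x1,x2,expected", [
        ((1, 0, 0, 0, 0, 0), 5.0, -3.0, 1.0),
        ((0, 1, 1, 0, 0, 0), 2.0, 3.0, 5.0),
        ((0, 0, 0, 1, 1, 1), 2.0, 3.0, 19.0),   # 4 + 9 + 6
        ((0.5, -1, 2, 0, 1, 3), 1.0, 1.0, 5.5),
    ])
    def test_polynomial_evaluation(self, coeffs, x1, x2, expected):
        assert neuron_forward(make_neuron(coeffs), x1, x2) == pytest.approx(expected)

    def test_requires_six_coefficients(self):
        with pytest.raises(ValueError, match="6 coefficients"):
            make_neuron([1, 2, 3])

    def test_requires_distinct_inputs(self):
        with pytest.raises(ValueError, match="distinct"):
            PolynomialNeuron(2, 2, np.zeros(6))


class TestFitNeuron:
    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_recovers_generating_coefficients(self, seed):
        # generate-then-recover oracle: a noiseless quadratic surface over a
        # rank-6 design must be recovered exactly
        rng = np.random.default_rng(seed)
        b = rng.uniform(-3, 3, 6)
        x1, x2 = rng.standard_normal(20), rng.standard_normal(20)
        target = neuron_forward(make_neuron(b), x1, x2)
        np.testing.assert_allclose(fit_neuron(x1, x2, target), b, atol=1e-8)

    def test_spec_coefficients_recovered(self):
        rng = np.random.default_rng(0)
        b = np.array([0.5, -1.0, 2.0, 0.0, 1.0, 3.0])
        x1, x2 = rng.standard_normal(20), rng.standard_normal(20)
        target = neuron_forward(make_neuron(b), x1, x2)
        np.testing.assert_allclose(fit_neuron(x1, x2, target), b, atol=1e-8)

    def test_constant_degenerate_design_predicts_constant(self):
        x1, x2 = np.full(10, 2.0), np.full(10, -1.0)
        target = np.full(10, 7.0)
        coeffs = fit_neuron(x1, x2, target)
        pred = neuron_forward(make_neuron(coeffs), x1, x2)
        np.testing.assert_allclose(pred, 7.0, atol=1e-9)

    def test_six_points_interpolate_exactly(self):
        rng = np.random.default_rng(3)
        x1, x2 = rng.standard_normal(6), rng.standard_normal(6)
        target = rng.standard_normal(6)
        coeffs = fit_neuron(x1, x2, target)
        pred = neuron_forward(make_neuron(coeffs), x1, x2)
        np.testing.assert_allclose(pred, target, atol=1e-8)


class TestScoreNeuron:
    def test_perfect_neuron_scores_zero(self):
        rng = np.random.default_rng(1)
        b = rng.uniform(-1, 1, 6)
        x1, x2 = rng.standard_normal(15), rng.standard_normal(15)
        nrn = make_neuron(b)
        assert score_neuron(nrn, x1, x2, neuron_forward(nrn, x1, x2)) == pytest.approx(0.0)

    def test_constant_zero_neuron_vs_ones(self):
        nrn = make_neuron(np.zeros(6))
        assert score_neuron(nrn, np.zeros(4), np.zeros(4), np.ones(4)) == pytest.approx(1.0)

    def test_empty_validation_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            score_neuron(make_neuron(np.zeros(6)), np.array([]), np.array([]), np.array([]))


def brute_force_layer(X, Xv, y, yv, width):
    """Independent oracle: fit/score every pair with the public single-pair
    operations and take the top-k by (score, a, b)."""
    candidates = []
    for a in range(X.shape[1]):
        for b in range(a + 1, X.shape[1]):
            coeffs = fit_neuron(X[:, a], X[:, b], y)
            nrn = PolynomialNeuron(a, b, coeffs)
            candidates.append((score_neuron(nrn, Xv[:, a], Xv[:, b], yv), a, b))
    candidates.sort()
    return candidates[:width]


class TestBuildLayer:
    def test_candidate_count_bound(self, rng):
        X, Xv = rng.standard_normal((30, 3)), rng.standard_normal((10, 3))
        y, yv = rng.standard_normal(30), rng.standard_normal(10)
        layer = build_layer(X, Xv, y, yv, width=40)
        assert len(layer) == 3  # C(3,2)

    @pytest.mark.parametrize("n_cols", [4, 7, 10])
    def test_matches_brute_force_selection(self, n_cols, rng):
        X, Xv = rng.standard_normal((40, n_cols)), rng.standard_normal((15, n_cols))
        y, yv = rng.standard_normal(40), rng.standard_normal(15)
        width = 5
        layer = build_layer(X, Xv, y, yv, width=width)
        oracle = brute_force_layer(X, Xv, y, yv, width)
        assert [(n.input_a, n.input_b) for n in layer] == [(a, b) for _, a, b in oracle]
        np.testing.assert_allclose([n.criterion_score for n in layer],
                                   [s for s, _, _ in oracle], rtol=1e-8)
        scores = [n.criterion_score for n in layer]
        assert scores == sorted(scores)

    def test_tie_breaks_lexicographically(self, rng):
        # duplicated columns make pairs (0,1) and (0,2) score identically
        col = rng.standard_normal(20)
        X = np.column_stack([rng.standard_normal(20), col, col])
        Xv = X[:8]
        y, yv = rng.standard_normal(20), rng.standard_normal(20)[:8]
        layer = build_layer(X, Xv, y, yv, width=3)
        pair_scores = {(n.input_a, n.input_b): n.criterion_score for n in layer}
        tied = [p for p, s in pair_scores.items()
                if abs(s - pair_scores[(0, 1)]) < 1e-12]
        assert sorted(tied)[0] == (0, 1)

    def test_seeded_subsample_cap(self, rng):
        X, Xv = rng.standard_normal((30, 10)), rng.standard_normal((10, 10))
        y, yv = rng.standard_normal(30), rng.standard_normal(10)
        l1 = build_layer(X, Xv, y, yv, width=40, max_candidate_pairs=12, seed=5)
        l2 = build_layer(X, Xv, y, yv, width=40, max_candidate_pairs=12, seed=5)
        assert len(l1) == 12
        assert [(n.input_a, n.input_b) for n in l1] == [(n.input_a, n.input_b) for n in l2]

    def test_needs_two_columns(self, rng):
        X = rng.standard_normal((10, 1))
        with pytest.raises(ValueError, match="2 input columns"):
            build_layer(X, X, np.zeros(10), np.zeros(10), width=1)


def separable_blobs(n_per_class=30, seed=0):
    """Two linearly separable classes in 2 informative features."""
    rng = np.random.default_rng(seed)
    a = rng.normal([-2, -2], 0.3, (n_per_class, 2))
    b = rng.normal([2, 2], 0.3, (n_per_class, 2))
    X = np.vstack([a, b])
    codes = np.r_[np.ones(n_per_class, dtype=int), np.full(n_per_class, 2)]
    return X, codes


class TestFitPredict:
    def test_single_neuron_model_on_separable_blobs(self):
        X, codes = separable_blobs()
        model = fit_gmdh(X, codes, FitConfig(schedule=(1,), seed=0))
        assert len(model.layers) == 1 and len(model.layers[0]) == 1
        assert np.mean(predict(model, X) == codes) >= 0.9

    def test_structural_invariants_on_small_fit(self, small_features):
        X, codes = small_features
        model = fit_gmdh(X, codes, FitConfig(schedule=(10, 8, 5), seed=3,
                                             max_candidate_pairs=300))
        validate_model(model)
        widths = model.realized_widths()
        assert all(w <= s for w, s in zip(widths, (10, 8, 5)))
        # parameter accounting consistency with the complexity module
        assert count_parameters(widths) == 6 * sum(widths)

    def test_determinism_bit_identical(self, small_features, tmp_path):
        X, codes = small_features
        cfg = FitConfig(schedule=(8, 5), seed=11, max_candidate_pairs=200)
        m1, m2 = fit_gmdh(X, codes, cfg), fit_gmdh(X, codes, cfg)
        save_model(m1, tmp_path / "a.json")
        save_model(m2, tmp_path / "b.json")
        assert (tmp_path / "a.json").read_bytes() == (tmp_path / "b.json").read_bytes()
        np.testing.assert_array_equal(predict(m1, X), predict(m2, X))

    def test_ordinal_decode_rounds_and_clamps(self, small_features):
        X, codes = small_features
        model = fit_gmdh(X, codes, FitConfig(schedule=(5,), seed=0,
                                             max_candidate_pairs=100))
        # overwrite the output neuron so the decision value is a known constant
        out = model.layers[-1][model.output_selector]
        out.coefficients = np.array([8.7, 0, 0, 0, 0, 0.0])
        assert np.all(predict(model, X[:3]) == 8)  # clamp to K=8
        out.coefficients = np.array([2.4, 0, 0, 0, 0, 0.0])
        assert np.all(predict(model, X[:3]) == 2)  # round to nearest

    def test_one_vs_rest_mode_trains_k_networks(self, small_features):
        X, codes = small_features
        model = fit_gmdh(X, codes, FitConfig(schedule=(6, 4), seed=2,
                                             max_candidate_pairs=150,
                                             encoding_mode="one_vs_rest"))
        assert len(model.networks) == 8
        preds = predict(model, X)
        assert preds.min() >= 1 and preds.max() <= 8

    def test_input_validation(self, small_features):
        X, codes = small_features
        with pytest.raises(ValueError, match="single class"):
            fit_gmdh(X[:20], np.ones(20, dtype=int), FitConfig(schedule=(2,)))
        with pytest.raises(ValueError, match="12 training rows"):
            fit_gmdh(X[:5], codes[:5], FitConfig(schedule=(2,)))
        with pytest.raises(ValueError, match="schedule"):
            fit_gmdh(X, codes, FitConfig(schedule=()))
        model = fit_gmdh(X, codes, FitConfig(schedule=(3,), max_candidate_pairs=50))
        with pytest.raises(ValueError, match="feature columns"):
            predict(model, X[:, :10])


class TestModelIO:
    def test_save_load_round_trip_preserves_predictions(self, small_features, tmp_path):
        X, codes = small_features
        model = fit_gmdh(X, codes, FitConfig(schedule=(8, 5), seed=1,
                                             max_candidate_pairs=200))
        save_model(model, tmp_path / "m.json")
        loaded = load_model(tmp_path / "m.json")
        np.testing.assert_array_equal(predict(model, X), predict(loaded, X))

    def test_schema_has_six_coefficients_per_neuron(self, small_features, tmp_path):
        import json
        X, codes = small_features
        save_model(fit_gmdh(X, codes, FitConfig(schedule=(4,), max_candidate_pairs=60)),
                   tmp_path / "m.json")
        doc = json.loads((tmp_path / "m.json").read_text())
        assert all(len(n["coeffs"]) == 6
                   for net in doc["networks"] for layer in net["layers"] for n in layer)

    def test_truncated_file_is_a_parse_error(self, small_features, tmp_path):
        X, codes = small_features
        save_model(fit_gmdh(X, codes, FitConfig(schedule=(3,), max_candidate_pairs=50)),
                   tmp_path / "m.json")
        text = (tmp_path / "m.json").read_text()
        (tmp_path / "bad.json").write_text(text[: len(text) // 2])
        with pytest.raises(ValueError, match="malformed"):
            load_model(tmp_path / "bad.json")

    def test_version_mismatch_rejected(self, tmp_path):
        (tmp_path / "m.json").write_text('{"version": 99}')
        with pytest.raises(ValueError, match="version"):
            load_model(tmp_path / "m.json")
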