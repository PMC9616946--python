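"""Network forward/backward correctness, the Adam recurrences, tuning, baselines.

Numerical checks run on deliberately small networks; the architecture code
is size-agnostic, so correctness at (H=5, N=12) transfers to (H=100, N=100).
"""

import numpy as np
import pytest

import headernet as hn
from headernet import classifier
from headernet.classifier import (
    NetworkConfig,
    OptimizerState,
    SearchSpace,
    TrainingConfig,
    adam_step,
    expected_improvement,
    forward,
    init_model,
    loss_and_gradients,
    threshold_classify,
    tune,
)


def small_cfg(**kw):
    defaults = dict(input_axes=3, seq_len=12, hidden_units=5, fc_nodes=20,
                    classes=2)
    defaults.update(kw)
    return NetworkConfig(**defaults)


class TestInitAndShapes:
    def test_deterministic_given_seed(self):
        a = init_model(NetworkConfig(), seed=42)
        b = init_model(NetworkConfig(), seed=42)
        assert a.keys() == b.keys()
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])

    def test_parameter_count_closed_form(self):
        """Total = 2 * 4H(D + H + 1) + (2H*F + F) + (F*C + C)."""
        for D, H, F, C in [(3, 100, 43, 2), (3, 100, 20, 2), (3, 100, 100, 2)]:
            cfg = NetworkConfig(input_axes=D, hidden_units=H, fc_nodes=F,
                                classes=C)
            expected = 2 * (4 * H * (D + H + 1)) + (2 * H * F + F) + (F * C + C)
            assert classifier.parameter_count(init_model(cfg, 0)) == expected

    def test_fc_width_changes_only_two_maps(self):
        p20 = init_model(NetworkConfig(fc_nodes=20), 0)
        p100 = init_model(NetworkConfig(fc_nodes=100), 0)
        diff = classifier.parameter_count(p100) - classifier.parameter_count(p20)
        H, C = 100, 2
        assert diff == (2 * H + 1) * (100 - 20) + (100 - 20) * C


class TestForward:
    def test_probabilities_sum_to_one(self, rng):
        params = init_model(small_cfg(), 1)
        X = rng.normal(size=(7, 3, 12))
        probs = forward(params, X)
        assert probs.shape == (7, 2)
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_duplicated_event_identical_output(self, rng):
        params = init_model(small_cfg(), 2)
        x = rng.normal(size=(3, 12))
        probs = forward(params, np.stack([x, x, rng.normal(size=(3, 12))]))
        np.testing.assert_array_equal(probs[0], probs[1])

    def test_batch_permutation_equivariance(self, rng):
        params = init_model(small_cfg(), 3)
        X = rng.normal(size=(6, 3, 12))
        perm = rng.permutation(6)
        np.testing.assert_allclose(forward(params, X)[perm],
                                   forward(params, X[perm]), atol=1e-12)

    def test_wrong_shape_rejected(self, rng):
        params = init_model(small_cfg(), 4)
        with pytest.raises(ValueError, match="shaped"):
            forward(params, rng.normal(size=(5, 4, 12)))

    def test_gradients_match_central_differences(self, rng):
        """Analytic gradients of the full forward/loss path vs finite
        differences on a 2-event batch, relative error < 1e-4."""
        params = init_model(small_cfg(), 5)
        X = rng.normal(size=(2, 3, 12))
        y = np.array([0, 1])
        l2 = 1e-3
        _, grads, _ = loss_and_gradients(params, X, y, l2)
        h = 1e-6
        for key in params:
            flat = params[key].reshape(-1)
            n_probe = min(flat.size, 25)
            idx = rng.choice(flat.size, size=n_probe, replace=False)
            for i in idx:
                orig = flat[i]
                flat[i] = orig + h
                lp, _, _ = loss_and_gradients(params, X, y, l2)
                flat[i] = orig - h
                lm, _, _ = loss_and_gradients(params, X, y, l2)
                flat[i] = orig
                numeric = (lp - lm) / (2 * h)
                analytic = grads[key].reshape(-1)[i]
                denom = max(abs(numeric), abs(analytic), 1e-8)
                assert abs(numeric - analytic) / denom < 1e-4, key


class TestAdam:
    def test_first_step_matches_hand_computation(self):
        """m1 = 0.1, v1 = 0.01, update = 0.1 * 0.1 / (0.1 + 1e-8)."""
        params = {"w": np.array([0.0])}
        grads = {"w": np.array([1.0])}
        state = OptimizerState.zeros_like(params)
        cfg = TrainingConfig(learning_rate=0.1)
        params, state = adam_step(params, grads, state, cfg)
        assert state.m["w"][0] == pytest.approx(0.1)
        assert state.v["w"][0] == pytest.approx(0.01)
        assert params["w"][0] == pytest.approx(-0.1 * 0.1 / (0.1 + 1e-8))
        assert state.iteration == 1

    def test_zero_gradient_from_zero_state_is_noop(self):
        params = {"w": np.array([1.5, -2.0])}
        state = OptimizerState.zeros_like(params)
        params, _ = adam_step(params, {"w": np.zeros(2)}, state,
                              TrainingConfig())
        np.testing.assert_array_equal(params["w"], [1.5, -2.0])

    def test_scripted_steps_match_independent_recurrence(self):
        """Minimize 0.5*w^2: five steps against a from-scratch iteration of
        the printed moving-average recurrences, agreement to 1e-12."""
        cfg = TrainingConfig(learning_rate=0.05)
        params = {"w": np.array([2.0])}
        state = OptimizerState.zeros_like(params)
        # independent oracle (plain floats, no shared code path)
        w, m, v = 2.0, 0.0, 0.0
        for _ in range(5):
            g = w  # d/dw 0.5 w^2
            params, state = adam_step(params, {"w": np.array([g])}, state, cfg)
            m = cfg.beta1 * m + (1 - cfg.beta1) * g
            v = cfg.beta2 * v + (1 - cfg.beta2) * g * g
            w = w - cfg.learning_rate * m / (np.sqrt(v) + cfg.eps)
            assert params["w"][0] == pytest.approx(w, abs=1e-12)

    def test_bias_corrected_variant_differs_as_standard_adam(self):
        cfg = TrainingConfig(learning_rate=0.1, bias_correction=True)
        params = {"w": np.array([0.0])}
        state = OptimizerState.zeros_like(params)
        params, _ = adam_step(params, {"w": np.array([1.0])}, state, cfg)
        # with correction the first update is alpha * g / (|g| + eps') ~ alpha
        assert params["w"][0] == pytest.approx(-0.1, rel=1e-5)

    def test_non_finite_gradient_raises_diagnostic(self):
        params = {"w": np.array([0.0])}
        state = OptimizerState.zeros_like(params)
        with pytest.raises(FloatingPointError, match="w"):
            adam_step(params, {"w": np.array([np.nan])}, state, TrainingConfig())


class TestTraining:
    TOY_CFG = dict(learning_rate=0.02, batch_size=32, l2=1e-4, epochs=3)

    def test_toy_problem_high_accuracy(self, toy_data):
        """Smooth header pulses vs narrow spikes separate within 3 epochs:
        mean validation sensitivity and specificity over 3 seeds >= 0.95."""
        train_xy, val_xy = toy_data
        net = small_cfg(seq_len=100, hidden_units=32)
        cfg = dict(learning_rate=0.005, batch_size=8, l2=1e-4, epochs=3,
                   val_check_steps=3)
        sens, spec = [], []
        for seed in range(3):
            params = init_model(net, 100 + seed)
            params, _ = classifier.train(params, train_xy, val_xy,
                                         TrainingConfig(**cfg, seed=seed))
            pred = classifier.predict(params, val_xy[0])
            pos, neg = val_xy[1] == 1, val_xy[1] == 0
            sens.append((pred[pos] == 1).mean())
            spec.append((pred[neg] == 0).mean())
        assert np.mean(sens) >= 0.95
        assert np.mean(spec) >= 0.95

    def test_seeded_history_bit_identical(self, toy_data):
        train_xy, val_xy = toy_data
        net = small_cfg(seq_len=100, hidden_units=6)
        runs = []
        for _ in range(2):
            params = init_model(net, 3)
            _, hist = classifier.train(params, train_xy, val_xy,
                                       TrainingConfig(**self.TOY_CFG, seed=9))
            runs.append(hist)
        assert runs[0] == runs[1]

    def test_larger_l2_shrinks_weights(self, toy_data):
        train_xy, val_xy = toy_data
        net = small_cfg(seq_len=100, hidden_units=6)
        norms = {}
        for l2 in (1e-8, 1e-1):
            params = init_model(net, 11)
            cfg = TrainingConfig(learning_rate=0.02, batch_size=32, l2=l2,
                                 epochs=3, seed=2)
            params, _ = classifier.train(params, train_xy, val_xy, cfg)
            norms[l2] = classifier.weight_norm(params)
        assert norms[1e-1] < norms[1e-8]

    def test_training_loss_decreases_on_toy(self, toy_data):
        """Mean first-epoch improvement across 5 seeds is positive."""
        train_xy, val_xy = toy_data
        net = small_cfg(seq_len=100, hidden_units=6)
        deltas = []
        for seed in range(5):
            params = init_model(net, seed)
            cfg = TrainingConfig(learning_rate=0.02, batch_size=32, l2=1e-4,
                                 epochs=2, seed=seed)
            _, hist = classifier.train(params, train_xy, val_xy, cfg)
            deltas.append(hist["train_loss"][0] - hist["train_loss"][1])
        assert np.mean(deltas) > 0

    def test_empty_set_rejected(self, toy_data):
        train_xy, _ = toy_data
        params = init_model(small_cfg(seq_len=100), 0)
        with pytest.raises(ValueError, match="nonempty"):
            classifier.train(params, train_xy,
                             (np.empty((0, 3, 100)), np.empty(0, dtype=int)),
                             TrainingConfig())


class TestTune:
    def test_reference_tuned_values_inside_ranges(self):
        space = SearchSpace()
        assert space.contains({"learning_rate": 0.168, "batch_size": 119,
                               "l2": 0.0016, "fc_nodes": 43})

    def test_proposals_never_leave_the_box(self):
        space = SearchSpace()
        rng = np.random.default_rng(0)
        observations = [(space.from_unit(rng.uniform(size=4)),
                         float(rng.uniform())) for _ in range(6)]
        for _ in range(20):
            x = classifier.propose_next(space, observations, rng)
            assert space.contains(x)
            observations.append((x, float(rng.uniform())))

    def test_search_finds_low_region_of_synthetic_objective(self):
        """On a smooth objective with one basin, the best found beats the
        median of all evaluations and the search box is respected."""
        target = np.array([0.2, 0.5, 0.8, 0.3])
        space = SearchSpace()

        def objective(x):
            return float(((space.to_unit(x) - target) ** 2).sum())

        result = tune(None, None, space=space, budget=10, seed=4,
                      n_initial=5, objective=objective)
        errors = [e for _, e in result.observations]
        assert result.best_error <= np.median(errors)
        assert result.best_error == min(errors)
        assert len(result.observations) == 10

    def test_budget_below_initial_design_rejected(self):
        with pytest.raises(ValueError, match="budget"):
            tune(None, None, budget=1, objective=lambda x: 0.0)

    def test_expected_improvement_properties(self):
        # no improvement possible when the posterior mean is far above best
        ei_bad = expected_improvement(np.array([2.0]), np.array([0.01]), 1.0)
        ei_good = expected_improvement(np.array([0.5]), np.array([0.01]), 1.0)
        assert ei_good[0] > ei_bad[0] >= 0.0


class TestThresholdBaseline:
    def test_twelve_g_peak_against_both_thresholds(self, rng):
        trace = np.zeros((3, 100))
        trace[0, 50] = 12.0
        assert threshold_classify([trace], 10.0) == ["VH"]
        assert threshold_classify([trace], 16.0) == ["NH"]

    def test_agrees_with_per_sample_scan(self, waveform_params):
        """Vectorized peak-resultant rule vs an explicit per-sample loop."""
        rng = np.random.default_rng(8)
        traces = [hn.simulate_header_trace(waveform_params, rng)
                  for _ in range(50)]
        traces += [hn.simulate_nonheader_trace(waveform_params, rng)
                   for _ in range(50)]
        for thr in (10.0, 16.0):
            got = threshold_classify(traces, thr)
            for trace, label in zip(traces, got):
                peak = 0.0
                for t in range(trace.shape[1]):
                    mag = (trace[0, t] ** 2 + trace[1, t] ** 2
                           + trace[2, t] ** 2) ** 0.5
                    peak = max(peak, mag)
                assert label == ("VH" if peak > thr else "NH")


class TestSerialization:
    def test_model_round_trip(self, tmp_path):
        cfg = small_cfg()
        params = init_model(cfg, 13)
        tcfg = TrainingConfig(learning_rate=0.05, seed=3)
        path = tmp_path / "model.json"
        classifier.save_model(params, cfg, tcfg, path)
        back, net, tr = classifier.load_model(path)
        assert net == cfg and tr == tcfg
        for k in params:
            np.testing.assert_array_equal(params[k], back[k])
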