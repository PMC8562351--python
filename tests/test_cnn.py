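"""The 1D convolutional ND classifier: architecture, training, prediction."""

import numpy as np
import pytest

from lssnd import cnn


def oracle_param_count(n, spec):
    """Independent layer-shape recurrence for the trainable-parameter count."""
    def conv_out(n):
        if spec.conv_padding == "same":
            return int(np.ceil(n / spec.conv_stride))
        return (n - spec.conv_kernel) // spec.conv_stride + 1

    def pool_out(n):
        return (n - spec.pool_size) // spec.pool_stride + 1

    k, f = spec.conv_kernel, spec.conv_filters
    total = 0
    c = 1
    for layer in ("c", "c", "p", "c", "p"):
        if layer == "c":
            total += k * c * f + f
            n, c = conv_out(n), f
        else:
            n = pool_out(n)
        if n < 1:
            raise ValueError("too short")
    total += n * c * spec.n_classes + spec.n_classes
    return total


def make_separable(n_per_class=30, length=120, seed=0):
    """Three linearly separable spectrum classes (distinct mean shift)."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for c, shift in enumerate((-1.0, 0.0, 1.0)):
        X.append(rng.normal(shift, 0.05, size=(n_per_class, length)))
        y += [c] * n_per_class
    return np.vstack(X).astype(np.float32), np.array(y)


class TestArchitecture:
    def test_output_is_probability_distribution(self):
        net = cnn.build_network(146)
        probs = net.predict_proba(np.random.default_rng(0).normal(
            size=(11, 146)))
        assert np.all(probs >= 0)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_parameter_count_for_length_146(self):
        # conv params 18 + 48 + 48; flatten 3x3=9 -> dense 30
        net = cnn.build_network(146)
        assert cnn.count_trainable_parameters(net) == 18 + 48 + 48 + 30

    def test_parameter_count_matches_oracle_across_settings(self):
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 20:
            n = int(rng.integers(40, 2000))
            padding = ("valid", "same")[int(rng.integers(2))]
            spec = cnn.NetworkSpec(conv_padding=padding)
            try:
                expected = oracle_param_count(n, spec)
            except ValueError:
                continue
            net = cnn.build_network(n, spec)
            assert cnn.count_trainable_parameters(net) == expected
            checked += 1

    def test_doubling_length_changes_only_dense(self):
        a = cnn.build_network(200)
        b = cnn.build_network(400)
        diff = cnn.count_trainable_parameters(b) - \
            cnn.count_trainable_parameters(a)
        flat_a = a.plan[-1][2]
        flat_b = b.plan[-1][2]
        assert diff == 3 * (flat_b - flat_a)

    def test_too_short_input_names_failing_layer(self):
        with pytest.raises(cnn.InputTooShortError, match="conv"):
            cnn.build_network(6)

    def test_count_invariant_to_seed(self):
        net = cnn.build_network(100)
        before = cnn.count_trainable_parameters(net)
        net.init_params(np.random.default_rng(99))
        assert cnn.count_trainable_parameters(net) == before


class TestEngines:
    def test_numba_and_numpy_engines_agree(self):
        X, y = make_separable(n_per_class=20, length=100)
        cfgs = [cnn.TrainingConfig(learning_rate=lr, min_delta=0.001,
                                   patience_epochs=10, max_epochs=10, seed=i)
                for i, lr in enumerate((0.002, 0.01))]
        out_np = cnn.train_population(100, cnn.NetworkSpec(), cfgs, X, y,
                                      perm_seed=3, engine="numpy")
        out_nb = cnn.train_population(100, cnn.NetworkSpec(), cfgs, X, y,
                                      perm_seed=3, engine="numba")
        for a, b in zip(out_np, out_nb):
            assert np.allclose(a.history, b.history, atol=1e-5)
            assert abs(a.best_loss - b.best_loss) < 1e-5

    def test_population_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        pop = cnn._Population(146, cnn.NetworkSpec(), 2, dtype=np.float64)
        for m in range(2):
            pop.load(m, cnn._glorot_init(pop.shapes,
                                         np.random.default_rng(m), np.float64))
        X = rng.normal(size=(5, 146))
        y = rng.integers(0, 3, 5)

        def losses():
            logits = pop.forward(X)
            z = logits - logits.max(2, keepdims=True)
            lse = np.log(np.exp(z).sum(2))
            return (lse - z[:, np.arange(5), y]).mean(1)

        cache = {}
        logits = pop.forward(X, cache)
        z = logits - logits.max(2, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(2, keepdims=True)
        d = p.copy()
        d[:, np.arange(5), y] -= 1
        d /= 5
        g = np.zeros_like(pop.flat)
        pop.backward(d, cache, g)
        eps = 1e-6
        for _ in range(15):
            m, i = rng.integers(2), rng.integers(pop.P)
            pop.flat[m, i] += eps
            lp = losses()[m]
            pop.flat[m, i] -= 2 * eps
            lm = losses()[m]
            pop.flat[m, i] += eps
            num = (lp - lm) / (2 * eps)
            assert abs(num - g[m, i]) < 1e-6 + 1e-4 * abs(num)


class TestTraining:
    def test_separable_data_reaches_perfect_training_accuracy(self):
        X, y = make_separable()
        net = cnn.build_network(X.shape[1])
        cfg = cnn.TrainingConfig(learning_rate=0.01, min_delta=0.001,
                                 patience_epochs=50, max_epochs=400, seed=0)
        trained = cnn.train_with_early_stopping(net, X, y, cfg)
        pred, _ = cnn.predict_classes(trained, X)
        assert np.mean(pred == y) == 1.0
        assert len(trained.history) < cfg.max_epochs

    def test_seeded_determinism(self):
        X, y = make_separable(n_per_class=15)
        cfg = cnn.TrainingConfig(learning_rate=0.005, min_delta=0.001,
                                 patience_epochs=20, max_epochs=40, seed=11)
        runs = []
        for _ in range(2):
            net = cnn.build_network(X.shape[1])
            runs.append(cnn.train_with_early_stopping(net, X, y, cfg))
        for key in runs[0].network.params:
            assert np.array_equal(runs[0].network.params[key],
                                  runs[1].network.params[key])
        assert runs[0].history == runs[1].history

    def test_restored_weights_are_minimum_loss_checkpoint(self):
        X, y = make_separable(n_per_class=10)
        net = cnn.build_network(X.shape[1])
        cfg = cnn.TrainingConfig(learning_rate=0.02, min_delta=0.005,
                                 patience_epochs=15, max_epochs=60, seed=2)
        trained = cnn.train_with_early_stopping(net, X, y, cfg)
        assert trained.best_loss <= min(trained.history) + 1e-12
        assert np.isclose(trained.history[trained.best_epoch],
                          trained.best_loss)

    def test_empty_training_set_rejected(self):
        net = cnn.build_network(100)
        with pytest.raises(ValueError):
            cnn.train_with_early_stopping(net, np.zeros((0, 100)),
                                          np.zeros(0, int))

    def test_single_class_warns(self):
        X = np.random.default_rng(0).normal(size=(8, 100)).astype(np.float32)
        cfg = cnn.TrainingConfig(max_epochs=2, patience_epochs=2)
        with pytest.warns(UserWarning, match="single-class"):
            cnn.train_with_early_stopping(cnn.build_network(100), X,
                                          np.zeros(8, int), cfg)


class TestPrediction:
    def test_tie_breaks_toward_lower_class_index(self):
        net = cnn.build_network(146)
        # zero weights -> identical logits -> argmax returns class 0 (low)
        for key in net.params:
            net.params[key] = np.zeros_like(net.params[key])
        pred, probs = cnn.predict_classes(
            net, np.random.default_rng(0).normal(size=(5, 146)))
        assert np.allclose(probs, 1.0 / 3)
        assert np.all(pred == 0)

    def test_length_mismatch_rejected(self):
        net = cnn.build_network(146)
        with pytest.raises(ValueError, match="length"):
            net.forward(np.zeros((3, 99)))
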