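"""Network mechanics: forward/backward correctness, training, splitting.

The gradient-vs-finite-differences check is the load-bearing test of the
module: everything else (training, early stopping) builds on it.
"""

import math

import numpy as np
import pytest
from scipy import stats

from mrresponse import bpnn
from mrresponse.bpnn import (
    NetworkConfig,
    TrainingDiverged,
    forward,
    gradient,
    init_network,
    loss,
    split_data,
    train,
)


def node_by_node_forward(state, x):
    """Independent matrix-free evaluator: explicit Python loops per node."""
    acts = {"tanh": math.tanh, "identity": lambda v: v,
            "logistic": lambda v: 1.0 / (1.0 + math.exp(-v))}
    h = list(x)
    last = state.n_layers - 1
    for l, (w, b) in enumerate(zip(state.weights, state.biases)):
        act = acts[state.output_activation if l == last else state.hidden_activation]
        h = [act(sum(w[j][k] * h[k] for k in range(len(h))) + b[j])
             for j in range(w.shape[0])]
    return np.array(h)


def flat_fd_gradient(state, x, y, eps=1e-6):
    """Central finite differences on every weight and bias."""
    gw, gb = [], []
    for arrs, grads in ((state.weights, gw), (state.biases, gb)):
        for a in arrs:
            g = np.zeros_like(a)
            for idx in np.ndindex(a.shape):
                a[idx] += eps
                e1, _ = loss(state, x, y)
                a[idx] -= 2 * eps
                e2, _ = loss(state, x, y)
                a[idx] += eps
                g[idx] = (e1 - e2) / (2 * eps)
            grads.append(g)
    return gw, gb


class TestInitNetwork:
    def test_zero_scale_gives_zero_weights(self):
        st = init_network(NetworkConfig(n_inputs=3, init_scale=0.0))
        assert all(np.all(w == 0) for w in st.weights)

    def test_same_seed_identical_state(self):
        cfg = NetworkConfig(n_inputs=4, seed=9)
        a, b = init_network(cfg), init_network(cfg)
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_weights_uniform_on_interval(self):
        """KS test of ~1e5 weight draws against Uniform(-s, s)."""
        cfg = NetworkConfig(n_inputs=1000, hidden_layout=(100,), init_scale=0.5, seed=0)
        st = init_network(cfg)
        draws = st.weights[0].ravel()
        assert draws.size == 100_000
        ks = stats.kstest(draws, stats.uniform(loc=-0.5, scale=1.0).cdf)
        assert ks.pvalue > 0.01
        assert all(np.all(b == 0) for b in st.biases)


class TestForward:
    def test_zero_network_outputs_zero(self):
        st = init_network(NetworkConfig(n_inputs=3, init_scale=0.0))
        assert forward(st, np.array([1.0, -2.0, 3.0])) == pytest.approx(0.0)

    def test_single_linear_path_hand_computed(self):
        cfg = NetworkConfig(
            n_inputs=1, hidden_layout=(1,), hidden_activation="identity",
            output_activation="identity", init_scale=0.0,
        )
        st = init_network(cfg)
        st.weights[0][0, 0] = 2.0
        st.biases[0][0] = 1.0
        st.weights[1][0, 0] = -3.0
        st.biases[1][0] = 0.5
        # x=4: hidden = 2*4+1 = 9; out = -3*9+0.5 = -26.5
        assert forward(st, np.array([4.0]))[0] == pytest.approx(-26.5)

    @pytest.mark.parametrize("layout", [(6,), (4, 3)])
    @pytest.mark.parametrize("out_act", ["identity", "tanh"])
    def test_matches_node_by_node_oracle(self, rng, layout, out_act):
        cfg = NetworkConfig(
            n_inputs=5, hidden_layout=layout, output_activation=out_act, seed=11
        )
        st = init_network(cfg)
        for _ in range(5):
            x = rng.normal(size=5)
            np.testing.assert_allclose(
                forward(st, x), node_by_node_forward(st, x), atol=1e-12
            )

    def test_dimension_mismatch_rejected(self):
        st = init_network(NetworkConfig(n_inputs=3))
        with pytest.raises(ValueError, match="inputs"):
            forward(st, np.ones(4))


class TestLoss:
    def test_perfect_predictions_zero(self):
        st = init_network(NetworkConfig(n_inputs=2, init_scale=0.0))
        e, rmse = loss(st, np.zeros((3, 2)), np.zeros((3, 1)))
        assert e == 0.0 and rmse == 0.0

    def test_half_sum_of_squares_and_rmse(self):
        """Two patterns with errors {1, -1}: E = 1, RMSE = 1."""
        st = init_network(NetworkConfig(n_inputs=1, init_scale=0.0))
        y = np.array([[-1.0], [1.0]])  # outputs are 0
        e, rmse = loss(st, np.zeros((2, 1)), y)
        assert e == pytest.approx(1.0)
        assert rmse == pytest.approx(1.0)

    def test_matches_independent_sum(self, rng):
        cfg = NetworkConfig(n_inputs=4, seed=2)
        st = init_network(cfg)
        x, y = rng.normal(size=(6, 4)), rng.normal(size=(6, 1))
        e, rmse = loss(st, x, y)
        out = np.array([node_by_node_forward(st, xi) for xi in x])
        e_ref = 0.5 * sum((y[i, 0] - out[i, 0]) ** 2 for i in range(6))
        assert e == pytest.approx(e_ref, rel=1e-12)
        assert rmse == pytest.approx(math.sqrt(2 * e_ref / 6), rel=1e-12)

    def test_empty_dataset_rejected(self):
        st = init_network(NetworkConfig(n_inputs=2))
        with pytest.raises(ValueError, match="empty"):
            loss(st, np.empty((0, 2)), np.empty((0, 1)))


class TestGradient:
    def test_zero_error_gives_zero_gradient(self):
        st = init_network(NetworkConfig(n_inputs=2, init_scale=0.0))
        x = np.ones((4, 2))
        y = forward(st, x)
        gw, gb = gradient(st, x, y)
        assert all(np.all(g == 0) for g in gw + gb)

    def test_matches_central_finite_differences_on_random_nets(self, rng):
        """<= 1e-6 relative agreement on 10 random networks."""
        for seed in range(10):
            cfg = NetworkConfig(
                n_inputs=4, hidden_layout=(5,), output_activation="identity", seed=seed
            )
            st = init_network(cfg)
            x = rng.normal(size=(6, 4))
            y = rng.normal(size=(6, 1))
            gw, gb = gradient(st, x, y)
            fw, fb = flat_fd_gradient(st, x, y)
            for g, f in zip(gw + gb, fw + fb):
                np.testing.assert_allclose(g, f, rtol=1e-6, atol=1e-9)

    def test_linear_net_matches_least_squares_gradient(self, rng):
        """No hidden layer + identity output: dE/dW = (XW' + b - y)' X."""
        cfg = NetworkConfig(
            n_inputs=3, hidden_layout=(), output_activation="identity", seed=4
        )
        st = init_network(cfg)
        x = rng.normal(size=(8, 3))
        y = rng.normal(size=(8, 1))
        resid = x @ st.weights[0].T + st.biases[0] - y
        gw, gb = gradient(st, x, y)
        np.testing.assert_allclose(gw[0], resid.T @ x, rtol=1e-12)
        np.testing.assert_allclose(gb[0], resid.sum(axis=0), rtol=1e-12)


class TestTrain:
    def _linear_data(self, rng, n=40, d=4):
        x = rng.normal(size=(n, d))
        beta = rng.normal(size=d)
        y = (x @ beta)[:, None] * 0.1
        return x, y

    def test_realizable_linear_target_is_driven_to_zero(self, rng):
        x, y = self._linear_data(rng)
        cfg = NetworkConfig(
            n_inputs=4, hidden_layout=(), output_activation="identity",
            eta=0.01, max_epochs=400, patience=400, rmse_tol=1e-8, seed=1,
        )
        state, trace = train(cfg, (x[:30], y[:30]), (x[30:], y[30:]))
        assert trace.train_rmse[-1] < 1e-6
        assert trace.best_epoch == len(trace.val_rmse)
        assert trace.stopped_reason in ("converged", "max_epochs")

    def test_single_epoch_boundary(self, rng):
        x, y = self._linear_data(rng)
        cfg = NetworkConfig(n_inputs=4, max_epochs=1, patience=0, seed=1)
        _, trace = train(cfg, (x[:30], y[:30]), (x[30:], y[30:]))
        assert len(trace.val_rmse) == 1 and trace.best_epoch == 1

    def test_returned_state_attains_minimum_validation_rmse(self, rng):
        x = rng.normal(size=(40, 4))
        y = np.tanh(x[:, :1]) + 0.5 * rng.normal(size=(40, 1))
        cfg = NetworkConfig(n_inputs=4, max_epochs=80, patience=15, seed=3)
        state, trace = train(cfg, (x[:24], y[:24]), (x[24:], y[24:]))
        _, val_rmse = loss(state, x[24:], y[24:])
        assert val_rmse == pytest.approx(min(trace.val_rmse), rel=1e-12)
        assert trace.val_rmse[trace.best_epoch - 1] == min(trace.val_rmse)

    def test_sequential_epoch_approaches_batch_step_as_eta_vanishes(self, rng):
        """First-order agreement: Delta_w / eta -> -dE/dw as eta -> 0."""
        x, y = self._linear_data(rng, n=12)
        eta = 1e-7
        cfg = NetworkConfig(
            n_inputs=4, hidden_layout=(3,), output_activation="identity",
            eta=eta, max_epochs=1, patience=0, seed=5,
        )
        st0 = init_network(cfg)
        gw, gb = gradient(st0, x, y)
        st1, _ = train(cfg, (x, y), (x, y))
        for w1, w0, g in zip(st1.weights, st0.weights, gw):
            np.testing.assert_allclose((w1 - w0) / eta, -g, rtol=1e-4)

    def test_constant_features_converge_to_target_mean(self, rng):
        """Linear output + squared loss: the optimum under constant inputs
        is the training-set target mean."""
        x = np.ones((20, 2))
        y = rng.normal(2.0, 0.5, size=(20, 1))
        cfg = NetworkConfig(
            n_inputs=2, hidden_layout=(), output_activation="identity",
            eta=0.01, max_epochs=600, patience=600, seed=0,
        )
        state, _ = train(cfg, (x, y), (x, y))
        assert forward(state, x)[0, 0] == pytest.approx(y.mean(), abs=1e-4)

    def test_divergence_raises_with_epoch(self, rng):
        x = rng.normal(size=(30, 6)) * 10
        y = rng.normal(size=(30, 1)) * 1e6
        cfg = NetworkConfig(
            n_inputs=6, output_activation="identity", eta=0.9, max_epochs=200,
            patience=200, seed=0,
        )
        with pytest.raises(TrainingDiverged, match="epoch"):
            with np.errstate(all="ignore"):
                train(cfg, (x, y), (x, y))

    def test_scg_minimizes_realizable_problem(self, rng):
        x, y = self._linear_data(rng)
        cfg = NetworkConfig(
            n_inputs=4, hidden_layout=(3,), output_activation="identity",
            optimizer="scg", max_epochs=500, patience=100, seed=2,
        )
        _, trace = train(cfg, (x[:30], y[:30]), (x[30:], y[30:]))
        assert trace.train_rmse[-1] < 0.2 * trace.train_rmse[0]
        assert min(trace.train_rmse) < 1e-3


class TestSplitData:
    def test_study_split_sizes(self):
        s = split_data(32, (0.5, 0.25, 0.25), seed=0)
        assert (s.train.size, s.validation.size, s.test.size) == (16, 8, 8)

    def test_deterministic_given_seed(self):
        a = split_data(32, seed=5)
        b = split_data(32, seed=5)
        np.testing.assert_array_equal(a.train, b.train)
        np.testing.assert_array_equal(a.test, b.test)

    def test_partition_covers_everything_disjointly(self):
        s = split_data(33, (0.5, 0.25, 0.25), seed=1)
        union = np.sort(np.concatenate([s.train, s.validation, s.test]))
        np.testing.assert_array_equal(union, np.arange(33))

    def test_stratified_counts_proportional_per_group(self):
        """Each of 4 groups of 8 must contribute 4/2/2 to the three splits."""
        groups = np.repeat(["a", "b", "c", "d"], 8)
        s = split_data(32, (0.5, 0.25, 0.25), seed=3, groups=groups)
        for part, expected in ((s.train, 4), (s.validation, 2), (s.test, 2)):
            labels, counts = np.unique(groups[part], return_counts=True)
            assert list(labels) == ["a", "b", "c", "d"]
            assert all(c == expected for c in counts)

    def test_empty_split_rejected(self):
        with pytest.raises(ValueError):
            split_data(4, (0.9, 0.05, 0.05), seed=0)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            split_data(32, (0.5, 0.3, 0.3), seed=0)


class TestNetworkConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"eta": 0.0},
            {"eta": 1.0},
            {"optimizer": "adam"},
            {"hidden_activation": "relu6"},
            {"max_epochs": 0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            NetworkConfig(**kwargs)
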