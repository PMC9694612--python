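"""Perceptron forward pass, loss, analytic gradient and training protocol."""

import numpy as np
import pytest

from anisann import (
    MLPParams,
    MLPRegressor,
    SplitIndices,
    TrainingConfig,
    forward,
    loss_gradient,
    overall_performance,
    search_architectures,
    sos_loss,
    train_mlp,
)
from anisann.mlp import ACTIVATIONS, ShapeError, load_params_text, save_params_text


def random_params(rng, n_in, n_hid, n_out, acts=("tanh", "identity"), scale=0.5):
    return MLPParams(
        W1=rng.uniform(-scale, scale, (n_in, n_hid)),
        B1=rng.uniform(-scale, scale, n_hid),
        W2=rng.uniform(-scale, scale, (n_hid, n_out)),
        B2=rng.uniform(-scale, scale, n_out),
        hidden_activation=acts[0],
        output_activation=acts[1],
    )


def forward_two_loop(params, X):
    """Independent per-row, per-unit evaluation of the network composition."""
    f1 = ACTIVATIONS[params.output_activation][0]
    f2 = ACTIVATIONS[params.hidden_activation][0]
    out = np.empty((len(X), params.n_outputs))
    for r, x in enumerate(X):
        hidden = np.empty(params.n_hidden)
        for k in range(params.n_hidden):
            acc = params.B1[k]
            for i in range(params.n_inputs):
                acc += x[i] * params.W1[i, k]
            hidden[k] = f2(acc)
        for j in range(params.n_outputs):
            acc = params.B2[j]
            for k in range(params.n_hidden):
                acc += hidden[k] * params.W2[k, j]
            out[r, j] = f1(acc)
    return out


class TestForward:
    def test_zero_network_is_zero_map(self):
        p = MLPParams(np.zeros((3, 2)), np.zeros(2), np.zeros((2, 4)), np.zeros(4),
                      "identity", "identity")
        assert np.all(forward(p, np.ones((5, 3))) == 0)

    def test_hand_affine_composition(self):
        # 2 inputs -> 1 hidden -> 1 output, identity: hidden 1+2=3, out 2*3+3=9
        p = MLPParams(np.array([[1.0], [1.0]]), np.array([0.0]),
                      np.array([[2.0]]), np.array([3.0]), "identity", "identity")
        assert forward(p, np.array([[1.0, 2.0]]))[0, 0] == pytest.approx(9.0)

    def test_zero_weights_exponential_gives_one(self):
        p = MLPParams(np.zeros((4, 3)), np.zeros(3), np.zeros((3, 2)), np.zeros(2),
                      "exponential", "exponential")
        # hidden units e^0 = 1; outputs e^(0·1+0) = 1
        assert np.allclose(forward(p, np.ones((6, 4))), 1.0)

    def test_dimension_mismatch_raises_shape_error(self):
        rng = np.random.default_rng(0)
        p = random_params(rng, 4, 3, 2)
        with pytest.raises(ShapeError, match="input width"):
            forward(p, np.ones((5, 7)))

    @pytest.mark.parametrize("acts", [("identity", "identity"),
                                      ("logistic", "tanh"),
                                      ("exponential", "exponential")])
    def test_vectorized_equals_two_loop_oracle(self, acts):
        rng = np.random.default_rng(17)
        for _ in range(10):
            p = random_params(rng, 5, 4, 3, acts)
            X = rng.uniform(-1, 1, (8, 5))
            assert np.allclose(forward(p, X), forward_two_loop(p, X), atol=1e-12)


class TestLoss:
    def test_perfect_prediction_zero_loss(self):
        rng = np.random.default_rng(1)
        p = random_params(rng, 3, 2, 2)
        X = rng.uniform(-1, 1, (6, 3))
        assert sos_loss(p, X, forward(p, X)) == 0.0

    def test_unit_offset_counts_entries(self):
        p = MLPParams(np.zeros((3, 2)), np.zeros(2), np.zeros((2, 4)), np.zeros(4),
                      "identity", "identity")
        Y = -np.ones((5, 4))  # prediction 0, offset 1 everywhere
        assert sos_loss(p, np.ones((5, 3)), Y) == pytest.approx(5 * 4)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(2)
        p = random_params(rng, 3, 2, 2)
        X = rng.uniform(-1, 1, (7, 3))
        Y = rng.uniform(-1, 1, (7, 2))
        perm = rng.permutation(7)
        assert sos_loss(p, X, Y) == pytest.approx(sos_loss(p, X[perm], Y[perm]))


def finite_difference_gradient(params, X, Y, step=1e-6):
    vec = params.to_vector()
    grad = np.empty_like(vec)
    for i in range(len(vec)):
        up, down = vec.copy(), vec.copy()
        up[i] += step
        down[i] -= step
        f_up = sos_loss(_rebuild(params, up), X, Y)
        f_dn = sos_loss(_rebuild(params, down), X, Y)
        grad[i] = (f_up - f_dn) / (2 * step)
    return grad


def _rebuild(params, vec):
    return MLPParams.from_vector(
        vec, params.n_inputs, params.n_hidden, params.n_outputs,
        params.hidden_activation, params.output_activation,
    )


class TestGradient:
    def test_zero_at_perfect_fit(self):
        rng = np.random.default_rng(3)
        p = random_params(rng, 3, 2, 2)
        X = rng.uniform(-1, 1, (5, 3))
        g = loss_gradient(p, X, forward(p, X))
        assert np.allclose(g, 0.0, atol=1e-12)

    @pytest.mark.parametrize("acts", [("logistic", "identity"),
                                      ("tanh", "exponential"),
                                      ("exponential", "logistic")])
    def test_matches_central_finite_differences(self, acts):
        rng = np.random.default_rng(11)
        p = random_params(rng, 2, 3, 2, acts)
        X = rng.uniform(-1, 1, (6, 2))
        Y = rng.uniform(0, 1, (6, 2))
        analytic = loss_gradient(p, X, Y)
        numeric = finite_difference_gradient(p, X, Y)
        assert np.allclose(analytic, numeric, rtol=1e-5, atol=1e-7)

    def test_target_shift_doubles_output_layer_gradient(self):
        """Doubling all residuals doubles ∂L/∂W2 under identity output."""
        rng = np.random.default_rng(4)
        p = random_params(rng, 3, 2, 2, ("tanh", "identity"))
        X = rng.uniform(-1, 1, (5, 3))
        pred = forward(p, X)
        resid = rng.uniform(0.1, 1.0, pred.shape)
        g1 = loss_gradient(p, X, pred - resid)
        g2 = loss_gradient(p, X, pred - 2 * resid)
        w2_slice = slice(p.n_inputs * p.n_hidden + p.n_hidden, None)
        assert np.allclose(g2[w2_slice], 2 * g1[w2_slice], rtol=1e-12)


def test_parameter_count_accounting():
    rng = np.random.default_rng(5)
    p = random_params(rng, 10, 10, 30)
    assert p.n_parameters == 10 * 10 + 10 + 10 * 30 + 30 == 440


def test_vector_roundtrip():
    rng = np.random.default_rng(6)
    p = random_params(rng, 4, 3, 2, ("logistic", "exponential"))
    q = MLPParams.from_vector(p.to_vector(), 4, 3, 2, "logistic", "exponential")
    assert np.array_equal(p.W1, q.W1) and np.array_equal(p.B2, q.B2)


def test_text_serialization_roundtrip(tmp_path):
    rng = np.random.default_rng(7)
    p = random_params(rng, 4, 3, 2, ("tanh", "identity"))
    path = tmp_path / "model.txt"
    save_params_text(p, path)
    q = load_params_text(path)
    assert np.array_equal(p.W1, q.W1)
    assert np.array_equal(p.B1, q.B1)
    assert np.array_equal(p.W2, q.W2)
    assert np.array_equal(p.B2, q.B2)
    assert q.hidden_activation == "tanh" and q.output_activation == "identity"


@pytest.fixture(scope="module")
def linear_problem():
    rng = np.random.default_rng(8)
    X = rng.uniform(0, 1, (40, 4))
    A = rng.uniform(-1, 1, (4, 3))
    Y = X @ A + rng.uniform(-0.5, 0.5, 3)
    split = SplitIndices(train=np.arange(0, 24), validation=np.arange(24, 32),
                         test=np.arange(32, 40))
    return X, Y, split


class TestTraining:
    def test_representable_linear_target_is_driven_to_zero(self, linear_problem):
        X, Y, split = linear_problem
        cfg = TrainingConfig(hidden_sizes=(4,), restarts=5, max_iterations=400, seed=1)
        model = train_mlp(X, Y, split, cfg, 4, ("identity", "identity"))
        initial = max(r["initial_sos"] for r in model.restart_log)
        assert model.sos["train"] <= 1e-6 * initial

    def test_selected_restart_has_minimal_validation_sos(self, linear_problem):
        X, Y, split = linear_problem
        cfg = TrainingConfig(hidden_sizes=(3,), restarts=6, max_iterations=150, seed=2)
        model = train_mlp(X, Y, split, cfg, 3, ("tanh", "identity"))
        kept = [r["val_sos"] for r in model.restart_log if not r["discarded"]]
        assert model.sos["validation"] == pytest.approx(min(kept), rel=1e-9)

    def test_each_run_improves_on_its_initial_loss(self, linear_problem):
        X, Y, split = linear_problem
        cfg = TrainingConfig(hidden_sizes=(3,), restarts=4, max_iterations=100, seed=3)
        model = train_mlp(X, Y, split, cfg, 3, ("logistic", "identity"))
        for run in model.restart_log:
            if not run["discarded"]:
                assert run["final_sos"] <= run["initial_sos"]

    def test_best_so_far_trajectory_is_monotone(self, linear_problem):
        X, Y, split = linear_problem
        cfg = TrainingConfig(hidden_sizes=(3,), restarts=2, max_iterations=100, seed=4)
        model = train_mlp(X, Y, split, cfg, 3, ("tanh", "identity"))
        traj = model.loss_trajectory
        assert np.all(np.diff(traj) <= 0)

    def test_same_seed_reproduces_model(self, linear_problem):
        X, Y, split = linear_problem
        cfg = TrainingConfig(hidden_sizes=(3,), restarts=3, max_iterations=80, seed=5)
        m1 = train_mlp(X, Y, split, cfg, 3, ("tanh", "identity"))
        m2 = train_mlp(X, Y, split, cfg, 3, ("tanh", "identity"))
        assert np.array_equal(m1.params.to_vector(), m2.params.to_vector())

    def test_estimator_sklearn_api(self, linear_problem):
        X, Y, _ = linear_problem
        est = MLPRegressor(hidden_units=3, hidden_activation="tanh",
                           output_activation="identity", restarts=2,
                           max_iter=60, random_state=0)
        assert est.get_params()["hidden_units"] == 3
        est.set_params(restarts=3)
        est.fit(X, Y)
        assert est.predict(X).shape == Y.shape
        assert 0.0 <= est.score(X, Y) <= 1.0
        assert est.n_parameters_ == 4 * 3 + 3 + 3 * 3 + 3


class TestArchitectureSearch:
    def test_single_combination_is_winner(self, linear_problem):
        X, Y, split = linear_problem
        cfg = TrainingConfig(hidden_sizes=(3,), activations=(("tanh", "identity"),),
                             restarts=2, max_iterations=60, seed=6)
        summary, best = search_architectures(X, Y, split, cfg)
        assert len(summary) == 1
        assert best.params.n_hidden == 3

    def test_summary_row_count_is_grid_cardinality(self, linear_problem):
        X, Y, split = linear_problem
        cfg = TrainingConfig(
            hidden_sizes=(2, 3),
            activations=(("tanh", "identity"), ("logistic", "identity")),
            restarts=2, max_iterations=40, seed=7,
        )
        summary, best = search_architectures(X, Y, split, cfg)
        assert len(summary) == 4
        assert summary["error_validation"].min() == pytest.approx(
            best.sos["validation"]
        )

    def test_empty_grid_rejected(self, linear_problem):
        X, Y, split = linear_problem
        with pytest.raises(ValueError):
            TrainingConfig(hidden_sizes=())


def test_overall_performance_excludes_degenerate_columns():
    y = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
    pred = np.column_stack([np.arange(5.0) * 2 + 1, np.full(5, 2.0)])
    assert overall_performance(y, pred) == pytest.approx(1.0)
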