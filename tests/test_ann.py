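"""Neural calibration model: transfer functions, forward pass, training, search."""

import math

import numpy as np
import pytest

from voltet.ann import (
    AffineScaler,
    MLPArchitecture,
    MLPModel,
    TRANSFER_FUNCTIONS,
    TrainConfig,
    architecture_search,
    forward,
    train,
    transfer,
)
from voltet.evaluate import nrmse
from voltet.exceptions import ConfigurationError, DataError, RegistryError, ShapeError


class TestTransfer:
    @pytest.mark.parametrize(
        "name,x,expected",
        [
            ("tansig", 0.0, 0.0),
            ("purelin", 3.7, 3.7),
            ("satlins", 2.5, 1.0),
            ("satlins", -0.3, -0.3),
            ("satlins", -4.0, -1.0),
            ("logsig", 0.0, 0.5),
            ("hardlims", -0.01, -1.0),
            ("hardlims", 0.01, 1.0),
        ],
    )
    def test_definitions(self, name, x, expected):
        assert transfer(name, x) == pytest.approx(expected)

    def test_unknown_name(self):
        with pytest.raises(RegistryError):
            transfer("sigmoidal", 0.0)

    def test_bounded_ranges(self):
        x = np.linspace(-50, 50, 1001)
        # tansig/logsig are open-interval maps; at float precision the bound
        # is attained, so assert the closed bound plus strictness near 0
        assert np.all(np.abs(transfer("tansig", x)) <= 1.0)
        assert abs(transfer("tansig", 5.0)) < 1.0
        assert np.all((transfer("logsig", x) >= 0) & (transfer("logsig", x) <= 1))
        assert 0 < transfer("logsig", 5.0) < 1
        assert set(np.unique(transfer("hardlims", x))) <= {-1.0, 1.0}
        assert np.all(np.abs(transfer("satlins", x)) <= 1.0)

    def test_subgradients_match_finite_differences(self):
        x = np.linspace(-0.9, 0.9, 7)  # interior, away from kinks
        eps = 1e-6
        for name in ("tansig", "logsig", "satlins", "purelin"):
            fn = TRANSFER_FUNCTIONS[name]
            num = (fn.f(x + eps) - fn.f(x - eps)) / (2 * eps)
            assert np.allclose(fn.df(x), num, atol=1e-8)


def _toy_model():
    arch = MLPArchitecture(
        n_input=2, n_hidden=2, n_output=1, hidden_fn="tansig", output_fn="purelin"
    )
    return MLPModel(
        architecture=arch,
        W1=np.array([[1.0, -1.0], [0.5, 0.25]]),
        b1=np.array([0.0, 0.1]),
        W2=np.array([[1.0, 2.0]]),
        b2=np.array([0.3]),
        x_scaler=AffineScaler(np.array([-1.0, -1.0]), np.array([1.0, 1.0])),
        y_scaler=AffineScaler(np.array([0.0]), np.array([30.0])),
    )


class TestForward:
    def test_hand_computed_composition(self):
        """Pencil-and-paper forward pass through a 2-2-1 tansig/purelin net."""
        model = _toy_model()
        x = [0.2, -0.4]  # x-scaler is the identity on [-1,1]
        h1 = math.tanh(1.0 * 0.2 + (-1.0) * (-0.4) + 0.0)
        h2 = math.tanh(0.5 * 0.2 + 0.25 * (-0.4) + 0.1)
        z = 1.0 * h1 + 2.0 * h2 + 0.3
        expected_ppm = (z + 1.0) / 2.0 * 30.0
        assert forward(model, x)[0] == pytest.approx(expected_ppm, abs=1e-12)

    def test_purity(self):
        model = _toy_model()
        assert np.array_equal(forward(model, [0.3, 0.7]), forward(model, [0.3, 0.7]))

    def test_degenerate_zero_net_returns_mid_domain(self):
        model = _toy_model()
        model.W1 = np.zeros_like(model.W1)
        model.b1 = np.zeros_like(model.b1)
        model.W2 = np.zeros_like(model.W2)
        model.b2 = np.zeros_like(model.b2)
        assert forward(model, [0.9, -0.9])[0] == pytest.approx(15.0)

    def test_length_mismatch(self):
        with pytest.raises(ShapeError):
            forward(_toy_model(), [1.0, 2.0, 3.0])

    def test_matches_naive_loop_oracle(self):
        """Vectorized forward equals an elementwise loop implementation."""
        rng = np.random.default_rng(0)
        for hf in ("satlins", "tansig", "logsig"):
            for of in ("purelin", "tansig"):
                ni, nh, no = 4, 3, 2
                arch = MLPArchitecture(ni, nh, no, hf, of)
                model = MLPModel(
                    arch,
                    W1=rng.normal(size=(nh, ni)),
                    b1=rng.normal(size=nh),
                    W2=rng.normal(size=(no, nh)),
                    b2=rng.normal(size=no),
                    x_scaler=AffineScaler(rng.normal(size=ni) - 3, rng.normal(size=ni) + 3),
                    y_scaler=AffineScaler(np.zeros(no), np.full(no, 10.0)),
                )
                x = rng.normal(size=ni)
                xs = [
                    2 * (x[i] - model.x_scaler.lo[i])
                    / (model.x_scaler.hi[i] - model.x_scaler.lo[i]) - 1
                    for i in range(ni)
                ]
                fh = TRANSFER_FUNCTIONS[hf].f
                fo = TRANSFER_FUNCTIONS[of].f
                hid = [
                    float(fh(sum(model.W1[j, i] * xs[i] for i in range(ni)) + model.b1[j]))
                    for j in range(nh)
                ]
                out = [
                    float(fo(sum(model.W2[k, j] * hid[j] for j in range(nh)) + model.b2[k]))
                    for k in range(no)
                ]
                expected = [(o + 1) / 2 * 10.0 for o in out]
                assert np.allclose(forward(model, x), expected, atol=1e-12)


class TestTrain:
    def _linear_toy(self, n=40, p=6, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.uniform(-1, 1, size=(n, p))
        A = rng.uniform(0.5, 1.5, size=(p, 3))
        return X, 15.0 + X @ A

    def test_fits_linear_data_like_least_squares(self):
        """A purelin/purelin net on exact linear data matches the OLS oracle."""
        X, Y = self._linear_toy()
        arch = MLPArchitecture(6, 4, 3, "purelin", "purelin")
        model = train(X, Y, arch, seed=0)
        assert nrmse(Y, model.predict(X)) < 1e-3
        # independent oracle: exact least-squares fit is perfect here
        coef, *_ = np.linalg.lstsq(np.hstack([X, np.ones((len(X), 1))]), Y, rcond=None)
        assert nrmse(Y, np.hstack([X, np.ones((len(X), 1))]) @ coef) < 1e-10

    def test_deterministic_given_seed(self):
        X, Y = self._linear_toy()
        arch = MLPArchitecture(6, 3, 3, "satlins", "tansig")
        cfg = TrainConfig(max_iter=200, n_restarts=2)
        m1 = train(X, Y, arch, seed=11, config=cfg)
        m2 = train(X, Y, arch, seed=11, config=cfg)
        assert np.array_equal(m1.W1, m2.W1) and np.array_equal(m1.b2, m2.b2)

    def test_loss_never_increases(self):
        X, Y = self._linear_toy()
        arch = MLPArchitecture(6, 3, 3, "hardlims", "purelin")  # untrainable hidden
        model = train(X, Y, arch, seed=0, config=TrainConfig(max_iter=50, n_restarts=1))
        assert np.isfinite(model.final_loss)

    def test_bounded_head_stays_in_target_box(self):
        X, Y = self._linear_toy()
        model = train(X, Y, MLPArchitecture(6, 3, 3, "satlins", "tansig"), seed=0,
                      config=TrainConfig(max_iter=300, n_restarts=1))
        wild = np.random.default_rng(1).uniform(-30, 30, size=(100, 6))
        pred = model.predict(wild)
        assert np.all(pred >= Y.min(axis=0) - 1e-9)
        assert np.all(pred <= Y.max(axis=0) + 1e-9)

    def test_non_finite_data_rejected(self):
        X, Y = self._linear_toy()
        X[0, 0] = np.nan
        with pytest.raises(DataError):
            train(X, Y, MLPArchitecture(6, 3, 3))

    def test_too_few_rows_rejected(self):
        X, Y = self._linear_toy(n=4)
        with pytest.raises(DataError):
            train(X, Y, MLPArchitecture(6, 5, 3))

    def test_zero_variance_feature_handled(self):
        X, Y = self._linear_toy()
        X[:, 2] = 7.7  # constant column
        model = train(X, Y, MLPArchitecture(6, 3, 3, "purelin", "purelin"), seed=0,
                      config=TrainConfig(max_iter=300, n_restarts=1))
        assert np.all(np.isfinite(model.predict(X)))

    def test_json_round_trip(self):
        X, Y = self._linear_toy()
        model = train(X, Y, MLPArchitecture(6, 3, 3), seed=0,
                      config=TrainConfig(max_iter=50, n_restarts=1))
        clone = MLPModel.from_json(model.to_json())
        assert np.array_equal(clone.predict(X), model.predict(X))


class TestSearch:
    @pytest.fixture(scope="class")
    def toy(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 4))
        Y = X @ rng.normal(size=(4, 2)) + 5.0
        return X, Y

    def test_full_grid_has_200_configurations(self, toy):
        X, Y = toy
        result = architecture_search(
            X, Y, seed=0, config=TrainConfig(max_iter=30, n_restarts=1)
        )
        assert result.grid_size == 200
        combos = {(r["hidden_size"], r["hidden_fn"], r["output_fn"]) for r in result.records}
        assert len(combos) == 8 * 5 * 5

    def test_purelin_head_wins_on_linear_data(self, toy):
        X, Y = toy
        result = architecture_search(
            X, Y, seed=0, config=TrainConfig(max_iter=30, n_restarts=1)
        )
        assert result.best_architecture.output_fn == "purelin"

    def test_best_so_far_non_increasing(self, toy):
        X, Y = toy
        result = architecture_search(
            X, Y, hidden_sizes=[2, 3], hidden_fns=("purelin", "tansig"),
            output_fns=("purelin",), seed=0, config=TrainConfig(max_iter=30, n_restarts=1),
        )
        best = np.minimum.accumulate([r["cv_nrmse"] for r in result.records])
        assert np.all(np.diff(best) <= 0)

    def test_singleton_grid_returns_that_triple(self, toy):
        X, Y = toy
        result = architecture_search(
            X, Y, hidden_sizes=[3], hidden_fns=("tansig",), output_fns=("purelin",),
            seed=0, config=TrainConfig(max_iter=30, n_restarts=1),
        )
        assert result.grid_size == 1
        assert result.best_architecture.hidden_fn == "tansig"
        assert result.best_architecture.n_hidden == 3

    def test_empty_grid_rejected(self, toy):
        X, Y = toy
        with pytest.raises(ConfigurationError):
            architecture_search(X, Y, hidden_sizes=[])

    def test_winner_attains_minimum(self, toy):
        X, Y = toy
        result = architecture_search(
            X, Y, hidden_sizes=[2, 4], hidden_fns=("purelin", "satlins"),
            output_fns=("purelin", "tansig"), seed=0,
            config=TrainConfig(max_iter=30, n_restarts=1),
        )
        scores = [r["cv_nrmse"] for r in result.records]
        winner = next(
            r for r in result.records
            if r["hidden_size"] == result.best_architecture.n_hidden
            and r["hidden_fn"] == result.best_architecture.hidden_fn
            and r["output_fn"] == result.best_architecture.output_fn
        )
        assert winner["cv_nrmse"] == min(scores)
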