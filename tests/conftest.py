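import numpy as np
import pytest

from voltet import (
    DesignSpec,
    MLPArchitecture,
    NoiseModel,
    build_design,
    compress_dataset,
    default_sensor_bank,
    make_grid,
    train,
)
from voltet.evaluate import nrmse
from voltet.pipeline import simulate_dataset


@pytest.fixture(scope="session")
def default_grid():
    return make_grid()


@pytest.fixture(scope="session")
def bank():
    return default_sensor_bank()


def study_dataset(seed: int, sigma_rel: float):
    """Default 36-sample calibration study: features + targets + subset mask."""
    table = build_design(DesignSpec(seed=seed))
    records = simulate_dataset(
        table, default_sensor_bank(), make_grid(), NoiseModel(sigma_rel=sigma_rel, seed=seed)
    )
    feats = compress_dataset(records)
    X = feats.iloc[:, 1:].to_numpy()
    Y = table.concentrations()
    train_mask = (table.frame.subset == "train").to_numpy()
    return table, records, X, Y, train_mask


def fit_and_score(seed: int, sigma_rel: float, **train_kwargs):
    """Train the 144-5-3 satlins/tansig network; return headline metrics."""
    _, _, X, Y, m = study_dataset(seed, sigma_rel)
    model = train(X[m], Y[m], MLPArchitecture(), seed=seed, **train_kwargs)
    pred_tr, pred_te = model.predict(X[m]), model.predict(X[~m])
    r_min = min(
        np.corrcoef(Y[~m][:, a], pred_te[:, a])[0, 1] for a in range(Y.shape[1])
    )
    return {
        "train_nrmse": nrmse(Y[m], pred_tr),
        "test_nrmse": nrmse(Y[~m], pred_te),
        "min_test_r": float(r_min),
        "model": model,
        "X": X,
        "Y": Y,
        "train_mask": m,
    }


@pytest.fixture(scope="session")
def lownoise_runs():
    """The default 0.5%-noise study for seeds 1-5 (shared across tests)."""
    return [fit_and_score(seed, 0.005) for seed in range(1, 6)]
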