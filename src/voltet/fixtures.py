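"""Deterministic canonical datasets for tests and worked examples.

Every fixture is regenerated from code at call time (nothing is shipped on
disk), written as ordinary pipeline CSVs/JSON under a caller-chosen directory,
and stamped with content hashes in a manifest so bit-reproducibility is
checkable: same name + seed -> identical hashes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as vio
from .ann import MLPArchitecture, MLPModel, AffineScaler
from .design import CONCENTRATION_COLUMNS, DesignSpec, build_design
from .exceptions import RegistryError
from .pipeline import simulate_dataset
from .simulate import NoiseModel, default_sensor_bank, make_grid

#: canonical noise levels: noiseless, the default study level, and a harsh one
NOISE_LEVELS = {"zeronoise": 0.0, "lownoise": 0.005, "noisy": 0.02}


@dataclass(frozen=True)
class FixtureSet:
    name: str
    seed: int
    files: tuple
    hashes: dict

    @property
    def content_hash(self) -> str:
        joined = ";".join(f"{k}={v}" for k, v in sorted(self.hashes.items()))
        return hashlib.sha256(joined.encode()).hexdigest()[:16]


def _default_run(sigma_rel: float):
    def build(outdir: Path, seed: int):
        spec = DesignSpec(seed=seed)
        table = build_design(spec)
        grid = make_grid()
        bank = default_sensor_bank()
        noise = NoiseModel(sigma_rel=sigma_rel, seed=seed)
        records = simulate_dataset(table, bank, grid, noise)
        vio.write_sample_table(table, outdir / "sample_table.csv")
        vio.write_voltammograms(records, outdir / "voltammograms.csv")
        return ["sample_table.csv", "voltammograms.csv"]

    return build


def _toy_linear_calibration(outdir: Path, seed: int):
    """20 samples whose concentrations are an exact linear map of 6 features."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(-1.0, 1.0, size=(20, 6))
    A = rng.uniform(0.5, 2.0, size=(6, 3))
    Y = 15.0 + X @ A  # exact affine map, centered in the 0-30 ppm domain
    feats = pd.DataFrame(X, columns=[f"f{i + 1:03d}" for i in range(6)])
    feats.insert(0, "sample_id", [f"L{i + 1:02d}" for i in range(20)])
    table = pd.DataFrame(Y, columns=list(CONCENTRATION_COLUMNS))
    table.insert(0, "sample_id", feats.sample_id)
    table["subset"] = ["train"] * 15 + ["test"] * 5
    vio.write_features(feats, outdir / "features.csv")
    vio.write_sample_table(table, outdir / "sample_table.csv")
    return ["features.csv", "sample_table.csv"]


def _toy_net(outdir: Path, seed: int):
    """Hand-sized 2-2-1 tansig/purelin network with seeded weights."""
    rng = np.random.default_rng(seed)
    arch = MLPArchitecture(n_input=2, n_hidden=2, n_output=1,
                           hidden_fn="tansig", output_fn="purelin")
    model = MLPModel(
        architecture=arch,
        W1=rng.normal(0, 1, (2, 2)),
        b1=rng.normal(0, 1, 2),
        W2=rng.normal(0, 1, (1, 2)),
        b2=rng.normal(0, 1, 1),
        x_scaler=AffineScaler(np.array([-1.0, -1.0]), np.array([1.0, 1.0])),
        y_scaler=AffineScaler(np.array([0.0]), np.array([30.0])),
        seed=seed,
    )
    model.save(outdir / "toy_net.json")
    return ["toy_net.json"]


def _sensor_bank(outdir: Path, seed: int):
    vio.write_sensor_bank(default_sensor_bank(), outdir / "sensor_bank.yaml")
    return ["sensor_bank.yaml"]


FIXTURES = {
    "default_run_zeronoise": _default_run(NOISE_LEVELS["zeronoise"]),
    "default_run_lownoise": _default_run(NOISE_LEVELS["lownoise"]),
    "default_run_noisy": _default_run(NOISE_LEVELS["noisy"]),
    "toy_linear_calibration": _toy_linear_calibration,
    "toy_net": _toy_net,
    "sensor_bank": _sensor_bank,
}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_fixture(name: str, seed: int, outdir) -> FixtureSet:
    """Generate the named fixture under ``outdir`` and write its manifest."""
    if name not in FIXTURES:
        raise RegistryError(f"unknown fixture {name!r}; known: {sorted(FIXTURES)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = FIXTURES[name](outdir, seed)
    hashes = {f: _sha256(outdir / f) for f in files}
    manifest = {"name": name, "seed": seed, "files": files, "sha256": hashes}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return FixtureSet(name, seed, tuple(files), hashes)
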