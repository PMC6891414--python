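"""End-to-end orchestration: design -> simulate -> compress -> train -> evaluate.

One seeded :class:`RunConfig` drives the whole calibration study and every
numeric artifact it writes (design CSV, voltammograms, feature matrix, search
report, model JSON, results CSV) is bit-reproducible for a fixed config+seed.
External instrument exports can replace the simulator through
:func:`ingest_external` as long as they follow the documented CSV schemas.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as vio
from .ann import MLPArchitecture, TrainConfig, architecture_search, train
from .design import DesignSpec, DesignTable, build_design
from .dwt import WaveletConfig, compress_dataset
from .evaluate import LabeledData, evaluate_model
from .exceptions import ConfigurationError
from .simulate import (
    NoiseModel,
    default_sensor_bank,
    make_grid,
    simulate_sample,
    E_MIN_DEFAULT,
    E_MAX_DEFAULT,
    N_POINTS_DEFAULT,
    SENSOR_ORDER,
)

log = logging.getLogger("voltet.pipeline")


@dataclass(frozen=True)
class SearchSpec:
    """Whether and how to run the exhaustive architecture search."""

    enabled: bool = False
    hidden_min: int = 2
    hidden_max: int = 9
    n_folds: int = 3
    max_iter: int = 300
    n_restarts: int = 1


@dataclass(frozen=True)
class RunConfig:
    design: DesignSpec = DesignSpec()
    sensor_bank_path: str | None = None  # None -> shipped default bank
    sigma_abs: float = 0.0
    sigma_rel: float = 0.005
    wavelet: WaveletConfig = WaveletConfig()
    architecture: MLPArchitecture = MLPArchitecture()
    training: TrainConfig = TrainConfig()
    search: SearchSpec = SearchSpec()
    e_min: float = E_MIN_DEFAULT
    e_max: float = E_MAX_DEFAULT
    n_points: int = N_POINTS_DEFAULT
    seed: int = 0

    # -- YAML round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        nested = {
            "design": DesignSpec,
            "wavelet": WaveletConfig,
            "architecture": MLPArchitecture,
            "training": TrainConfig,
            "search": SearchSpec,
        }
        kwargs = {}
        for key, value in d.items():
            if key in nested and isinstance(value, dict):
                kwargs[key] = nested[key](**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


@dataclass(frozen=True)
class RunReport:
    config: RunConfig
    outdir: Path
    paths: dict
    results: object  # pandas frame
    combined_nrmse: dict
    model: object


def _seed_int(master: int, stream: int) -> int:
    """Derive a stable 31-bit child seed for a named stream."""
    return int(
        np.random.SeedSequence([int(master), stream]).generate_state(1)[0] % 2**31
    )


def simulate_dataset(table: DesignTable, sensor_bank, grid, noise: NoiseModel) -> list:
    """Simulate one SampleRecord per design row."""
    return [
        simulate_sample(row, sensor_bank, grid, noise, sample_id=sid)
        for sid, row in zip(table.ids(), table.concentrations())
    ]


def features_and_targets(feature_frame, table: DesignTable, subset: str) -> LabeledData:
    """Align the feature matrix with design rows of one subset."""
    sub = table.frame[table.frame.subset == subset]
    merged = sub.merge(feature_frame, on="sample_id", validate="one_to_one")
    fcols = [c for c in feature_frame.columns if c != "sample_id"]
    from .design import CONCENTRATION_COLUMNS

    return LabeledData(
        ids=merged.sample_id.tolist(),
        X=merged[fcols].to_numpy(dtype=float),
        Y=merged[list(CONCENTRATION_COLUMNS)].to_numpy(dtype=float),
    )


def run_pipeline(config: RunConfig, outdir, overwrite: bool = False) -> RunReport:
    """Execute all stages and write every artifact under ``outdir``."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise ConfigurationError(
            f"output directory {outdir} is not empty (pass overwrite=True to replace)"
        )
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        name: outdir / fname
        for name, fname in {
            "design": "design.csv",
            "voltammograms": "voltammograms.csv",
            "features": "features.csv",
            "search_report": "search_report.csv",
            "model": "model.json",
            "results": "results.csv",
            "log": "run.log",
        }.items()
    }
    handler = logging.FileHandler(paths["log"], mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("config hash %s, master seed %d", config.config_hash(), config.seed)

        # (A) design
        design_seed = _seed_int(config.seed, 1)
        spec = dataclasses.replace(config.design, seed=design_seed)
        table = build_design(spec)
        vio.write_sample_table(table, paths["design"])
        log.info("design: %d train + %d test rows (design seed %d)",
                 table.n_train, table.n_test, design_seed)

        # (B) measurement (simulated)
        grid = make_grid(config.e_min, config.e_max, config.n_points)
        if config.sensor_bank_path is None:
            bank = default_sensor_bank()
        else:
            bank = vio.read_sensor_bank(config.sensor_bank_path)
        noise = NoiseModel(config.sigma_abs, config.sigma_rel, _seed_int(config.seed, 2))
        records = simulate_dataset(table, bank, grid, noise)
        vio.write_voltammograms(records, paths["voltammograms"])
        log.info("simulated %d samples x %d sensors x %d points",
                 len(records), len(bank), grid.n_points)

        # (C) compression
        features = compress_dataset(records, config.wavelet)
        vio.write_features(features, paths["features"])
        log.info("compressed to %d coefficients/sample", features.shape[1] - 1)

        # (D) training / selection
        train_data = features_and_targets(features, table, "train")
        train_seed = _seed_int(config.seed, 3)
        if config.search.enabled:
            result = architecture_search(
                train_data.X,
                train_data.Y,
                hidden_sizes=range(config.search.hidden_min, config.search.hidden_max + 1),
                seed=train_seed,
                n_folds=config.search.n_folds,
                config=TrainConfig(
                    max_iter=config.search.max_iter,
                    n_restarts=config.search.n_restarts,
                ),
            )
            model, report = result.best_model, result.to_frame()
            log.info("search: %d configurations, winner %s", result.grid_size,
                     result.best_architecture)
        else:
            model = train(
                train_data.X, train_data.Y, config.architecture,
                seed=train_seed, config=config.training,
            )
            import pandas as pd

            report = pd.DataFrame(
                [{
                    "hidden_size": config.architecture.n_hidden,
                    "hidden_fn": config.architecture.hidden_fn,
                    "output_fn": config.architecture.output_fn,
                    "cv_nrmse": float("nan"),
                }]
            )
            log.info("trained fixed architecture %s (train seed %d)",
                     config.architecture, train_seed)
        report.to_csv(paths["search_report"], index=False, float_format=vio.FLOAT_FMT)
        model.save(paths["model"])

        # (E) validation
        test_data = features_and_targets(features, table, "test")
        evaluation = evaluate_model(model, train_data, test_data)
        results = evaluation.to_frame()
        vio.write_results(results, paths["results"])
        log.info("combined NRMSE: train %.4f, test %.4f",
                 evaluation.combined["train"], evaluation.combined["test"])
        return RunReport(config, outdir, paths, results, dict(evaluation.combined), model)
    finally:
        log.removeHandler(handler)
        handler.close()


def ingest_external(voltammogram_csv, sample_table_csv,
                    sensor_order=SENSOR_ORDER, expected_n_points: int = N_POINTS_DEFAULT):
    """Load instrument-exported CSVs as validated SampleRecords.

    Returns ``(records, design_table)``; raises :class:`SchemaError` naming
    the offending file/sample/sensor on any schema violation.
    """
    table = vio.read_sample_table(sample_table_csv)
    records = vio.read_voltammograms(
        voltammogram_csv, table, sensor_order, expected_n_points=expected_n_points
    )
    return records, table
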