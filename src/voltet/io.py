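"""CSV/YAML schemas for designs, voltammograms, features, results and banks.

All CSV files are RFC-4180 with a header row and '.' decimal separator;
floats are written with 17 significant digits so a write -> read round trip
is lossless.

Schemas
-------
sample table     : sample_id, c_<analyte>_ppm x3, subset{train|test}
voltammograms    : sample_id, sensor_id, point_index, potential_V, current_uA
feature matrix   : sample_id, f001..fNNN
results          : subset, analyte, r, r_squared, slope, intercept_ppm, nrmse
sensor bank YAML : mapping sensor_id -> SensorParams fields
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .design import CONCENTRATION_COLUMNS, DesignTable
from .exceptions import SchemaError
from .simulate import (
    PotentialGrid,
    SampleRecord,
    SensorParams,
    Voltammogram,
    make_grid,
)

FLOAT_FMT = "%.17g"

SAMPLE_TABLE_COLUMNS = ("sample_id", *CONCENTRATION_COLUMNS, "subset")
VOLTAMMOGRAM_COLUMNS = ("sample_id", "sensor_id", "point_index", "potential_V", "current_uA")


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


# -- sample table ----------------------------------------------------------


def write_sample_table(table: DesignTable | pd.DataFrame, path) -> None:
    frame = table.frame if isinstance(table, DesignTable) else table
    frame.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_sample_table(path) -> DesignTable:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, SAMPLE_TABLE_COLUMNS, path)
    bad = set(df.subset) - {"train", "test"}
    if bad:
        raise SchemaError(f"{path}: unknown subset labels {sorted(bad)}")
    if df.sample_id.duplicated().any():
        dup = df.sample_id[df.sample_id.duplicated()].iloc[0]
        raise SchemaError(f"{path}: duplicate sample_id {dup!r}")
    return DesignTable(df[list(SAMPLE_TABLE_COLUMNS)])


# -- voltammograms ---------------------------------------------------------


def write_voltammograms(records, path) -> None:
    chunks = []
    for rec in records:
        for vg in rec.voltammograms:
            n = vg.grid.n_points
            chunks.append(
                pd.DataFrame(
                    {
                        "sample_id": rec.sample_id,
                        "sensor_id": vg.sensor_id,
                        "point_index": np.arange(n),
                        "potential_V": vg.grid.potentials,
                        "current_uA": vg.currents,
                    }
                )
            )
    pd.concat(chunks, ignore_index=True).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


def _grid_from_potentials(potentials: np.ndarray, path, sample, sensor) -> PotentialGrid:
    n = len(potentials)
    if n < 4 or n % 2:
        raise SchemaError(
            f"{path}: sample {sample!r} sensor {sensor!r}: "
            f"trace has {n} points, expected an even count >= 4"
        )
    half = n // 2
    up, down = potentials[:half], potentials[half:]
    if not (np.all(np.diff(up) > 0) and np.all(np.diff(down) < 0)):
        raise SchemaError(
            f"{path}: sample {sample!r} sensor {sensor!r}: "
            "potential halves are not strictly monotone (ascending then descending)"
        )
    return PotentialGrid(float(up[0]), float(up[-1]), n, np.asarray(potentials, dtype=float))


def read_voltammograms(
    path,
    sample_table: DesignTable,
    sensor_order,
    expected_n_points: int | None = None,
) -> list:
    """Reconstruct validated :class:`SampleRecord` objects from the long CSV."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, VOLTAMMOGRAM_COLUMNS, path)
    conc = {
        row.sample_id: np.array([getattr(row, c) for c in CONCENTRATION_COLUMNS])
        for row in sample_table.frame.itertuples()
    }
    records = []
    sensor_order = list(sensor_order)
    for sample_id, sdf in df.groupby("sample_id", sort=False):
        if sample_id not in conc:
            raise SchemaError(f"{path}: sample {sample_id!r} absent from sample table")
        present = list(dict.fromkeys(sdf.sensor_id))
        missing = [s for s in sensor_order if s not in present]
        if missing:
            raise SchemaError(
                f"{path}: sample {sample_id!r}: missing sensor(s) {missing}"
            )
        vgs = []
        for sensor_id in sensor_order:
            trace = sdf[sdf.sensor_id == sensor_id].sort_values("point_index")
            n = len(trace)
            if expected_n_points is not None and n != expected_n_points:
                raise SchemaError(
                    f"{path}: sample {sample_id!r} sensor {sensor_id!r}: "
                    f"{n} points, expected {expected_n_points}"
                )
            grid = _grid_from_potentials(
                trace.potential_V.to_numpy(), path, sample_id, sensor_id
            )
            vgs.append(Voltammogram(sensor_id, grid, trace.current_uA.to_numpy()))
        records.append(SampleRecord(sample_id, conc[sample_id], tuple(vgs)))
    return records


# -- features / results ----------------------------------------------------


def write_features(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_features(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ("sample_id",), path)
    return df


def write_results(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False, float_format=FLOAT_FMT)


# -- sensor bank YAML ------------------------------------------------------

_ANALYTE_FIELDS = ("sensitivity", "saturation", "peak_potential", "peak_width")
_SCALAR_FIELDS = ("anodic_fraction", "baseline_slope", "baseline_offset")


def write_sensor_bank(bank, path) -> None:
    payload = {}
    for p in bank:
        entry = {f: [float(v) for v in getattr(p, f)] for f in _ANALYTE_FIELDS}
        entry.update({f: float(getattr(p, f)) for f in _SCALAR_FIELDS})
        entry["interaction"] = [[float(v) for v in row] for row in p.interaction]
        payload[p.sensor_id] = entry
    with open(path, "w") as fh:
        yaml.safe_dump({"sensors": payload}, fh, sort_keys=False)


def read_sensor_bank(path) -> list:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, dict) or "sensors" not in payload:
        raise SchemaError(f"{path}: expected a top-level 'sensors' mapping")
    bank = []
    for sensor_id, entry in payload["sensors"].items():
        try:
            bank.append(
                SensorParams(
                    sensor_id=sensor_id,
                    sensitivity=np.array(entry["sensitivity"], dtype=float),
                    saturation=np.array(entry["saturation"], dtype=float),
                    peak_potential=np.array(entry["peak_potential"], dtype=float),
                    peak_width=np.array(entry["peak_width"], dtype=float),
                    anodic_fraction=float(entry["anodic_fraction"]),
                    baseline_slope=float(entry["baseline_slope"]),
                    baseline_offset=float(entry["baseline_offset"]),
                    interaction=np.array(entry["interaction"], dtype=float),
                )
            )
        except KeyError as exc:
            raise SchemaError(f"{path}: sensor {sensor_id!r} missing field {exc}") from exc
    return bank
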