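"""Wavelet compression of voltammetric fingerprints.

Each sensor's 752-point trace is reduced to its depth-5 Daubechies-3
approximation coefficients under periodized boundary handling, giving 24
coefficients per sensor and a 144-long feature vector per six-sensor sample
(a 96.8% compression of the 4512 raw currents).  Periodization halves the
length exactly (ceil(n/2) per level), which is what makes 752 -> 24 work.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt

from .exceptions import DecompositionError, DomainError, ShapeError
from .simulate import SampleRecord


@dataclass(frozen=True)
class WaveletConfig:
    family: str = "db3"
    depth: int = 5
    boundary: str = "periodization"
    keep: str = "approximation"

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise DecompositionError("depth must be >= 1")
        wavelet = pywt.Wavelet(self.family)
        if not wavelet.orthogonal:
            raise DomainError(f"wavelet {self.family!r} is not orthonormal")
        if self.keep != "approximation":
            raise DomainError("only approximation coefficients are supported")


@dataclass(frozen=True)
class FeatureVector:
    """Concatenated per-sensor approximation coefficients for one sample."""

    sample_id: str
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        coef = np.asarray(self.coefficients, dtype=float)
        object.__setattr__(self, "coefficients", coef)
        if not np.all(np.isfinite(coef)):
            raise DomainError("coefficients must be finite")


def approx_length(n: int, depth: int) -> int:
    """Length of the depth-level periodized approximation: ceil(n / 2**depth)."""
    return -(-n // 2**depth)


def dwt_approx(signal, config: WaveletConfig = WaveletConfig()) -> np.ndarray:
    """Depth-level approximation coefficients of an orthonormal periodized DWT."""
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ShapeError(f"signal must be 1-D, got shape {x.shape}")
    if len(x) < 2**config.depth:
        raise DecompositionError(
            f"signal of length {len(x)} too short for depth {config.depth}"
        )
    coeffs = pywt.wavedec(x, config.family, mode=config.boundary, level=config.depth)
    return coeffs[0]


def compress_sample(
    rec: SampleRecord, config: WaveletConfig = WaveletConfig()
) -> FeatureVector:
    """Per-sensor DWT approximations concatenated in fixed sensor order."""
    lengths = {len(v.currents) for v in rec.voltammograms}
    if len(lengths) != 1:
        raise ShapeError(f"voltammograms have unequal lengths: {sorted(lengths)}")
    blocks = [dwt_approx(v.currents, config) for v in rec.voltammograms]
    return FeatureVector(rec.sample_id, np.concatenate(blocks))


def compress_dataset(records, config: WaveletConfig = WaveletConfig()) -> pd.DataFrame:
    """Feature matrix for a list of samples: sample_id + f001..fNNN columns."""
    rows = [compress_sample(r, config) for r in records]
    width = len(rows[0].coefficients)
    cols = [f"f{i + 1:03d}" for i in range(width)]
    frame = pd.DataFrame([fv.coefficients for fv in rows], columns=cols)
    frame.insert(0, "sample_id", [fv.sample_id for fv in rows])
    return frame


def compression_percent(n_in: int, n_out: int) -> float:
    """Percentage of raw values discarded: 100 * (1 - n_out/n_in)."""
    if n_in <= 0:
        raise DomainError("n_in must be positive")
    if n_out > n_in or n_out < 0:
        raise DomainError(f"need 0 <= n_out <= n_in, got {n_out} > {n_in}")
    return 100.0 * (1.0 - n_out / n_in)
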