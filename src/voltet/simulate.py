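"""Synthetic six-sensor cyclic voltammetry for ternary benzodiazepine mixtures.

The simulator is phenomenological, not first-principles: each sensor responds
to each analyte with a Gaussian reduction peak on the cathodic (return) sweep,
a partially mirrored anodic peak on the forward sweep, a saturating
(Michaelis-type) amplitude law in concentration, pairwise cross-suppression
between analytes, a capacitive baseline that changes sign with scan direction,
and additive Gaussian measurement noise.  The point is to reproduce the
*statistical structure* of an electronic-tongue dataset — six partially
selective, mutually complementary, mildly nonlinear sensors — so the whole
calibration pipeline (design, wavelet compression, neural-network inversion,
evaluation) can be exercised and tested without instrument data.

Units: potentials in volts, currents in microamperes, concentrations in ppm.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    ConfigurationError,
    DomainError,
    InvalidGridError,
    ShapeError,
)

#: Analyte order used everywhere (concentration vectors, sensitivity matrices).
ANALYTES = ("diazepam", "flunitrazepam", "lorazepam")

#: Fixed sensor order of the array: bare graphite-epoxy composite, four
#: nanoparticle-modified composites, and a platinum disk electrode.
SENSOR_ORDER = ("GEC", "CuO", "Cu", "Pt-np", "WO3", "Pt-disk")

E_MIN_DEFAULT = -1.5
E_MAX_DEFAULT = 1.5
#: Points per full cycle so that six sensors yield 4512 raw currents/sample.
N_POINTS_DEFAULT = 752


@dataclass(frozen=True)
class PotentialGrid:
    """Triangular potential sweep e_min -> e_max -> e_min.

    ``potentials`` holds the ascending half followed by the descending half,
    each half equally spaced with ``n_points // 2`` samples.
    """

    e_min: float
    e_max: float
    n_points: int
    potentials: np.ndarray

    @property
    def half(self) -> int:
        return self.n_points // 2

    @property
    def step(self) -> float:
        """Potential step within a half-sweep (V)."""
        return (self.e_max - self.e_min) / (self.half - 1)

    def direction(self) -> np.ndarray:
        """+1 on the ascending half, -1 on the descending half."""
        d = np.ones(self.n_points)
        d[self.half:] = -1.0
        return d


def make_grid(
    e_min: float = E_MIN_DEFAULT,
    e_max: float = E_MAX_DEFAULT,
    n_points: int = N_POINTS_DEFAULT,
) -> PotentialGrid:
    """Build the cyclic-voltammetry potential grid.

    Parameters
    ----------
    e_min, e_max
        Sweep limits in volts (vs. the reference electrode).
    n_points
        Total points per full cycle; must be even and >= 4.  The default 752
        gives 6 x 752 = 4512 raw currents per six-sensor sample.
    """
    if not (isinstance(n_points, (int, np.integer))) or n_points < 4 or n_points % 2:
        raise InvalidGridError(
            f"n_points must be an even integer >= 4, got {n_points!r}"
        )
    if not e_min < e_max:
        raise InvalidGridError(f"need e_min < e_max, got {e_min} >= {e_max}")
    half = n_points // 2
    up = np.linspace(e_min, e_max, half)
    down = np.linspace(e_max, e_min, half)
    potentials = np.concatenate([up, down])
    return PotentialGrid(float(e_min), float(e_max), int(n_points), potentials)


@dataclass(frozen=True)
class SensorParams:
    """Phenomenological response parameters of one working electrode.

    Per-analyte arrays follow :data:`ANALYTES` order.

    sensitivity : uA/ppm initial slope of the peak-amplitude law.
    saturation : ppm Michaelis-type constant; amplitude = S*c/(1 + c/K + supp).
    peak_potential : V center of the Gaussian reduction peak.
    peak_width : V Gaussian sigma of the peak.
    anodic_fraction : fraction of the cathodic peak mirrored on the forward sweep.
    baseline_slope : uA/V resistive tilt of the baseline.
    baseline_offset : uA capacitive offset; its sign follows the scan direction.
    interaction : ppm^-1 symmetric zero-diagonal cross-suppression matrix G;
        analyte a sees suppression sum_b G[a, b] * c_b.
    """

    sensor_id: str
    sensitivity: np.ndarray
    saturation: np.ndarray
    peak_potential: np.ndarray
    peak_width: np.ndarray
    anodic_fraction: float
    baseline_slope: float
    baseline_offset: float
    interaction: np.ndarray

    def __post_init__(self) -> None:
        for name in ("sensitivity", "saturation", "peak_potential", "peak_width"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != (len(ANALYTES),):
                raise ShapeError(f"{name} must have shape (3,), got {arr.shape}")
        g = np.asarray(self.interaction, dtype=float)
        object.__setattr__(self, "interaction", g)
        if g.shape != (3, 3):
            raise ShapeError(f"interaction must be 3x3, got {g.shape}")
        if np.any(self.sensitivity < 0):
            raise DomainError("sensitivities must be nonnegative")
        if np.any(self.saturation <= 0):
            raise DomainError("saturation constants must be positive")
        if np.any(self.peak_width <= 0):
            raise DomainError("peak widths must be positive")
        if not 0.0 <= self.anodic_fraction <= 1.0:
            raise DomainError("anodic_fraction must lie in [0, 1]")
        if np.any(g < 0) or np.any(np.abs(np.diag(g)) > 0) or not np.allclose(g, g.T):
            raise DomainError("interaction matrix must be symmetric, nonnegative, zero-diagonal")


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian measurement noise.

    The per-point standard deviation is ``sigma_abs + sigma_rel * full_scale``
    where full_scale is the maximum |current| of the noiseless trace.
    """

    sigma_abs: float = 0.0
    sigma_rel: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_abs < 0 or self.sigma_rel < 0:
            raise DomainError("noise sigmas must be nonnegative")


@dataclass(frozen=True)
class Voltammogram:
    """One sensor's current trace over the cyclic potential grid."""

    sensor_id: str
    grid: PotentialGrid
    currents: np.ndarray

    def __post_init__(self) -> None:
        cur = np.asarray(self.currents, dtype=float)
        object.__setattr__(self, "currents", cur)
        if cur.shape != (self.grid.n_points,):
            raise ShapeError(
                f"currents length {cur.shape} != grid n_points {self.grid.n_points}"
            )
        if not np.all(np.isfinite(cur)):
            raise DomainError("currents must be finite")


@dataclass(frozen=True)
class SampleRecord:
    """Three analyte concentrations plus the six-sensor voltammetric fingerprint."""

    sample_id: str
    concentrations: np.ndarray
    voltammograms: tuple

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "voltammograms", tuple(self.voltammograms))
        if c.shape != (len(ANALYTES),):
            raise ShapeError(f"concentrations must have shape (3,), got {c.shape}")
        if np.any(c < 0):
            raise DomainError("concentrations must be nonnegative")
        if len(self.voltammograms) != len(SENSOR_ORDER):
            raise ShapeError(
                f"expected {len(SENSOR_ORDER)} voltammograms, got {len(self.voltammograms)}"
            )

    @property
    def raw_vector(self) -> np.ndarray:
        """All currents concatenated in sensor order (4512 values at defaults)."""
        return np.concatenate([v.currents for v in self.voltammograms])


def peak_current(c: float, S: float, K: float, suppression: float = 0.0):
    """Saturating peak-amplitude law ``S*c / (1 + c/K + suppression)``.

    Monotone nondecreasing and concave in ``c``; bounded above by ``S*K`` as
    c -> infinity, which is what forces the calibration model to be nonlinear.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise DomainError("concentration must be nonnegative")
    if np.any(np.asarray(suppression) < 0):
        raise DomainError("suppression must be nonnegative")
    return S * c / (1.0 + c / K + suppression)


def _gauss(e: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((e - center) / width) ** 2)


def clean_voltammogram(
    params: SensorParams, concentrations, grid: PotentialGrid
) -> np.ndarray:
    """Noiseless current trace for one sensor (uA)."""
    c = np.asarray(concentrations, dtype=float)
    if c.shape != (len(ANALYTES),):
        raise ShapeError(f"concentration vector must have shape (3,), got {c.shape}")
    if np.any(c < 0):
        raise DomainError("concentrations must be nonnegative")
    e = grid.potentials
    direction = grid.direction()
    currents = params.baseline_offset * direction + params.baseline_slope * e
    # Cathodic peaks carried at full height on the return (descending) sweep,
    # anodic_fraction-scaled on the forward sweep.
    peak_scale = np.where(direction < 0, 1.0, params.anodic_fraction)
    suppression = params.interaction @ c
    for a in range(len(ANALYTES)):
        amp = peak_current(
            c[a], params.sensitivity[a], params.saturation[a], suppression[a]
        )
        currents = currents + amp * peak_scale * _gauss(
            e, params.peak_potential[a], params.peak_width[a]
        )
    return currents


def noise_sigma(params: SensorParams, concentrations, grid: PotentialGrid,
                noise: NoiseModel) -> float:
    """Effective noise standard deviation for one trace (uA)."""
    clean = clean_voltammogram(params, concentrations, grid)
    full_scale = float(np.max(np.abs(clean)))
    return noise.sigma_abs + noise.sigma_rel * full_scale


def simulate_voltammogram(
    params: SensorParams,
    concentrations,
    grid: PotentialGrid,
    noise: NoiseModel,
    rng: np.random.Generator | None = None,
) -> Voltammogram:
    """Simulate one sensor's cyclic voltammogram.

    Deterministic for a fixed ``noise.seed`` (or a caller-supplied ``rng``).
    """
    clean = clean_voltammogram(params, concentrations, grid)
    sigma = noise.sigma_abs + noise.sigma_rel * float(np.max(np.abs(clean)))
    currents = clean
    if sigma > 0:
        if rng is None:
            rng = np.random.default_rng(noise.seed)
        currents = clean + rng.normal(0.0, sigma, grid.n_points)
    return Voltammogram(params.sensor_id, grid, currents)


def _sensor_rng(seed: int, sample_id: str, sensor_index: int) -> np.random.Generator:
    """Independent, stable noise stream per (seed, sample, sensor)."""
    tag = zlib.crc32(str(sample_id).encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag, sensor_index]))


def simulate_sample(
    design_row,
    sensor_bank,
    grid: PotentialGrid,
    noise: NoiseModel,
    sample_id: str = "S00",
) -> SampleRecord:
    """Simulate the full six-sensor record of one mixture sample."""
    bank = list(sensor_bank)
    ids = [p.sensor_id for p in bank]
    if len(set(ids)) != len(ids):
        raise ConfigurationError(f"duplicate sensor_id in bank: {ids}")
    if len(bank) != len(SENSOR_ORDER):
        raise ConfigurationError(
            f"sensor bank must contain {len(SENSOR_ORDER)} sensors, got {len(bank)}"
        )
    vgs = []
    for k, params in enumerate(bank):
        rng = _sensor_rng(noise.seed, sample_id, k)
        vgs.append(simulate_voltammogram(params, design_row, grid, noise, rng=rng))
    return SampleRecord(sample_id, np.asarray(design_row, dtype=float), tuple(vgs))


# --------------------------------------------------------------------------
# Default sensor bank
# --------------------------------------------------------------------------
# Six distinct sensitivity/peak-position profiles.  The reduction peaks sit in
# the -1.3..-0.6 V window (azomethine reduction; the flunitrazepam column also
# carries the less negative nitro-group signature), widths are broad enough
# that peaks overlap heavily within each trace, and the 6x3 sensitivity matrix
# has full column rank so the array as a whole can resolve the mixture.
# These are package constants chosen for realism, not measured values.

_G_DEFAULT = np.array(
    [
        [0.0, 0.006, 0.004],
        [0.006, 0.0, 0.005],
        [0.004, 0.005, 0.0],
    ]
)

_BANK_TABLE = {
    # sensor:  S (uA/ppm),        K (ppm),      E0 (V),                 w (V),              anodic, b1,   b0
    "GEC":     ((1.00, 1.40, 0.80), (45, 55, 40), (-1.10, -0.72, -1.22), (0.14, 0.12, 0.16), 0.35, 0.8, 2.0),
    "CuO":     ((1.60, 0.70, 1.10), (50, 40, 55), (-1.02, -0.80, -1.15), (0.13, 0.15, 0.14), 0.45, 1.2, 2.8),
    "Cu":      ((0.60, 1.10, 1.50), (40, 60, 50), (-1.18, -0.76, -1.05), (0.16, 0.13, 0.12), 0.30, 0.6, 1.6),
    "Pt-np":   ((1.30, 1.00, 0.50), (55, 45, 60), (-0.95, -0.68, -1.25), (0.12, 0.14, 0.15), 0.50, 1.0, 2.4),
    "WO3":     ((0.90, 0.50, 1.30), (60, 50, 45), (-1.25, -0.85, -0.98), (0.15, 0.16, 0.13), 0.40, 0.9, 1.8),
    "Pt-disk": ((0.50, 1.20, 1.00), (45, 55, 50), (-1.08, -0.62, -1.30), (0.13, 0.12, 0.14), 0.55, 1.4, 3.2),
}


def default_sensor_bank() -> list:
    """The six-sensor bank shipped with the package, in :data:`SENSOR_ORDER`."""
    bank = []
    for sid in SENSOR_ORDER:
        S, K, E0, w, anodic, b1, b0 = _BANK_TABLE[sid]
        bank.append(
            SensorParams(
                sensor_id=sid,
                sensitivity=np.array(S, dtype=float),
                saturation=np.array(K, dtype=float),
                peak_potential=np.array(E0, dtype=float),
                peak_width=np.array(w, dtype=float),
                anodic_fraction=anodic,
                baseline_slope=b1,
                baseline_offset=b0,
                interaction=_G_DEFAULT.copy(),
            )
        )
    return bank


def sensitivity_matrix(sensor_bank) -> np.ndarray:
    """Stack per-sensor initial sensitivities into a (n_sensors, 3) matrix."""
    return np.vstack([p.sensitivity for p in sensor_bank])
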