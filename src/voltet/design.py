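"""Calibration experimental design.

Training standards come from a 3-level / 3-factor full factorial over the
0-30 ppm domain, rotated ("tilted") 45 degrees about each axis for a better
coverage of composition space, rescaled and shifted back into the domain cube.
The external test set is drawn uniformly at random inside the same domain and
is never used for model building or selection.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .exceptions import DomainError, ShapeError
from .simulate import ANALYTES

CONCENTRATION_COLUMNS = tuple(f"c_{a}_ppm" for a in ANALYTES)


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of the factorial + random-test calibration design."""

    levels: int = 3
    factors: int = 3
    domain_lo: float = 0.0
    domain_hi: float = 30.0
    tilt_deg: float = 45.0
    n_test: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise DomainError("levels must be >= 1")
        if self.factors < 1:
            raise DomainError("factors must be >= 1")
        if not self.domain_lo < self.domain_hi:
            raise DomainError("need domain_lo < domain_hi")
        if not 0.0 <= self.tilt_deg < 90.0:
            raise DomainError("tilt_deg must lie in [0, 90)")
        if self.n_test < 0:
            raise DomainError("n_test must be nonnegative")


@dataclass(frozen=True)
class DesignTable:
    """Concentration rows with train/test labels.

    ``frame`` columns: sample_id, one concentration column per analyte, subset.
    """

    frame: pd.DataFrame

    def concentrations(self, subset: str | None = None) -> np.ndarray:
        df = self.frame if subset is None else self.frame[self.frame.subset == subset]
        return df[list(CONCENTRATION_COLUMNS)].to_numpy(dtype=float)

    def ids(self, subset: str | None = None) -> list:
        df = self.frame if subset is None else self.frame[self.frame.subset == subset]
        return df.sample_id.tolist()

    @property
    def n_train(self) -> int:
        return int((self.frame.subset == "train").sum())

    @property
    def n_test(self) -> int:
        return int((self.frame.subset == "test").sum())


def full_factorial(levels: int, factors: int, lo: float, hi: float) -> np.ndarray:
    """Cartesian grid of equally spaced levels spanning [lo, hi] per factor."""
    if lo >= hi:
        raise DomainError(f"need lo < hi, got {lo} >= {hi}")
    if factors < 1:
        raise DomainError("factors must be >= 1")
    if levels < 1:
        raise DomainError("levels must be >= 1")
    if levels == 1:
        axis = np.array([(lo + hi) / 2.0])
    else:
        axis = np.linspace(lo, hi, levels)
    points = np.array(list(itertools.product(axis, repeat=factors)), dtype=float)
    return points


def _rotation_matrix(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    rx = np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)
    ry = np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)
    rz = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)
    return rx @ ry @ rz


def tilt_points(points, tilt_deg: float, lo: float, hi: float) -> np.ndarray:
    """Rotate a 3-D point cloud by ``tilt_deg`` about each axis and refit.

    The rotation Rx(t)Ry(t)Rz(t) is applied about the domain centroid, then a
    single uniform scale (never > 1) and a minimal per-axis shift bring the
    bounding box inside [lo, hi]^3.  The map is a similarity transform, so
    pairwise-distance ratios are preserved; with tilt 0 and in-domain input it
    is the exact identity.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ShapeError(f"expected (n, 3) points, got {pts.shape}")
    center = np.full(3, (lo + hi) / 2.0)
    rot = _rotation_matrix(np.deg2rad(tilt_deg))
    q = (pts - center) @ rot.T
    span = hi - lo
    extent = q.max(axis=0) - q.min(axis=0)
    with np.errstate(divide="ignore"):
        ratios = np.where(extent > 0, span / extent, np.inf)
    scale = min(1.0, float(ratios.min()))
    q = q * scale + center
    # minimal shift into the box (at most one side can overflow per axis
    # because the scaled extent fits within the span)
    low_over = np.minimum(q.min(axis=0) - lo, 0.0)
    high_over = np.maximum(q.max(axis=0) - hi, 0.0)
    q = q - low_over - high_over
    if len(q) > 1 and pdist(q).min() < 1e-9:
        raise DomainError("tilt produced coincident design points")
    return q


def random_test_set(n: int, lo: float, hi: float, seed: int) -> np.ndarray:
    """``n`` uniform random composition points inside [lo, hi]^3."""
    if lo >= hi:
        raise DomainError(f"need lo < hi, got {lo} >= {hi}")
    if n < 1:
        raise DomainError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.uniform(lo, hi, size=(n, 3))


def build_design(spec: DesignSpec = DesignSpec()) -> DesignTable:
    """Full tilted-factorial train set plus random external test set."""
    train = full_factorial(spec.levels, spec.factors, spec.domain_lo, spec.domain_hi)
    if spec.factors == 3 and spec.tilt_deg != 0.0:
        train = tilt_points(train, spec.tilt_deg, spec.domain_lo, spec.domain_hi)
    rows = []
    for i, p in enumerate(train, start=1):
        rows.append((f"C{i:02d}", *p, "train"))
    if spec.n_test > 0:
        test = random_test_set(spec.n_test, spec.domain_lo, spec.domain_hi, spec.seed)
        for i, p in enumerate(test, start=1):
            rows.append((f"T{i:02d}", *p, "test"))
    frame = pd.DataFrame(
        rows, columns=["sample_id", *CONCENTRATION_COLUMNS, "subset"]
    )
    return DesignTable(frame)
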