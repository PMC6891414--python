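"""Model performance metrics: NRMSE and obtained-vs-expected regression lines.

NRMSE here is the residual 2-norm relative to the 2-norm of the reference
values, sqrt(sum (obtained - expected)^2 / sum expected^2), pooled over every
included entry; a range-normalized variant (RMSE over the reference range) is
available behind the ``normalization`` flag.  The combined NRMSE of a subset
pools all three analytes into one ratio rather than averaging per-analyte
values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError, DomainError, ProtocolError, ShapeError
from .simulate import ANALYTES


@dataclass(frozen=True)
class RegressionStats:
    """Obtained-vs-expected line fit for one analyte in one subset.

    ``r`` is the Pearson correlation coefficient; ``r_squared`` its square.
    """

    analyte: str
    subset: str
    slope: float
    intercept: float
    r: float
    r_squared: float
    nrmse: float


@dataclass(frozen=True)
class LabeledData:
    """A feature matrix with sample ids and reference concentrations."""

    ids: tuple
    X: np.ndarray
    Y: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "X", np.asarray(self.X, dtype=float))
        object.__setattr__(self, "Y", np.asarray(self.Y, dtype=float))
        if len(self.ids) != len(self.X) or len(self.X) != len(self.Y):
            raise ShapeError("ids, X and Y must have equal length")


def nrmse(expected, obtained, normalization: str = "signal") -> float:
    """Normalized root-mean-squared error pooled over all entries."""
    e = np.asarray(expected, dtype=float)
    o = np.asarray(obtained, dtype=float)
    if e.shape != o.shape or e.size == 0:
        raise ShapeError(f"shapes must match and be nonempty: {e.shape} vs {o.shape}")
    rss = float(np.sum((o - e) ** 2))
    if normalization == "signal":
        denom = float(np.sum(e**2))
        if denom == 0.0:
            raise DomainError("NRMSE undefined: reference values are all zero")
        return float(np.sqrt(rss / denom))
    if normalization == "range":
        rng = float(e.max() - e.min())
        if rng == 0.0:
            raise DomainError("NRMSE undefined: reference range is zero")
        return float(np.sqrt(rss / e.size) / rng)
    raise DomainError(f"unknown normalization {normalization!r}")


def regression_line(
    expected, obtained, analyte: str = "", subset: str = ""
) -> RegressionStats:
    """Ordinary least squares of obtained on expected (ideal: slope 1, intercept 0)."""
    e = np.asarray(expected, dtype=float).ravel()
    o = np.asarray(obtained, dtype=float).ravel()
    if e.shape != o.shape:
        raise ShapeError("expected and obtained must have equal length")
    if len(e) < 3:
        raise DataError("need at least 3 points for a regression line")
    if np.var(e) == 0.0:
        raise DataError("degenerate fit: expected values have zero variance")
    fit = stats.linregress(e, o)
    return RegressionStats(
        analyte=analyte,
        subset=subset,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        r_squared=float(fit.rvalue**2),
        nrmse=nrmse(e, o),
    )


@dataclass(frozen=True)
class EvaluationResult:
    stats: tuple
    combined: dict

    def to_frame(self) -> pd.DataFrame:
        """Eight-row results table: 3 analytes x 2 subsets + 2 combined rows."""
        rows = [
            {
                "subset": s.subset,
                "analyte": s.analyte,
                "r": s.r,
                "r_squared": s.r_squared,
                "slope": s.slope,
                "intercept_ppm": s.intercept,
                "nrmse": s.nrmse,
            }
            for s in self.stats
        ]
        for subset, value in self.combined.items():
            rows.append(
                {
                    "subset": subset,
                    "analyte": "combined",
                    "r": np.nan,
                    "r_squared": np.nan,
                    "slope": np.nan,
                    "intercept_ppm": np.nan,
                    "nrmse": value,
                }
            )
        return pd.DataFrame(rows)


def evaluate_model(model, train: LabeledData, test: LabeledData) -> EvaluationResult:
    """Per-analyte regression stats and combined NRMSE for both subsets.

    ``model`` needs only a ``predict(X) -> (n, 3)`` method.  Train and test
    subsets must be disjoint by sample id.
    """
    overlap = set(train.ids) & set(test.ids)
    if overlap:
        raise ProtocolError(f"train/test subsets overlap: {sorted(overlap)}")
    stats_rows = []
    combined = {}
    for subset, data in (("train", train), ("test", test)):
        pred = np.asarray(model.predict(data.X), dtype=float)
        for a, analyte in enumerate(ANALYTES):
            stats_rows.append(
                regression_line(data.Y[:, a], pred[:, a], analyte=analyte, subset=subset)
            )
        combined[subset] = nrmse(data.Y, pred)
    return EvaluationResult(tuple(stats_rows), combined)


def plot_obtained_vs_expected(result_frames: dict, path=None):
    """Obtained-vs-expected scatter per analyte (train filled, test open).

    ``result_frames`` maps subset name -> (expected (n,3), obtained (n,3)).
    Returns the matplotlib figure; saves it if ``path`` is given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(ANALYTES), figsize=(12, 4), sharex=True, sharey=True)
    styles = {"train": dict(marker="o", color="k"), "test": dict(marker="o", mfc="none", color="k")}
    for a, (ax, analyte) in enumerate(zip(axes, ANALYTES)):
        for subset, (e, o) in result_frames.items():
            st = styles.get(subset, dict(marker="x"))
            ax.plot(np.asarray(e)[:, a], np.asarray(o)[:, a], ls="", **st, label=subset)
        lims = ax.get_xlim()
        ax.plot(lims, lims, "--", color="grey", lw=1)
        ax.set_title(analyte)
        ax.set_xlabel("expected (ppm)")
    axes[0].set_ylabel("obtained (ppm)")
    axes[0].legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
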