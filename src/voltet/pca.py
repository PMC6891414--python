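"""PCA complementarity diagnostics for the sensor array.

Before any quantification, the array must be shown to carry non-redundant
information: single-analyte replicates are measured (here: simulated) on every
sensor, each (sensor, replicate) voltammogram becomes one PCA row, and the
score plot should separate both sensors and compounds away from the origin.
Centering only, no autoscaling — all variables are currents in the same unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SkPCA
from sklearn.metrics import silhouette_score

from .exceptions import DiagnosticError, DomainError
from .simulate import (
    ANALYTES,
    NoiseModel,
    PotentialGrid,
    simulate_sample,
)


@dataclass(frozen=True)
class PCAResult:
    """Scores (samples x k), loadings (variables x k), explained fractions."""

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_fraction: np.ndarray


def pca(data, n_components: int) -> PCAResult:
    """Column-mean-centered SVD principal components.

    Sign convention: within each component the largest-magnitude loading is
    made positive, so results are deterministic.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise DomainError("need a 2-D matrix with at least 2 rows")
    max_k = min(X.shape[0] - 1, X.shape[1])
    if not 1 <= n_components <= max_k:
        raise DomainError(
            f"n_components must be in [1, {max_k}] for shape {X.shape}"
        )
    model = _SkPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_.T.copy()  # (p, k)
    for j in range(n_components):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    total_var = np.var(X - X.mean(axis=0), axis=0, ddof=1).sum()
    if total_var > 0:
        frac = model.explained_variance_ / total_var
    else:
        frac = np.zeros(n_components)
    return PCAResult(scores, loadings, frac)


@dataclass(frozen=True)
class ComplementarityReport:
    """Score table plus clustering summary of the single-analyte PCA."""

    scores: pd.DataFrame  # sensor_id, compound, replicate, pc1, pc2
    centroids: pd.DataFrame  # sensor_id, compound, pc1, pc2
    mean_silhouette: float
    explained_variance_fraction: np.ndarray


def complementarity_report(
    sensor_bank,
    grid: PotentialGrid,
    noise: NoiseModel,
    n_replicates: int = 5,
    concentration: float = 25.0,
    compounds=ANALYTES,
) -> ComplementarityReport:
    """Simulate single-analyte replicates and run the array-complementarity PCA.

    One PCA row per (sensor, compound, replicate) voltammogram; groups are the
    (sensor, compound) pairs.  Reports per-group score centroids on the first
    two components and the mean silhouette of the grouping.
    """
    compounds = list(compounds)
    if len(compounds) < 2:
        raise DiagnosticError("need at least 2 compound groups for the diagnostic")
    if n_replicates < 1:
        raise DiagnosticError("need at least one replicate")
    rows, meta = [], []
    for compound in compounds:
        c = np.zeros(len(ANALYTES))
        c[ANALYTES.index(compound)] = concentration
        for rep in range(1, n_replicates + 1):
            rec = simulate_sample(
                c,
                sensor_bank,
                grid,
                noise,
                sample_id=f"{compound}-r{rep:02d}",
            )
            for vg in rec.voltammograms:
                rows.append(vg.currents)
                meta.append((vg.sensor_id, compound, rep))
    X = np.vstack(rows)
    result = pca(X, n_components=2)
    scores = pd.DataFrame(meta, columns=["sensor_id", "compound", "replicate"])
    scores["pc1"] = result.scores[:, 0]
    scores["pc2"] = result.scores[:, 1]
    centroids = (
        scores.groupby(["sensor_id", "compound"], sort=False)[["pc1", "pc2"]]
        .mean()
        .reset_index()
    )
    if np.allclose(centroids[["pc1", "pc2"]].to_numpy(), 0.0, atol=1e-9):
        raise DiagnosticError("all score centroids at the origin: no information")
    labels = (scores.sensor_id + "/" + scores.compound).to_numpy()
    if n_replicates > 1:
        sil = float(silhouette_score(result.scores, labels))
    else:
        sil = float("nan")
    return ComplementarityReport(scores, centroids, sil, result.explained_variance_fraction)


def plot_scores(report: ComplementarityReport, path=None):
    """Fig-7-style score plot colored by compound, one marker per sensor."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    markers = ["o", "s", "^", "v", "D", "x"]
    sensors = list(dict.fromkeys(report.scores.sensor_id))
    colors = {c: f"C{i}" for i, c in enumerate(dict.fromkeys(report.scores.compound))}
    for i, sensor in enumerate(sensors):
        sub = report.scores[report.scores.sensor_id == sensor]
        for compound, grp in sub.groupby("compound", sort=False):
            ax.scatter(
                grp.pc1, grp.pc2, marker=markers[i % len(markers)],
                color=colors[compound], s=30,
                label=f"{sensor}/{compound}" if i == 0 else None,
            )
    evf = report.explained_variance_fraction
    ax.set_xlabel(f"PC1 ({evf[0] * 100:.1f}%)")
    ax.set_ylabel(f"PC2 ({evf[1] * 100:.1f}%)")
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
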