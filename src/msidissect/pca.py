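"""Principal component analysis of individual pixel spectra.

Columns of the peak table are centered and (by default) scaled to unit
variance, and the covariance matrix is eigendecomposed. A deterministic sign
convention — each loading column's largest-magnitude element is positive —
makes results reproducible across linear-algebra backends. Scores rendered
on the pixel grid give the component images in which the first component
separates the two molecular phenotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .preprocess import PeakTable

logger = logging.getLogger("msidissect")


@dataclass
class PCAResult:
    """Scores (pixels x components), orthonormal loadings (bins x
    components), per-component explained-variance fractions (non-increasing),
    and the bookkeeping needed to render score images."""

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_fraction: np.ndarray
    bin_centers: np.ndarray
    pixel_index: list[tuple[int, int]]
    pixel_rows: np.ndarray  # rows of the peak table that entered the fit
    grid_shape: tuple[int, int]
    scaling: str

    @property
    def n_components(self) -> int:
        return int(self.loadings.shape[1])


def run_pca(
    peak_table: PeakTable,
    n_components: int = 5,
    scaling: str = "unit_variance",
) -> PCAResult:
    """PCA of the non-blank peak-table rows via covariance eigendecomposition.

    Zero-variance columns are dropped with a warning under unit-variance
    scaling (their loadings would be undefined); blank pixels are excluded
    exactly as in segmentation.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if scaling not in ("unit_variance", "none"):
        raise ValueError(f"unknown scaling {scaling!r}")

    blank = peak_table.empty_rows()
    rows = np.flatnonzero(~blank)
    if rows.size < 2:
        raise ValueError("PCA requires at least 2 non-empty pixels")

    X = peak_table.matrix[rows].astype(float)
    bin_centers = peak_table.bin_centers
    X = X - X.mean(axis=0)
    if scaling == "unit_variance":
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            logger.warning("run_pca: dropping %d zero-variance column(s)", int((~keep).sum()))
            X = X[:, keep]
            bin_centers = bin_centers[keep]
            sd = sd[keep]
        X = X / sd

    n, p = X.shape
    if n_components > min(n, p):
        raise ValueError(f"n_components {n_components} > min(pixels, bins) = {min(n, p)}")

    cov = (X.T @ X) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]

    loadings = eigvecs[:, :n_components]
    # sign convention: largest-|loading| element positive per component
    for j in range(loadings.shape[1]):
        k = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[k, j] < 0:
            loadings[:, j] = -loadings[:, j]

    scores = X @ loadings
    total_var = eigvals.sum()
    frac = eigvals[:n_components] / total_var if total_var > 0 else np.zeros(n_components)

    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance_fraction=frac,
        bin_centers=bin_centers,
        pixel_index=peak_table.pixel_index,
        pixel_rows=rows,
        grid_shape=peak_table.grid_shape(),
        scaling=scaling,
    )


def loading_extremes(
    result: PCAResult, component: int = 0, k: int = 5
) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """The k most-positive and k most-negative loadings of a component, with
    their bin m/z — the peaks specific to either molecular phenotype."""
    if not 0 <= component < result.n_components:
        raise ValueError(f"component {component} out of range")
    if k > result.bin_centers.size:
        raise ValueError(f"k={k} exceeds bin count {result.bin_centers.size}")
    col = result.loadings[:, component]
    order = np.argsort(col)
    positive = [(float(result.bin_centers[i]), float(col[i])) for i in order[::-1][:k] if col[i] > 0]
    negative = [(float(result.bin_centers[i]), float(col[i])) for i in order[:k] if col[i] < 0]
    return positive, negative


def score_image(result: PCAResult, component: int = 0) -> np.ndarray:
    """Raster of one component's score per pixel; off-tissue pixels are NaN."""
    if not 0 <= component < result.n_components:
        raise ValueError(f"component {component} out of range")
    img = np.full(result.grid_shape, np.nan)
    for score, row in zip(result.scores[:, component], result.pixel_rows):
        x, y = result.pixel_index[row]
        img[y, x] = score
    return img
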