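"""Spectrum preprocessing: baseline subtraction, TIC normalization, peak
picking, and tolerance-based peak alignment into a pixels x bins PeakTable.

The chain mirrors common MALDI-TOF peptide-imaging practice: a convolution
baseline (morphological opening smoothed by a moving average), total-ion-
current rescaling so every pixel carries the same summed intensity, local-
maximum peak picking against a MAD noise floor, and pooling of per-pixel
centroids into shared m/z bins wherever consecutive peaks are closer than a
tolerance (default 0.3 Da, appropriate for reflectron-TOF peptide data over
m/z 600-3200).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d, minimum_filter1d, uniform_filter1d
from scipy.signal import find_peaks

from .msi_io import MSIDataset, Spectrum

logger = logging.getLogger("msidissect")

DEFAULT_BASELINE_HALF_WIDTH = 50
DEFAULT_TIC_TARGET = 100.0
DEFAULT_ALIGN_TOLERANCE_DA = 0.3
DEFAULT_PEAK_SNR = 5.0


@dataclass
class PeakTable:
    """Aligned pixels x m/z-bins intensity matrix.

    Attributes
    ----------
    bin_centers
        Strictly ascending m/z bin centers (intensity-weighted means of the
        pooled peaks in each bin).
    matrix
        Non-negative ``(n_pixels, n_bins)`` intensity matrix; pixels without
        a peak in a bin hold 0.
    pixel_index
        Ordered (x, y) coordinates, one per matrix row.
    provenance
        Record of the applied preprocessing steps and their parameters.
    """

    bin_centers: np.ndarray
    matrix: np.ndarray
    pixel_index: list[tuple[int, int]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.pixel_index), self.bin_centers.size):
            raise ValueError(
                f"matrix shape {self.matrix.shape} inconsistent with "
                f"{len(self.pixel_index)} pixels x {self.bin_centers.size} bins"
            )
        if self.bin_centers.size > 1 and not np.all(np.diff(self.bin_centers) > 0):
            raise ValueError("bin_centers must be strictly increasing")
        if np.any(self.matrix < 0):
            raise ValueError("peak table intensities must be non-negative")

    @property
    def n_pixels(self) -> int:
        return len(self.pixel_index)

    @property
    def n_bins(self) -> int:
        return int(self.bin_centers.size)

    def empty_rows(self) -> np.ndarray:
        """Boolean mask of all-zero (off-tissue) pixel rows, which are flagged
        and excluded from clustering and PCA."""
        return ~np.any(self.matrix > 0, axis=1)

    def grid_shape(self) -> tuple[int, int]:
        xs = [x for x, _ in self.pixel_index]
        ys = [y for _, y in self.pixel_index]
        return (max(ys) + 1, max(xs) + 1)

    def to_csv(self, path: str | Path) -> Path:
        """Serialize as CSV: pixel x, y as the first two columns, one column
        per bin center; provenance as a JSON sidecar."""
        path = Path(path)
        df = pd.DataFrame(self.matrix, columns=[f"{c:.6f}" for c in self.bin_centers])
        df.insert(0, "y", [y for _, y in self.pixel_index])
        df.insert(0, "x", [x for x, _ in self.pixel_index])
        df.to_csv(path, index=False)
        path.with_suffix(".provenance.json").write_text(
            json.dumps(self.provenance, indent=2, default=str)
        )
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "PeakTable":
        path = Path(path)
        df = pd.read_csv(path)
        pixels = list(zip(df["x"].astype(int), df["y"].astype(int)))
        cols = [c for c in df.columns if c not in ("x", "y")]
        prov_path = path.with_suffix(".provenance.json")
        prov = json.loads(prov_path.read_text()) if prov_path.exists() else {}
        return cls(
            bin_centers=np.array([float(c) for c in cols]),
            matrix=df[cols].to_numpy(dtype=float),
            pixel_index=pixels,
            provenance=prov,
        )


# ---------------------------------------------------------------------------
# Baseline
# ---------------------------------------------------------------------------

def subtract_baseline(spectrum: Spectrum, half_width: int = DEFAULT_BASELINE_HALF_WIDTH) -> Spectrum:
    """Remove a slowly varying baseline from a profile-mode spectrum.

    The baseline is estimated by a grey-scale morphological opening (moving
    minimum then moving maximum over a ``2*half_width + 1`` bin window) and
    smoothed with a moving average of the same width, then subtracted and the
    result clipped at zero. The opening removes any peak narrower than the
    window while reproducing linear trends exactly, so a ramp baseline leaves
    no residual and peak apex heights are preserved.
    """
    if half_width < 1:
        raise ValueError("half_width must be >= 1")
    n = len(spectrum)
    if half_width >= n:
        raise ValueError(f"half_width {half_width} >= spectrum length {n}")
    window = 2 * half_width + 1
    eroded = minimum_filter1d(spectrum.intensity, size=window, mode="nearest")
    opened = maximum_filter1d(eroded, size=window, mode="nearest")
    baseline = uniform_filter1d(opened, size=window, mode="nearest")
    corrected = np.clip(spectrum.intensity - baseline, 0.0, None)
    return Spectrum(spectrum.mz.copy(), corrected)


# ---------------------------------------------------------------------------
# TIC normalization
# ---------------------------------------------------------------------------

def tic_normalize(values: np.ndarray | Spectrum, target: float = DEFAULT_TIC_TARGET):
    """Rescale intensities uniformly so they sum to ``target``.

    Accepts a :class:`Spectrum` (returns a Spectrum) or a bare intensity
    vector (returns an array). All-zero input is returned unchanged with a
    warning; callers flag such pixels and exclude them downstream, since TIC
    normalization is undefined on blank (off-tissue) spectra.
    """
    if target <= 0:
        raise ValueError("TIC target must be positive")
    if isinstance(values, Spectrum):
        out = tic_normalize(values.intensity, target)
        return Spectrum(values.mz.copy(), out)
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 0):
        raise ValueError("TIC normalization requires non-negative intensities")
    total = arr.sum()
    if total == 0:
        logger.warning("tic_normalize: all-zero spectrum left unchanged")
        return arr.copy()
    return (arr / total) * target  # divide first: stable for tiny totals


# ---------------------------------------------------------------------------
# Peak picking
# ---------------------------------------------------------------------------

def pick_peaks(spectrum: Spectrum, snr: float = DEFAULT_PEAK_SNR) -> list[tuple[float, float]]:
    """Detect local maxima above ``snr`` times the noise floor.

    Noise is the robust scale estimate 1.4826 x median absolute deviation of
    the spectrum's non-zero intensities. Returns (apex m/z, apex intensity)
    pairs in ascending m/z order.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    inten = spectrum.intensity
    nonzero = inten[inten > 0]
    if nonzero.size == 0:
        return []
    mad = np.median(np.abs(nonzero - np.median(nonzero)))
    noise = 1.4826 * mad
    idx, _ = find_peaks(inten)
    if noise > 0:
        idx = idx[inten[idx] >= snr * noise]
    return [(float(spectrum.mz[i]), float(inten[i])) for i in idx]


# ---------------------------------------------------------------------------
# Peak alignment
# ---------------------------------------------------------------------------

def align_peaks(
    per_pixel_peaks: list[list[tuple[float, float]]],
    pixel_index: list[tuple[int, int]],
    tolerance_da: float = DEFAULT_ALIGN_TOLERANCE_DA,
    provenance: dict | None = None,
) -> PeakTable:
    """Pool per-pixel centroid lists into shared m/z bins.

    All peaks are sorted by m/z and split into bins wherever the gap between
    consecutive peaks exceeds ``tolerance_da``; each bin's center is the
    intensity-weighted mean m/z of its members, and each pixel contributes
    the sum of its peaks falling in the bin. Raising the tolerance can only
    merge bins, never create new ones.
    """
    if tolerance_da <= 0:
        raise ValueError("tolerance must be positive")
    if len(per_pixel_peaks) != len(pixel_index):
        raise ValueError("one peak list per pixel required")
    if not any(per_pixel_peaks):
        raise ValueError("at least one non-empty peak list required")

    mzs, intens, owners = [], [], []
    for row, peaks in enumerate(per_pixel_peaks):
        for mz, inten in peaks:
            mzs.append(float(mz))
            intens.append(float(inten))
            owners.append(row)
    mzs = np.asarray(mzs)
    intens = np.asarray(intens)
    owners = np.asarray(owners)

    order = np.argsort(mzs, kind="stable")
    mzs, intens, owners = mzs[order], intens[order], owners[order]

    # new bin starts wherever the m/z gap exceeds the tolerance
    bin_ids = np.concatenate([[0], np.cumsum(np.diff(mzs) > tolerance_da)])
    n_bins = int(bin_ids[-1]) + 1

    weights = np.where(intens > 0, intens, 1e-30)  # zero-intensity peaks still locate
    centers = np.bincount(bin_ids, weights=weights * mzs, minlength=n_bins) / np.bincount(
        bin_ids, weights=weights, minlength=n_bins
    )

    matrix = np.zeros((len(pixel_index), n_bins))
    np.add.at(matrix, (owners, bin_ids), intens)

    prov = dict(provenance or {})
    prov["alignment_tolerance_da"] = tolerance_da
    return PeakTable(
        bin_centers=centers,
        matrix=matrix,
        pixel_index=list(pixel_index),
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------

def build_peak_table(
    dataset: MSIDataset,
    baseline_half_width: int = DEFAULT_BASELINE_HALF_WIDTH,
    tic_target: float = DEFAULT_TIC_TARGET,
    snr: float = DEFAULT_PEAK_SNR,
    tolerance_da: float = DEFAULT_ALIGN_TOLERANCE_DA,
) -> PeakTable:
    """Run the full preprocessing chain on a dataset.

    Profile-mode spectra are baseline-subtracted and peak-picked; centroid
    spectra are used as-is. Peaks are aligned into bins and every non-blank
    row is TIC-normalized to ``tic_target``. Blank (all-zero) pixels are left
    unscaled and flagged via :meth:`PeakTable.empty_rows`.
    """
    per_pixel: list[list[tuple[float, float]]] = []
    for sp in dataset.spectra:
        if dataset.mode == "profile":
            if len(sp) == 0:
                per_pixel.append([])
                continue
            corrected = subtract_baseline(sp, half_width=baseline_half_width)
            per_pixel.append(pick_peaks(corrected, snr=snr))
        else:
            per_pixel.append(list(zip(sp.mz.tolist(), sp.intensity.tolist())))

    table = align_peaks(
        per_pixel,
        dataset.pixels,
        tolerance_da=tolerance_da,
        provenance={
            "mode": dataset.mode,
            "baseline_half_width": baseline_half_width if dataset.mode == "profile" else None,
            "peak_snr": snr if dataset.mode == "profile" else None,
            "tic_target": tic_target,
        },
    )
    sums = table.matrix.sum(axis=1)
    nonblank = sums > 0
    table.matrix[nonblank] *= tic_target / sums[nonblank, None]
    n_blank = int((~nonblank).sum())
    if n_blank:
        logger.warning("build_peak_table: %d blank pixel(s) flagged off-tissue", n_blank)
    return table
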