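"""Virtual immunohistochemistry: match marker tryptic peptides into the MSI
peak list, render their ion images, and score spatial overlap with annotated
regions.

Each selected proteome-unique peptide of a marker protein is matched to the
nearest aligned m/z bin within a tolerance (default 0.3 Da). Its ion image —
summed intensity over the matched window per pixel — is the "virtual stain";
binarizing it (Otsu by default) and comparing against a region mask with
Dice and IoU turns the visual overlap of stains and ion images into numbers.
Pixels positive in the ion image but outside the region are counted, never
auto-interpreted: they are the candidate regions a stain may have missed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .digest import Proteome, TrypticPeptide, select_marker_peptides
from .msi_io import ProteinRecord, RegionAnnotation
from .preprocess import PeakTable

logger = logging.getLogger("msidissect")

DEFAULT_MATCH_TOLERANCE_DA = 0.3


@dataclass
class IonImage:
    """Spatial intensity map of one m/z window; the virtual stain for the
    marker peptide recorded in ``marker``/``peptide_sequence``."""

    target_mz: float
    tolerance_da: float
    raster: np.ndarray  # NaN off-tissue, >= 0 on tissue
    marker: str = ""
    peptide_sequence: str = ""

    def on_tissue(self) -> np.ndarray:
        return self.raster[~np.isnan(self.raster)]


def match_peptide(
    peptide: TrypticPeptide,
    peak_table: PeakTable,
    tolerance_da: float = DEFAULT_MATCH_TOLERANCE_DA,
) -> int | None:
    """Index of the aligned bin nearest the peptide's [M+H]+ within the
    tolerance, or None. A distance tie is broken toward the lower-m/z bin."""
    if tolerance_da <= 0:
        raise ValueError("tolerance must be positive")
    centers = peak_table.bin_centers
    if centers.size == 0:
        return None
    dist = np.abs(centers - peptide.mh_mono)
    best = int(np.flatnonzero(dist == dist.min())[0])  # tie -> lower m/z
    if int((dist == dist.min()).sum()) > 1:
        logger.warning(
            "match_peptide: distance tie for %s broken toward m/z %.4f",
            peptide.sequence,
            centers[best],
        )
    return best if dist[best] <= tolerance_da else None


def render_ion_image(
    peak_table: PeakTable,
    target_mz: float,
    tolerance_da: float = DEFAULT_MATCH_TOLERANCE_DA,
) -> IonImage:
    """Per-pixel summed intensity over all bins within the m/z window.

    A window containing no bin yields an all-zero (on-tissue) image with a
    warning. Off-tissue (blank) pixels are NaN.
    """
    if tolerance_da <= 0:
        raise ValueError("tolerance must be positive")
    in_window = np.abs(peak_table.bin_centers - target_mz) <= tolerance_da
    if not in_window.any():
        logger.warning(
            "render_ion_image: no bin within %.3f Da of m/z %.4f", tolerance_da, target_mz
        )
    values = peak_table.matrix[:, in_window].sum(axis=1)
    raster = np.full(peak_table.grid_shape(), np.nan)
    blank = peak_table.empty_rows()
    for row, (x, y) in enumerate(peak_table.pixel_index):
        if not blank[row]:
            raster[y, x] = values[row]
    return IonImage(target_mz=float(target_mz), tolerance_da=float(tolerance_da), raster=raster)


def dice_iou(mask_a: np.ndarray, mask_b: np.ndarray) -> tuple[float, float]:
    """Dice and IoU of two boolean masks (0.0 for disjoint or empty pairs)."""
    inter = float(np.logical_and(mask_a, mask_b).sum())
    a, b = float(mask_a.sum()), float(mask_b.sum())
    union = a + b - inter
    dice = 2.0 * inter / (a + b) if (a + b) > 0 else 0.0
    iou = inter / union if union > 0 else 0.0
    return dice, iou


def binarize(image: IonImage, threshold: str | float = "otsu") -> tuple[np.ndarray, float]:
    """Threshold an ion image into a positive-pixel mask (NaN pixels never
    positive). Returns (mask, threshold value)."""
    values = image.on_tissue()
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold {threshold!r}")
        if values.size == 0 or np.allclose(values, values[0] if values.size else 0.0):
            thr = float(values[0]) / 2 if values.size else 0.0  # constant image guard
        else:
            thr = float(threshold_otsu(values))
    else:
        thr = float(threshold)
    mask = np.where(np.isnan(image.raster), False, image.raster > thr)
    return mask.astype(bool), thr


def overlap_score(
    ion_image: IonImage,
    annotation: RegionAnnotation,
    region_name: str,
    threshold: str | float = "otsu",
) -> dict:
    """One overlap-report row: Dice/IoU between the binarized ion image and
    the named region's mask, plus the count of positive pixels outside it."""
    if ion_image.raster.shape != annotation.label_map.shape:
        raise ValueError(
            f"raster shape {ion_image.raster.shape} incongruent with "
            f"annotation {annotation.label_map.shape}"
        )
    region_mask = annotation.mask(region_name)  # raises KeyError if absent
    if not region_mask.any():
        raise ValueError(f"region {region_name!r} is empty")
    pos_mask, thr = binarize(ion_image, threshold)
    dice, iou = dice_iou(pos_mask, region_mask)
    return {
        "marker": ion_image.marker,
        "peptide": ion_image.peptide_sequence,
        "target_mz": ion_image.target_mz,
        "region_name": region_name,
        "dice": dice,
        "iou": iou,
        "threshold_used": thr,
        "positive_outside_region": int(np.logical_and(pos_mask, ~region_mask).sum()),
        "status": "ok",
    }


def virtual_panel(
    markers: list[tuple[ProteinRecord, str]],
    proteome: Proteome,
    peak_table: PeakTable,
    annotation: RegionAnnotation,
    n_peptides: int = 2,
    max_missed: int = 1,
    match_tolerance_da: float = DEFAULT_MATCH_TOLERANCE_DA,
    threshold: str | float = "otsu",
) -> pd.DataFrame:
    """Run the whole virtual-IHC panel.

    ``markers`` pairs each marker protein with the annotation region it
    stains. For every marker: select its proteome-unique peptides, match
    each into the peak list, render the ion image, and score overlap against
    the marker's region. Peptides without a matching peak are reported with
    status ``"no_peak"``; markers without unique peptides with
    ``"no_unique_peptides"``. One row per marker-peptide.
    """
    rows: list[dict] = []
    for protein, region_name in markers:
        try:
            peptides = select_marker_peptides(
                protein, proteome, n=n_peptides, max_missed=max_missed
            )
        except Exception as exc:
            raise RuntimeError(f"marker {protein.accession}: {exc}") from exc
        if not peptides:
            rows.append(
                {
                    "marker": protein.accession,
                    "peptide": "",
                    "target_mz": np.nan,
                    "region_name": region_name,
                    "dice": np.nan,
                    "iou": np.nan,
                    "threshold_used": np.nan,
                    "positive_outside_region": 0,
                    "status": "no_unique_peptides",
                }
            )
            continue
        for pep in peptides:
            bin_idx = match_peptide(pep, peak_table, tolerance_da=match_tolerance_da)
            if bin_idx is None:
                rows.append(
                    {
                        "marker": protein.accession,
                        "peptide": pep.sequence,
                        "target_mz": pep.mh_mono,
                        "region_name": region_name,
                        "dice": np.nan,
                        "iou": np.nan,
                        "threshold_used": np.nan,
                        "positive_outside_region": 0,
                        "status": "no_peak",
                    }
                )
                continue
            image = render_ion_image(
                peak_table,
                float(peak_table.bin_centers[bin_idx]),
                tolerance_da=match_tolerance_da,
            )
            image.marker = protein.accession
            image.peptide_sequence = pep.sequence
            try:
                rows.append(overlap_score(image, annotation, region_name, threshold))
            except (KeyError, ValueError) as exc:
                raise RuntimeError(f"marker {protein.accession}: {exc}") from exc
    return pd.DataFrame(rows)
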