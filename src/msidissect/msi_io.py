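"""Raster data model and readers/writers for every external format the pipeline touches.

Formats: imzML 1.1 (continuous and processed binary modes), FASTA protein
records, MGF peak-list export, and CSV/PNG region-annotation rasters with a
CSV legend. Internal conventions: pixel coordinates are 0-based with x
increasing rightward and y increasing downward; imzML's 1-based convention is
converted at the boundary.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger("msidissect")

#: The 20 standard amino-acid one-letter codes. Ambiguity codes (B, Z, X) and
#: the rare translated residues (U, O) are rejected because downstream peptide
#: masses must be exact.
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


class MsiIOError(IOError):
    """Raised when an external file is missing, malformed or unsupported."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Spectrum:
    """A single mass spectrum: m/z values (Da, strictly ascending) and
    non-negative intensities of equal length."""

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError(
                f"mz and intensity must be 1-D arrays of equal length, "
                f"got {self.mz.shape} vs {self.intensity.shape}"
            )
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("mz values must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return int(self.mz.size)

    @property
    def tic(self) -> float:
        """Total ion current (summed intensity)."""
        return float(self.intensity.sum())


@dataclass
class MSIDataset:
    """An MSI acquisition: one spectrum per (x, y) grid pixel.

    Parameters
    ----------
    pixels
        0-based integer (x, y) coordinates, unique, x right / y down.
    spectra
        One :class:`Spectrum` per pixel, same order as ``pixels``.
    pixel_size_um
        Physical pixel spacing; 100 um is the nominal acquisition raster.
    mz_range
        Optional acquisition window (low, high) in Da; when set, every
        spectrum must lie inside it.
    mode
        ``"profile"`` or ``"centroid"``.
    """

    pixels: list[tuple[int, int]]
    spectra: list[Spectrum]
    pixel_size_um: float = 100.0
    mz_range: tuple[float, float] | None = (600.0, 3200.0)
    mode: str = "centroid"

    def __post_init__(self) -> None:
        if len(self.pixels) != len(self.spectra):
            raise ValueError("one spectrum per pixel required")
        if len(set(self.pixels)) != len(self.pixels):
            raise ValueError("duplicate pixel coordinates")
        if self.mode not in ("profile", "centroid"):
            raise ValueError(f"mode must be 'profile' or 'centroid', got {self.mode!r}")
        if self.mz_range is not None:
            lo, hi = self.mz_range
            for (x, y), sp in zip(self.pixels, self.spectra):
                if len(sp) and (sp.mz[0] < lo - 1e-9 or sp.mz[-1] > hi + 1e-9):
                    raise ValueError(
                        f"pixel ({x},{y}) has m/z outside the acquisition "
                        f"window [{lo}, {hi}]"
                    )

    def __len__(self) -> int:
        return len(self.pixels)

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of the bounding grid."""
        xs = [x for x, _ in self.pixels]
        ys = [y for _, y in self.pixels]
        return (max(ys) + 1, max(xs) + 1)


@dataclass
class RegionAnnotation:
    """Pathologist-style region labels on the pixel grid.

    ``label_map`` is an integer raster (rows = y); ``legend`` maps each code
    to a region name. Code 0 is reserved for background/off-tissue.
    """

    label_map: np.ndarray
    legend: dict[int, str]

    def __post_init__(self) -> None:
        self.label_map = np.asarray(self.label_map, dtype=int)
        if self.label_map.ndim != 2:
            raise ValueError("label_map must be 2-D")
        codes = set(np.unique(self.label_map)) - {0}
        orphans = sorted(codes - set(self.legend))
        if orphans:
            raise ValueError(
                "orphan code" + ("s" if len(orphans) > 1 else "")
                + " " + ", ".join(str(c) for c in orphans)
                + " present in raster but absent from legend"
            )

    def mask(self, region_name: str) -> np.ndarray:
        """Boolean mask of all codes whose legend name equals ``region_name``."""
        codes = [c for c, n in self.legend.items() if n == region_name]
        if not codes:
            raise KeyError(f"region {region_name!r} not in legend")
        return np.isin(self.label_map, codes)

    def name_of(self, code: int) -> str:
        if code == 0:
            return "background"
        return self.legend[code]


@dataclass
class ProteinRecord:
    """A protein sequence with its accession (e.g. UniProt 'P08729')."""

    accession: str
    name: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"record {self.accession}: empty sequence")
        bad = sorted(set(self.sequence) - STANDARD_RESIDUES)
        if bad:
            raise ValueError(
                f"record {self.accession}: illegal residue(s) "
                f"{', '.join(bad)} (only the 20 standard amino acids allowed)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# imzML
# ---------------------------------------------------------------------------

def read_imzml(path: str | Path) -> MSIDataset:
    """Read an imzML/ibd file pair into an :class:`MSIDataset`.

    Both continuous and processed binary modes are supported. imzML's 1-based
    pixel coordinates are shifted to the internal 0-based convention, and
    negative raw intensities are clipped to zero (their count is logged).
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    if not path.exists():
        raise MsiIOError(f"imzML file not found: {path}")
    ibd = path.with_suffix(".ibd")
    if not ibd.exists():
        raise MsiIOError(f"missing companion binary file: expected {ibd}")
    try:
        parser = ImzMLParser(str(path))
    except Exception as exc:  # malformed XML / unsupported dialect
        raise MsiIOError(f"cannot parse {path}: unsupported dialect ({exc})") from exc

    pixels: list[tuple[int, int]] = []
    spectra: list[Spectrum] = []
    n_clipped = 0
    per_pixel_axes = False
    first_mz: np.ndarray | None = None
    for i, (x, y, _z) in enumerate(parser.coordinates):
        mz, inten = parser.getspectrum(i)
        mz = np.asarray(mz, dtype=float)
        inten = np.asarray(inten, dtype=float)
        neg = inten < 0
        if neg.any():
            n_clipped += int(neg.sum())
            inten = np.where(neg, 0.0, inten)
        if first_mz is None:
            first_mz = mz
        elif mz.shape != first_mz.shape or not np.array_equal(mz, first_mz):
            per_pixel_axes = True
        pixels.append((int(x) - 1, int(y) - 1))  # imzML is 1-based
        spectra.append(Spectrum(mz, inten))
    if n_clipped:
        logger.warning("read_imzml: clipped %d negative intensities to 0", n_clipped)

    mode = "processed" if per_pixel_axes else "continuous"
    lo = min((float(s.mz[0]) for s in spectra if len(s)), default=0.0)
    hi = max((float(s.mz[-1]) for s in spectra if len(s)), default=0.0)
    return MSIDataset(
        pixels=pixels,
        spectra=spectra,
        mz_range=(lo, hi) if spectra else None,
        mode="centroid" if mode == "processed" else "profile",
    )


def write_imzml(dataset: MSIDataset, path: str | Path) -> Path:
    """Write a dataset as a standard imzML/ibd pair; returns the imzML path.

    Centroid datasets are written in processed mode (per-pixel m/z axes);
    profile datasets in continuous mode. Pixels with empty spectra
    (off-tissue blanks) are omitted — imzML has no representation for a
    pixel without data — and their count is logged.
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    if len(dataset) == 0:
        raise ValueError("refusing to write an empty dataset")
    path = Path(path)
    mode = "processed" if dataset.mode == "centroid" else "continuous"
    n_empty = 0
    with ImzMLWriter(
        str(path),
        mode=mode,
        intensity_dtype=np.float64,
        spec_type=dataset.mode,
    ) as writer:
        for (x, y), sp in zip(dataset.pixels, dataset.spectra):
            if len(sp) == 0:
                n_empty += 1
                continue
            writer.addSpectrum(sp.mz, sp.intensity, (x + 1, y + 1, 1))
    if n_empty == len(dataset):
        raise ValueError("refusing to write a dataset with only empty spectra")
    if n_empty:
        logger.warning("write_imzml: omitted %d empty (off-tissue) spectra", n_empty)
    return path


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_UNIPROT_HEADER = re.compile(r"^(?:sp|tr)\|([^|]+)\|(\S*)")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records, accepting UniProt ('sp|P51654|GPC3_HUMAN ...')
    and bare ('>P51654') header dialects."""
    from Bio import SeqIO

    path = Path(path)
    records: list[ProteinRecord] = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        m = _UNIPROT_HEADER.match(rec.id)
        if m:
            accession, name = m.group(1), m.group(2) or m.group(1)
        else:
            accession, name = rec.id, rec.description or rec.id
        seq = re.sub(r"\s", "", str(rec.seq)).upper()
        try:
            records.append(ProteinRecord(accession=accession, name=name, sequence=seq))
        except ValueError as exc:
            raise ValueError(f"FASTA record {i} ({accession}): {exc}") from exc
    if not records:
        raise MsiIOError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path, width: int = 60) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.accession} {rec.name}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")
    return path


# ---------------------------------------------------------------------------
# MGF export
# ---------------------------------------------------------------------------

def write_mgf(peak_list, path: str | Path, title: str = "msidissect peak list") -> Path:
    """Export a peak list as a single-block Mascot Generic Format file.

    Peaks are written sorted ascending by m/z, one "m/z intensity" pair per
    line between BEGIN IONS / END IONS.
    """
    peaks = sorted((float(mz), float(inten)) for mz, inten in peak_list)
    if not peaks:
        raise ValueError("refusing to write an empty peak list")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("BEGIN IONS\n")
        fh.write(f"TITLE={title}\n")
        fh.write("CHARGE=1+\n")
        for mz, inten in peaks:
            fh.write(f"{mz:.6f} {inten:.6f}\n")
        fh.write("END IONS\n")
    return path


# ---------------------------------------------------------------------------
# Region annotations
# ---------------------------------------------------------------------------

def read_region_annotation(raster_path: str | Path, legend_path: str | Path) -> RegionAnnotation:
    """Load a label raster (integer CSV, or palette/grayscale PNG) plus a
    ``code,name`` legend CSV into a validated :class:`RegionAnnotation`."""
    raster_path = Path(raster_path)
    legend_path = Path(legend_path)
    if raster_path.suffix.lower() == ".png":
        from PIL import Image

        img = Image.open(raster_path)
        if img.mode not in ("P", "L", "I", "I;16"):
            raise MsiIOError(
                f"PNG raster must be palette or grayscale, got mode {img.mode!r}"
            )
        label_map = np.asarray(img, dtype=int)
    else:
        label_map = np.loadtxt(raster_path, delimiter=",", dtype=int, ndmin=2)

    legend: dict[int, str] = {}
    with open(legend_path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].strip().lower() in ("code", ""):
                continue
            legend[int(row[0])] = row[1].strip()
    return RegionAnnotation(label_map=label_map, legend=legend)


def write_region_annotation(
    annotation: RegionAnnotation, raster_path: str | Path, legend_path: str | Path
) -> None:
    """Write the raster as an integer CSV and the legend as code,name CSV."""
    np.savetxt(raster_path, annotation.label_map, fmt="%d", delimiter=",")
    with open(legend_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["code", "name"])
        for code in sorted(annotation.legend):
            writer.writerow([code, annotation.legend[code]])
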