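"""Hierarchical spatial segmentation of pixel spectra and component
quantification.

Segmentation is recursive bisecting k-means (k = 2 at each split) on the
rows of an aligned peak table, optionally unit-variance scaled per column.
"Weak denoising" is a single 3x3 median filter applied to the binary label
image after each split (off-grid and off-node neighbours ignored), which
suppresses salt-and-pepper misassignments the way spatial denoising presets
do in MSI segmentation software. The result is an arborescence whose leaves
tile the tissue mask; cutting it at depth 1 yields the two dominant
molecular phenotypes, and relative quantification compares each component's
spectrum count to the total per case.
"""

from __future__ import annotations

import decimal
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import convolve2d
from sklearn.cluster import KMeans

from .msi_io import RegionAnnotation
from .preprocess import PeakTable

logger = logging.getLogger("msidissect")

MIN_NODE_PIXELS = 10  # below this, splits chase noise at phantom scale
KMEANS_RESTARTS = 10


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal round-half-up (0.05 at one decimal rounds to 0.1)."""
    q = decimal.Decimal(1).scaleb(-decimals)
    return float(decimal.Decimal(repr(float(value))).quantize(q, rounding=decimal.ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Tree structure
# ---------------------------------------------------------------------------

@dataclass
class SegmentationNode:
    """One node of the arborescence: a set of member pixel rows and, through
    the owning tree, a renderable label image."""

    node_id: int
    depth: int
    pixel_rows: np.ndarray  # row indices into the peak table
    children: list["SegmentationNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __len__(self) -> int:
        return int(self.pixel_rows.size)


@dataclass
class SegmentationTree:
    """Binary segmentation arborescence over the non-blank pixels.

    ``params`` records scaling/denoise/seed/depth so identical input and
    seed reproduce an identical tree.
    """

    root: SegmentationNode
    pixel_index: list[tuple[int, int]]
    grid_shape: tuple[int, int]
    params: dict

    def nodes_at_depth(self, depth: int) -> list[SegmentationNode]:
        """Clusters of the cut at ``depth``: nodes at that depth plus any
        leaf that bottomed out shallower."""
        found: list[SegmentationNode] = []

        def walk(node: SegmentationNode) -> None:
            if node.depth == depth or (node.is_leaf and node.depth < depth):
                found.append(node)
                return
            for child in node.children:
                walk(child)

        walk(self.root)
        return found

    def leaves(self) -> list[SegmentationNode]:
        found: list[SegmentationNode] = []

        def walk(node: SegmentationNode) -> None:
            if node.is_leaf:
                found.append(node)
            for child in node.children:
                walk(child)

        walk(self.root)
        return found

    def label_image(self, depth: int) -> np.ndarray:
        """Integer raster of the cut at ``depth``; -1 marks off-tissue."""
        img = np.full(self.grid_shape, -1, dtype=int)
        for label, node in enumerate(self.nodes_at_depth(depth)):
            for row in node.pixel_rows:
                x, y = self.pixel_index[row]
                img[y, x] = label
        return img

    def to_json(self, path: str | Path) -> Path:
        def encode(node: SegmentationNode) -> dict:
            return {
                "node_id": node.node_id,
                "depth": node.depth,
                "n_pixels": len(node),
                "pixel_rows": node.pixel_rows.tolist(),
                "children": [encode(c) for c in node.children],
            }

        path = Path(path)
        path.write_text(json.dumps({"params": self.params, "root": encode(self.root)}, indent=2))
        return path


# ---------------------------------------------------------------------------
# Weak denoising
# ---------------------------------------------------------------------------

def _median_denoise(
    labels: np.ndarray, rows: np.ndarray, pixel_index: list, grid_shape: tuple[int, int]
) -> np.ndarray:
    """One pass of a 3x3 majority (median) filter on the binary split labels,
    restricted to the node's own pixels; ties keep the original label."""
    in_node = np.zeros(grid_shape, dtype=float)
    lab_img = np.zeros(grid_shape, dtype=float)
    coords = [(pixel_index[r][1], pixel_index[r][0]) for r in rows]  # (y, x)
    for (y, x), lab in zip(coords, labels):
        in_node[y, x] = 1.0
        lab_img[y, x] = float(lab)
    kernel = np.ones((3, 3))
    votes_total = convolve2d(in_node, kernel, mode="same")
    votes_one = convolve2d(lab_img, kernel, mode="same")
    new_labels = labels.copy()
    for i, (y, x) in enumerate(coords):
        ones = votes_one[y, x]
        total = votes_total[y, x]
        if 2 * ones > total:
            new_labels[i] = 1
        elif 2 * ones < total:
            new_labels[i] = 0
        # exact tie: keep original
    return new_labels


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def segment(
    peak_table: PeakTable,
    depth: int = 1,
    scaling: str = "unit_variance",
    denoise: str = "weak",
    seed: int = 0,
) -> SegmentationTree:
    """Recursive bisecting k-means segmentation of the peak table rows.

    Blank (all-zero) pixels are excluded up front. Columns are optionally
    scaled to unit variance over the non-blank rows. At each node a 2-means
    split (k-means++ init, 10 restarts, seeded deterministically from the
    caller's seed and the node id) partitions the pixels; with
    ``denoise="weak"`` the binary label image is median-filtered once before
    memberships are fixed. Recursion stops at ``depth``, below
    ``MIN_NODE_PIXELS`` members, or when a split yields no within-cluster
    variance reduction (identical rows), which produces a single leaf.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if scaling not in ("unit_variance", "none"):
        raise ValueError(f"unknown scaling {scaling!r}")
    if denoise not in ("weak", "none"):
        raise ValueError(f"unknown denoise {denoise!r}")

    blank = peak_table.empty_rows()
    rows = np.flatnonzero(~blank)
    if rows.size < 2:
        raise ValueError("segmentation requires at least 2 non-empty pixels")

    X = peak_table.matrix[rows].astype(float)
    X = X - X.mean(axis=0)
    if scaling == "unit_variance":
        sd = X.std(axis=0)
        keep = sd > 0
        if not keep.all():
            logger.warning("segment: dropping %d zero-variance column(s)", int((~keep).sum()))
        X = X[:, keep] / sd[keep]

    grid_shape = peak_table.grid_shape()
    counter = [0]

    def split(node: SegmentationNode) -> None:
        if node.depth >= depth or len(node) < MIN_NODE_PIXELS:
            return
        local = np.searchsorted(rows, node.pixel_rows)
        sub = X[local]
        if np.allclose(sub, sub[0], atol=1e-12):
            logger.warning("segment: node %d has identical rows; not split", node.node_id)
            return
        node_seed = (int(seed) * 100003 + node.node_id * 9973) % (2**31)
        km = KMeans(
            n_clusters=2,
            n_init=KMEANS_RESTARTS,
            random_state=node_seed,
            init="k-means++",
        ).fit(sub)
        labels = km.labels_.astype(int)
        if denoise == "weak":
            denoised = _median_denoise(labels, node.pixel_rows, peak_table.pixel_index, grid_shape)
            if 0 < denoised.sum() < denoised.size:
                labels = denoised  # keep only if both children survive
        if labels.sum() in (0, labels.size):
            logger.warning("segment: degenerate split at node %d; kept as leaf", node.node_id)
            return
        for lab in (0, 1):
            counter[0] += 1
            child = SegmentationNode(
                node_id=counter[0],
                depth=node.depth + 1,
                pixel_rows=node.pixel_rows[labels == lab],
            )
            node.children.append(child)
            split(child)

    root = SegmentationNode(node_id=0, depth=0, pixel_rows=rows)
    split(root)
    return SegmentationTree(
        root=root,
        pixel_index=peak_table.pixel_index,
        grid_shape=grid_shape,
        params={
            "depth": depth,
            "scaling": scaling,
            "denoise": denoise,
            "seed": int(seed),
            "min_node_pixels": MIN_NODE_PIXELS,
        },
    )


# ---------------------------------------------------------------------------
# Component assignment
# ---------------------------------------------------------------------------

def assign_components(
    tree: SegmentationTree,
    depth_of_cut: int,
    annotation: RegionAnnotation | None = None,
    mapping: dict[int, str] | None = None,
) -> dict:
    """Name each cluster of a tree cut with a tissue component.

    With an annotation, each cluster takes the majority region name among its
    pixels (background code 0 ignored; an exact tie is broken toward the
    lower region code and logged). Without one, an explicit ``mapping`` from
    cluster position to name is required. Returns a dict with the named
    label map (string raster, "" off-tissue) and the recorded mapping.
    """
    clusters = tree.nodes_at_depth(depth_of_cut)
    if len(clusters) < 2:
        raise ValueError("tree cut must yield at least 2 clusters")

    names: dict[int, str] = {}
    for idx, node in enumerate(clusters):
        if mapping is not None:
            if idx not in mapping:
                raise ValueError(f"cluster {idx} has no name in the supplied mapping")
            names[idx] = mapping[idx]
            continue
        if annotation is None:
            raise ValueError(f"cluster {idx} unnamed: provide an annotation or mapping")
        codes = np.array(
            [
                annotation.label_map[tree.pixel_index[r][1], tree.pixel_index[r][0]]
                for r in node.pixel_rows
            ]
        )
        codes = codes[codes != 0]
        if codes.size == 0:
            raise ValueError(f"cluster {idx} lies entirely on background; cannot name it")
        counts = np.bincount(codes)
        best = int(np.flatnonzero(counts == counts.max())[0])  # tie -> lower code
        if int((counts == counts.max()).sum()) > 1:
            logger.warning("assign_components: tie for cluster %d broken toward code %d", idx, best)
        names[idx] = annotation.legend[best]

    label_map = np.full(tree.grid_shape, "", dtype=object)
    for idx, node in enumerate(clusters):
        for r in node.pixel_rows:
            x, y = tree.pixel_index[r]
            label_map[y, x] = names[idx]
    return {"label_map": label_map, "mapping": names, "clusters": clusters}


# ---------------------------------------------------------------------------
# Quantification
# ---------------------------------------------------------------------------

@dataclass
class QuantificationTable:
    """Per-component spectrum counts and percentages (one decimal, half-up),
    mirroring a per-case quantification table."""

    total_spectra: int
    counts: dict[str, int]
    percentages: dict[str, float]

    @classmethod
    def from_counts(cls, counts: dict[str, int]) -> "QuantificationTable":
        total = sum(counts.values())
        if total <= 0:
            raise ValueError("zero total spectra")
        pct = {k: round_half_up(100.0 * v / total, 1) for k, v in counts.items()}
        return cls(total_spectra=total, counts=dict(counts), percentages=pct)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "component": list(self.counts),
                "spectra": [self.counts[k] for k in self.counts],
                "percent": [self.percentages[k] for k in self.counts],
                "total_spectra": self.total_spectra,
            }
        )


DEFAULT_FOLDING = {
    "fibrosis_iCCA": "iCCA",
    "fibrosis_HCC": "HCC",
    "focus_iCCA": "iCCA",
    "focus_HCC": "HCC",
}


def quantify(label_map: np.ndarray, fold: dict[str, str] | None = None) -> QuantificationTable:
    """Count labeled pixels per component and convert to percentages.

    ``label_map`` holds component names ("" or None = off-tissue). Fibrosis
    and focus sub-labels are folded into their parent component by default,
    so the result is the iCCA/HCC two-component table.
    """
    fold = DEFAULT_FOLDING if fold is None else fold
    counts: dict[str, int] = {}
    for value in np.asarray(label_map, dtype=object).ravel():
        if value in (None, "", -1):
            continue
        name = fold.get(str(value), str(value))
        counts[name] = counts.get(name, 0) + 1
    if not counts:
        raise ValueError("zero total spectra: no labeled pixels")
    return QuantificationTable.from_counts(counts)
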