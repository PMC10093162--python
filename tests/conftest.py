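"""Shared fixtures: seeded phantoms and the 20-seed evaluation suite."""

from __future__ import annotations

import logging

import numpy as np
import pytest
from scipy.stats import pointbiserialr

import msidissect as md

logging.disable(logging.WARNING)

SUITE_SEEDS = list(range(1, 21))


@pytest.fixture(scope="session")
def phantom_bundle():
    """One default phantom (seed 1) with its peak table and marker context."""
    spec, ctx = md.default_phantom_spec(seed=1)
    dataset, annotation, truth = md.make_phantom(spec)
    table = md.build_peak_table(dataset)
    return {
        "spec": spec,
        "ctx": ctx,
        "dataset": dataset,
        "annotation": annotation,
        "truth": truth,
        "table": table,
    }


def evaluate_phantom(seed: int, denoise: str = "weak") -> dict:
    """Run segmentation, quantification, PCA and the virtual-IHC panel on
    one default phantom and collect the recovery metrics."""
    spec, ctx = md.default_phantom_spec(seed=seed)
    dataset, annotation, _ = md.make_phantom(spec)
    table = md.build_peak_table(dataset)

    tree = md.segment(table, depth=1, denoise=denoise, seed=seed)
    ari = md.segmentation_ari(tree, annotation)
    assigned = md.assign_components(tree, 1, annotation=annotation)
    quant = md.quantify(assigned["label_map"])
    planted = md.phenotype_fractions(annotation)
    pct_err = max(
        abs(quant.percentages.get(name, 0.0) - planted[name]) for name in planted
    )
    recall = md.focus_recall(assigned["label_map"], annotation)

    pca = md.run_pca(table, n_components=2)
    pm = md.phenotype_map(annotation)
    is_icca = [
        1 if pm[y, x] == "iCCA" else 0
        for x, y in (table.pixel_index[r] for r in pca.pixel_rows)
    ]
    pbc, _ = pointbiserialr(is_icca, pca.scores[:, 0])

    specific = [
        (ctx["markers"][acc], region)
        for acc, region in ctx["marker_regions"].items()
        if region in ("HCC", "iCCA")
    ]
    own = md.virtual_panel(specific, ctx["proteome"], table, annotation)
    flip = {"HCC": "iCCA", "iCCA": "HCC"}
    other = md.virtual_panel(
        [(p, flip[r]) for p, r in specific], ctx["proteome"], table, annotation
    )
    return {
        "seed": seed,
        "ari": ari,
        "pct_err": pct_err,
        "focus_recall": recall,
        "pc1_point_biserial": abs(float(pbc)),
        "own_dice_min": float(own["dice"].min()),
        "other_dice_max": float(other["dice"].max()),
        "own_dice": own["dice"].tolist(),
        "other_dice": other["dice"].tolist(),
        "panel_status": own["status"].tolist(),
    }


@pytest.fixture(scope="session")
def phantom_suite():
    """Recovery metrics over the 20-seed default-phantom suite."""
    return [evaluate_phantom(seed) for seed in SUITE_SEEDS]
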