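"""Desk-scale end-to-end experiments on synthetic cohorts.

These are the study conditions the package's tests and the reproduction
script run: 256×256 synthetic slides tiled at 64×64, a compact residual
network (8 filters, 2 residual blocks, 10 epochs, CPU), and twofold
slide-level cross-validation.  The full-scale profile (512×512 tiles, 32
filters) uses the same code paths and is documented in docs/methods.md.
"""

from __future__ import annotations

import logging

import numpy as np

from .aggregate import roc_auc
from .cv import cross_validate, split_slides
from .io import BIOMARKERS, BiomarkerLabelVector
from .synthetic import SynthParams, generate_dataset
from .tiling import tile_slide

logger = logging.getLogger("histomut")

#: Compact network profile used for CPU-scale experiments.
DESK_NET: dict = {
    "input_size": 64,
    "n_filters": 8,
    "kernel_size": 3,
    "n_residual_blocks": 2,
    "batch_size": 16,
    "loss": "bce",
    "learning_rate": 0.05,
    "l2": 1e-4,
    "epochs": 10,
}

DESK_TILE_SIZE = 64


def build_tile_dataset(params: SynthParams, tile_size: int = DESK_TILE_SIZE,
                       bg_max: float = 0.75, tumor_min: float = 0.5):
    """Generate a cohort and tile it: (tile stack, tile slide ids, labels)."""
    slides, labels, _ = generate_dataset(params)
    X, sids = [], []
    for rec in slides:
        for t in tile_slide(rec, size=tile_size, bg_max=bg_max,
                            tumor_min=tumor_min):
            X.append(t.pixels)
            sids.append(rec.slide_id)
    if not X:
        raise RuntimeError("no tiles survived filtering")
    return np.stack(X), np.asarray(sids), labels


def _shuffle_labels(labels: dict[str, BiomarkerLabelVector], seed: int
                    ) -> dict[str, BiomarkerLabelVector]:
    """Permute label vectors across slides (breaks any label-image link)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5FFE]))
    sids = sorted(labels)
    perm = rng.permutation(len(sids))
    return {sids[i]: labels[sids[perm[i]]] for i in range(len(sids))}


def signal_recovery_run(delta: float, seed: int, n_slides: int = 20,
                        shuffle_labels: bool = False,
                        net: dict | None = None) -> dict:
    """One twofold-CV run on a fresh synthetic cohort with effect size δ.

    Returns slide-level AUCs per biomarker, the signal biomarker's slide- and
    tile-level AUC, and the CV report (fold assignments included).
    """
    net = dict(DESK_NET if net is None else net)
    params = SynthParams(effect_size=delta, seed=seed, n_slides=n_slides)
    X, sids, labels = build_tile_dataset(params)
    if shuffle_labels:
        labels = _shuffle_labels(labels, seed)

    report = cross_validate(X, sids, labels, seed=seed, **net)

    # tile-level AUC for the signal biomarker over pooled validation tiles
    j = BIOMARKERS.index(params.signal_biomarker)
    scores, ys = [], []
    for probs, tile_sids in report.val_tile_probs.values():
        scores.append(probs[:, j])
        ys.append(np.array([labels[s].values[j] for s in tile_sids]))
    scores = np.concatenate(scores)
    ys = np.concatenate(ys)
    tile_auc = roc_auc(scores, ys).auc if len(np.unique(ys)) == 2 else float("nan")

    return {
        "signal_biomarker": params.signal_biomarker,
        "signal_auc": report.mean_auc[params.signal_biomarker],
        "tile_auc": tile_auc,
        "mean_auc": report.mean_auc,
        "n_tiles": len(X),
        "report": report,
    }


def median_signal_auc(delta: float, seeds, n_slides: int = 20,
                      shuffle_labels: bool = False) -> dict:
    """Median slide/tile signal AUC over several seeded cohorts."""
    runs = [signal_recovery_run(delta, s, n_slides, shuffle_labels)
            for s in seeds]
    return {
        "runs": runs,
        "median_signal_auc": float(np.median([r["signal_auc"] for r in runs])),
        "median_tile_auc": float(np.median([r["tile_auc"] for r in runs])),
    }
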