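"""Slide-level aggregation: mean tile probabilities, ROC/AUC, heat maps.

A slide's score for a biomarker is the unweighted arithmetic mean of its
tiles' predicted probabilities.  ROC curves sweep the unique scores as
thresholds; the trapezoidal AUC then equals the Mann-Whitney concordance
probability with ties counted one half.  Heat maps score scanning windows
with the tile classifier and assign every pixel the mean probability of the
windows covering it; windows failing the tiling keep-rule contribute nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
from matplotlib import colormaps

from .io import BIOMARKERS, N_BIOMARKERS, BiomarkerLabelVector, SlideRecord
from .tiling import background_mask

logger = logging.getLogger("histomut")


@dataclass
class SlidePrediction:
    """Per-biomarker mean tile probability for one slide."""

    slide_id: str
    mean_probability: np.ndarray  # (8,)
    n_tiles: int

    def __post_init__(self) -> None:
        self.mean_probability = np.asarray(self.mean_probability, dtype=float)
        if self.n_tiles < 1:
            raise ValueError("n_tiles must be >= 1")
        if self.mean_probability.shape != (N_BIOMARKERS,):
            raise ValueError(
                f"expected {N_BIOMARKERS} probabilities, got "
                f"{self.mean_probability.shape}")
        if np.any(self.mean_probability < 0) or np.any(self.mean_probability > 1):
            raise ValueError("probabilities outside [0, 1]")


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


@dataclass
class HeatMap:
    """Per-pixel mean window probability for one slide and biomarker."""

    values: np.ndarray    # (H, W) float, NaN where coverage == 0
    coverage: np.ndarray  # (H, W) int, windows contributing per pixel
    biomarker: str
    slide_id: str = ""


def slide_probability(tile_probs: np.ndarray, slide_id: str = ""
                      ) -> SlidePrediction:
    """Mean of per-tile probability 8-vectors."""
    P = np.atleast_2d(np.asarray(tile_probs, dtype=float))
    if P.size == 0:
        raise ValueError("no tiles to aggregate")
    return SlidePrediction(slide_id=slide_id,
                           mean_probability=P.mean(axis=0),
                           n_tiles=len(P))


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """ROC curve and trapezoidal AUC; ties contribute half a concordance."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        missing = "positive" if n_pos == 0 else "negative"
        raise ValueError(f"ROC needs both classes; no {missing} labels")

    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    # group tied scores so the curve steps diagonally through ties
    uniq, idx = np.unique(-s_sorted, return_index=True)
    boundaries = np.append(idx, len(s_sorted))
    tp = fp = 0
    tpr = [0.0]
    fpr = [0.0]
    for b0, b1 in zip(boundaries[:-1], boundaries[1:]):
        tp += int((y_sorted[b0:b1] == 1).sum())
        fp += int((y_sorted[b0:b1] == 0).sum())
        tpr.append(tp / n_pos)
        fpr.append(fp / n_neg)
    thresholds = np.array([np.inf, *(-uniq)])
    fpr = np.asarray(fpr)
    tpr = np.asarray(tpr)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


def evaluate_dataset(predictions: Sequence[SlidePrediction],
                     labels: Mapping[str, BiomarkerLabelVector]
                     ) -> dict[str, ROCResult]:
    """One ROCResult per biomarker over slide-level mean probabilities."""
    if len(predictions) == 0:
        raise ValueError("no predictions to evaluate")
    out: dict[str, ROCResult] = {}
    y = np.stack([labels[p.slide_id].as_array() for p in predictions])
    scores = np.stack([p.mean_probability for p in predictions])
    for j, biomarker in enumerate(BIOMARKERS):
        if len(np.unique(y[:, j])) < 2:
            logger.warning("biomarker %s has a single class; skipped",
                           biomarker)
            continue
        out[biomarker] = roc_auc(scores[:, j], y[:, j])
    return out


def metrics_bundle(rocs: Mapping[str, ROCResult]) -> dict:
    """Evaluation bundle in the on-disk metrics layout."""
    return {b: {"auc": r.auc, "fpr": r.fpr.tolist(), "tpr": r.tpr.tolist()}
            for b, r in rocs.items()}


def heatmap(slide: SlideRecord,
            model,
            biomarker: str,
            window: int = 512,
            stride: int | None = None,
            bg_max: float = 0.75,
            tumor_min: float = 0.5) -> HeatMap:
    """Scan the slide with a window, score each kept window, average per pixel.

    ``model`` is either a fitted tile classifier (``predict_proba``) or a
    callable mapping an (n, window, window, 3) batch to (n,) scores.
    """
    if stride is None:
        stride = window
    if stride < 1:
        raise ValueError("stride must be >= 1")
    h, w = slide.shape
    if window > h or window > w:
        raise ValueError(
            f"window {window} exceeds slide dimensions {(h, w)}")

    j = BIOMARKERS.index(biomarker)
    bg = background_mask(slide.image)
    origins, batches = [], []
    for y0 in range(0, h - window + 1, stride):
        for x0 in range(0, w - window + 1, stride):
            win = (slice(y0, y0 + window), slice(x0, x0 + window))
            if float(bg[win].mean()) <= bg_max and \
                    float(slide.tumor_mask[win].mean()) >= tumor_min:
                origins.append((y0, x0))
                batches.append(slide.image[win])

    acc = np.zeros((h, w), dtype=float)
    cov = np.zeros((h, w), dtype=int)
    if origins:
        batch = np.stack(batches)
        if callable(model) and not hasattr(model, "predict_proba"):
            scores = np.asarray(model(batch), dtype=float)
        else:
            scores = model.predict_proba(batch)[:, j]
        for (y0, x0), p in zip(origins, scores):
            acc[y0:y0 + window, x0:x0 + window] += p
            cov[y0:y0 + window, x0:x0 + window] += 1

    values = np.full((h, w), np.nan)
    covered = cov > 0
    values[covered] = acc[covered] / cov[covered]
    return HeatMap(values=values, coverage=cov, biomarker=biomarker,
                   slide_id=slide.slide_id)


def render_heatmap(hm: HeatMap, out_path: str | Path,
                   cmap_name: str = "bwr") -> None:
    """Write a blue→red RGBA overlay plus the numeric matrix (lossless CSV).

    Uncovered pixels are fully transparent in the overlay and NaN in the
    matrix, which is written next to the image with suffix ``.csv``.
    """
    out_path = Path(out_path)
    cmap = colormaps[cmap_name]
    vals = np.where(np.isnan(hm.values), 0.0, hm.values)
    rgba = (cmap(vals) * 255).astype(np.uint8)
    rgba[..., 3] = np.where(hm.coverage > 0, 255, 0)
    iio.imwrite(out_path, rgba)
    np.savetxt(out_path.with_suffix(out_path.suffix + ".csv"),
               hm.values, delimiter=",", fmt="%.17g")


def read_heatmap_matrix(path: str | Path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=","))
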