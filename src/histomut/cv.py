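"""Slide-level twofold cross-validation and hyperparameter grid search.

Slides — never tiles — are split 1:1 into two folds, so all tiles of a slide
share its fold and no slide leaks between training and validation.  Each fold
serves once as validation for a model trained on the other; per-biomarker
slide-level AUCs are averaged over the two folds.  The hyperparameter grid
spans exactly four dimensions: filter count, residual-block count, batch
size, and loss function.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aggregate import roc_auc, slide_probability
from .io import BIOMARKERS, N_BIOMARKERS, BiomarkerLabelVector
from .net import TilePatchClassifier

logger = logging.getLogger("histomut")

GRID_DIMENSIONS = ("n_filters", "n_residual_blocks", "batch_size", "loss")


@dataclass
class CVReport:
    fold_assignments: dict[str, int]
    per_fold_auc: dict[str, list[float]]   # biomarker -> [fold1, fold2] AUC
    mean_auc: dict[str, float]             # biomarker -> mean over folds
    best_config: dict | None = None
    table: pd.DataFrame | None = None      # grid-search score table
    #: per validation fold: (tile probability matrix, tile slide-id array)
    val_tile_probs: dict[int, tuple[np.ndarray, np.ndarray]] | None = None

    @property
    def overall_mean_auc(self) -> float:
        vals = [v for v in self.mean_auc.values() if np.isfinite(v)]
        return float(np.mean(vals)) if vals else float("nan")


def split_slides(slide_ids: list[str], seed: int) -> dict[str, int]:
    """Seeded 1:1 slide-level partition into folds {1, 2}.

    With an odd count the extra slide goes to fold 1.
    """
    ids = list(slide_ids)
    if len(ids) < 2:
        raise ValueError(f"need at least 2 slides to split, got {len(ids)}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF01D]))
    order = rng.permutation(len(ids))
    half = (len(ids) + 1) // 2
    folds = {}
    for rank, i in enumerate(order):
        folds[ids[i]] = 1 if rank < half else 2
    return folds


def _slide_level_aucs(probs: np.ndarray, slide_ids: np.ndarray,
                      labels: dict[str, BiomarkerLabelVector]
                      ) -> dict[str, float]:
    """Mean tile probability per slide, then per-biomarker AUC over slides."""
    uniq = sorted(set(slide_ids.tolist()))
    preds = [slide_probability(probs[slide_ids == sid], sid) for sid in uniq]
    scores = np.stack([p.mean_probability for p in preds])
    y = np.stack([labels[sid].as_array() for sid in uniq])
    out: dict[str, float] = {}
    for j, b in enumerate(BIOMARKERS):
        if len(np.unique(y[:, j])) < 2:
            out[b] = float("nan")
        else:
            out[b] = roc_auc(scores[:, j], y[:, j]).auc
    return out


def label_matrix(slide_ids, labels: dict[str, BiomarkerLabelVector]
                 ) -> np.ndarray:
    return np.stack([labels[sid].as_array() for sid in slide_ids])


def train_fold(X: np.ndarray, slide_ids: np.ndarray,
               labels: dict[str, BiomarkerLabelVector],
               **net_params) -> TilePatchClassifier:
    """Fit the tile classifier on one fold's tiles (labels inherited per slide)."""
    clf = TilePatchClassifier(**net_params)
    clf.fit(X, label_matrix(slide_ids, labels))
    return clf


def cross_validate(X: np.ndarray, slide_ids, labels, seed: int = 0,
                   folds: dict[str, int] | None = None,
                   **net_params) -> CVReport:
    """Twofold CV with slide-level folds; returns per-biomarker AUCs.

    ``X`` is the (n_tiles, H, W, 3) tile stack, ``slide_ids`` the tile→slide
    map (length n_tiles), ``labels`` the slide-level label vectors.
    """
    slide_ids = np.asarray(slide_ids)
    if folds is None:
        folds = split_slides(sorted(set(slide_ids.tolist())), seed)
    tile_fold = np.array([folds[sid] for sid in slide_ids])
    net_params.setdefault("random_state", seed)

    per_fold: dict[str, list[float]] = {b: [] for b in BIOMARKERS}
    val_probs: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for val_fold in (1, 2):
        train_sel = tile_fold != val_fold
        val_sel = ~train_sel
        clf = train_fold(X[train_sel], slide_ids[train_sel], labels,
                         **net_params)
        probs = clf.predict_proba(X[val_sel])
        val_probs[val_fold] = (probs, slide_ids[val_sel])
        aucs = _slide_level_aucs(probs, slide_ids[val_sel], labels)
        for b in BIOMARKERS:
            per_fold[b].append(aucs[b])

    mean_auc = {b: float(np.nanmean(v)) if np.isfinite(v).any()
                else float("nan") for b, v in per_fold.items()}
    return CVReport(fold_assignments=folds, per_fold_auc=per_fold,
                    mean_auc=mean_auc, val_tile_probs=val_probs)


def grid_search(grid: dict[str, list], X, slide_ids, labels,
                seed: int = 0, **base_params) -> CVReport:
    """Evaluate every point of the 4-D hyperparameter grid by twofold CV.

    ``grid`` must cover exactly filter count, residual-block count, batch
    size and loss function; all other hyperparameters come from
    ``base_params``.  The best configuration maximizes the mean validation
    AUC averaged over biomarkers.
    """
    if set(grid) != set(GRID_DIMENSIONS):
        raise ValueError(
            f"grid must cover exactly the dimensions {GRID_DIMENSIONS}, "
            f"got {tuple(grid)}")
    for dim, vals in grid.items():
        if not vals:
            raise ValueError(f"grid dimension {dim!r} is empty")

    slide_ids = np.asarray(slide_ids)
    folds = split_slides(sorted(set(slide_ids.tolist())), seed)
    rows = []
    best = None
    for point in itertools.product(*(grid[d] for d in GRID_DIMENSIONS)):
        params = dict(zip(GRID_DIMENSIONS, point))
        report = cross_validate(X, slide_ids, labels, seed=seed, folds=folds,
                                **{**base_params, **params})
        score = report.overall_mean_auc
        rows.append({**params, "mean_auc": score,
                     **{f"auc_{b}": report.mean_auc[b] for b in BIOMARKERS}})
        if best is None or (np.isfinite(score)
                            and score > best[0]):
            best = (score if np.isfinite(score) else -np.inf,
                    params, report)
        logger.info("grid point %s -> mean AUC %.3f", params, score)

    _, best_params, best_report = best
    best_report.best_config = {**base_params, **best_params}
    best_report.table = pd.DataFrame(rows)
    return best_report
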