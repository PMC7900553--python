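"""Synthetic H&E-like slides with known ground truth.

The generator emulates the inputs of the pipeline: white-glass background, a
tissue region built from a union of random disks, eosin-pink cytoplasm, and
hematoxylin-dark elliptical nuclei placed by a Poisson count with uniform
positions.  Pixel colors are drawn from a known 3-component Gaussian color
mixture (nucleus / cytoplasm / background), so stain-model recovery can be
scored against the truth.  The label signal is morphological: slides mutated
in the signal biomarker carry a nucleus density scaled by (1 + δ), which
stain normalization cannot erase.  All randomness flows from one master seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.draw import disk as _disk
from skimage.draw import ellipse as _ellipse

from .io import (BIOMARKERS, BiomarkerLabelVector, SlideRecord, write_labels,
                 write_slide)
from .stain import StainGMM

logger = logging.getLogger("histomut")


def default_color_model() -> StainGMM:
    """The true color mixture: dark blue-purple nuclei, pink cytoplasm,
    near-white background (diagonal covariances, colors in [0, 1])."""
    return StainGMM(
        weights=np.array([0.2, 0.5, 0.3]),
        means=np.array([
            [0.30, 0.20, 0.50],    # nucleus (hematoxylin)
            [0.85, 0.55, 0.70],    # cytoplasm (eosin)
            [0.97, 0.96, 0.97],    # background glass
        ]),
        covariances=np.array([
            np.diag([2e-3, 2e-3, 2e-3]),
            np.diag([2e-3, 2e-3, 2e-3]),
            np.diag([4e-4, 4e-4, 4e-4]),
        ]),
    )


NUCLEUS, CYTOPLASM, BACKGROUND = 0, 1, 2


@dataclass
class SynthParams:
    """Study conditions for the synthetic cohort."""

    slide_size: tuple[int, int] = (256, 256)
    class_gmm: StainGMM = field(default_factory=default_color_model)
    nucleus_density: float = 800.0   # expected nuclei per 512x512 tissue area
    nucleus_radius: tuple[float, float] = (2.0, 4.0)
    effect_size: float = 1.0         # δ: density scaled by (1+δ) on label-1
    signal_biomarker: str = "TP53"
    n_slides: int = 20
    tissue_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not (0 < self.tissue_fraction <= 1):
            raise ValueError("tissue_fraction must lie in (0, 1]")
        if self.signal_biomarker not in BIOMARKERS:
            raise ValueError(f"unknown biomarker {self.signal_biomarker!r}")
        self.class_gmm.validate()


def generate_pixel_mixture(model: StainGMM, n: int, seed: int
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Draw n pixels from the mixture; returns (pixels in [0,1], assignments)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    assign = rng.choice(model.n_components, size=n, p=model.weights)
    pixels = np.empty((n, 3))
    for c in range(model.n_components):
        sel = assign == c
        if sel.any():
            pixels[sel] = rng.multivariate_normal(
                model.means[c], model.covariances[c], size=int(sel.sum()))
    return np.clip(pixels, 0.0, 1.0), assign


def _sample_component(model: StainGMM, component: int, n: int,
                      rng: np.random.Generator) -> np.ndarray:
    return np.clip(rng.multivariate_normal(
        model.means[component], model.covariances[component], size=n), 0, 1)


def _tissue_mask(shape: tuple[int, int], fraction: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Union of random disks grown until it covers ≈ the target fraction."""
    h, w = shape
    if fraction >= 0.999:
        return np.ones(shape, dtype=bool)
    mask = np.zeros(shape, dtype=bool)
    r_lo, r_hi = min(h, w) / 8, min(h, w) / 4
    for _ in range(500):
        if mask.mean() >= fraction:
            break
        r = rng.uniform(r_lo, r_hi)
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        rr, cc = _disk((cy, cx), r, shape=shape)
        mask[rr, cc] = True
    return mask


def generate_slide(params: SynthParams, label: BiomarkerLabelVector,
                   seed: int, slide_id: str = "synthetic"
                   ) -> tuple[SlideRecord, dict]:
    """One synthetic slide plus its ground truth.

    Truth dict keys: ``tissue_mask`` (bool raster), ``nucleus_count``,
    ``nucleus_mask`` (bool raster of nucleus pixels), ``density_scale``.
    """
    h, w = params.slide_size
    r_lo, r_hi = params.nucleus_radius
    if r_hi * 2 > min(h, w):
        raise ValueError(
            f"nucleus radius {r_hi} infeasible for slide size {(h, w)}")
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, seed]))

    gmm = params.class_gmm
    image = _sample_component(gmm, BACKGROUND, h * w, rng).reshape(h, w, 3)
    tissue = _tissue_mask((h, w), params.tissue_fraction, rng)
    n_tissue = int(tissue.sum())
    if n_tissue:
        image[tissue] = _sample_component(gmm, CYTOPLASM, n_tissue, rng)

    scale = 1.0 + (params.effect_size
                   if label[params.signal_biomarker] == 1 else 0.0)
    lam = params.nucleus_density * scale * n_tissue / (512.0 * 512.0)
    n_nuclei = int(rng.poisson(lam))
    nucleus_mask = np.zeros((h, w), dtype=bool)
    if n_nuclei and n_tissue:
        rows, cols = np.nonzero(tissue)
        centers = rng.integers(0, n_tissue, size=n_nuclei)
        for idx in centers:
            r = rng.uniform(r_lo, r_hi)
            ratio = rng.uniform(0.6, 1.0)
            theta = rng.uniform(0, np.pi)
            rr, cc = _ellipse(rows[idx], cols[idx], r, r * ratio,
                              shape=(h, w), rotation=theta)
            nucleus_mask[rr, cc] = True
        n_nuc_px = int(nucleus_mask.sum())
        image[nucleus_mask] = _sample_component(gmm, NUCLEUS, n_nuc_px, rng)

    record = SlideRecord(
        slide_id=slide_id,
        image=np.round(image * 255.0).astype(np.uint8),
        tumor_mask=tissue.astype(np.uint8),
        labels=label,
    )
    truth = {"tissue_mask": tissue, "nucleus_count": n_nuclei,
             "nucleus_mask": nucleus_mask, "density_scale": scale,
             "expected_nuclei": lam}
    return record, truth


def generate_dataset(params: SynthParams, out_dir: str | Path | None = None
                     ) -> tuple[list[SlideRecord], dict[str, BiomarkerLabelVector],
                                list[dict]]:
    """A balanced synthetic cohort: slides, label table, truth manifest.

    The signal biomarker gets exactly half label-1 slides; the other seven
    biomarkers get independent fair-coin labels with no morphological effect.
    With ``out_dir`` set, slides/masks (PNG), labels (CSV) and the truth
    manifest (JSON) are written through the package's I/O formats.
    """
    if params.n_slides < 4:
        raise ValueError("need at least 4 slides")
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0xDA7A]))
    sig = BIOMARKERS.index(params.signal_biomarker)

    n1 = params.n_slides // 2
    signal_labels = np.zeros(params.n_slides, dtype=int)
    signal_labels[:n1] = 1
    signal_labels = signal_labels[rng.permutation(params.n_slides)]

    slides, labels, truths = [], {}, []
    for i in range(params.n_slides):
        vals = rng.integers(0, 2, size=len(BIOMARKERS))
        vals[sig] = signal_labels[i]
        vec = BiomarkerLabelVector(tuple(int(v) for v in vals))
        sid = f"S{i:03d}"
        record, truth = generate_slide(params, vec, seed=i + 1, slide_id=sid)
        slides.append(record)
        labels[sid] = vec
        truths.append({"slide_id": sid,
                       "nucleus_count": truth["nucleus_count"],
                       "density_scale": truth["density_scale"],
                       "tissue_fraction": float(truth["tissue_mask"].mean())})

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for rec in slides:
            write_slide(rec, out / f"{rec.slide_id}.png",
                        out / f"{rec.slide_id}_mask.png")
        write_labels(labels, out / "labels.csv")
        (out / "truth.json").write_text(json.dumps(truths, indent=2))
    return slides, labels, truths
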