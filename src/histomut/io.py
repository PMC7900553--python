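"""Reading and writing slides, masks, label tables, metrics and configs.

All rasters are row-major with the origin at the top-left pixel and 0-based
indices.  Tumor masks are stored on disk as single-channel 8-bit images with
values in {0, 255} and are mapped to {0, 1} in memory.  Label tables are CSV
with a header naming the eight biomarker genes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from skimage.draw import polygon as _polygon_fill

logger = logging.getLogger("histomut")

#: Canonical biomarker order used everywhere in the package.  Label files may
#: list the columns in any order; they are canonicalized on read.
BIOMARKERS: tuple[str, ...] = (
    "TP53", "EGFR", "STK11", "POLE", "POLD1", "PBRM1", "DNMT3A", "KRAS",
)
N_BIOMARKERS = len(BIOMARKERS)


class DimensionMismatchError(ValueError):
    """Image and mask shapes disagree."""


class LabelParseError(ValueError):
    """A label table violates the binary-cell / column contract."""


@dataclass(frozen=True)
class BiomarkerLabelVector:
    """Binary mutation status for the eight biomarker genes of one slide.

    ``values`` follows :data:`BIOMARKERS` order; 1 = mutated, 0 = wild-type.
    """

    values: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.values) != N_BIOMARKERS:
            raise ValueError(
                f"expected {N_BIOMARKERS} biomarker values, got {len(self.values)}"
            )
        if any(v not in (0, 1) for v in self.values):
            raise ValueError(f"labels must be binary, got {self.values}")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, int]) -> "BiomarkerLabelVector":
        missing = [b for b in BIOMARKERS if b not in mapping]
        if missing:
            raise LabelParseError(f"missing biomarker columns: {missing}")
        return cls(tuple(int(mapping[b]) for b in BIOMARKERS))

    def as_dict(self) -> dict[str, int]:
        return dict(zip(BIOMARKERS, self.values))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=np.int8)

    def __getitem__(self, biomarker: str) -> int:
        return self.values[BIOMARKERS.index(biomarker)]


@dataclass
class SlideRecord:
    """One slide: RGB image, binary tumor mask, and (optionally) its labels."""

    slide_id: str
    image: np.ndarray            # (H, W, 3) uint8
    tumor_mask: np.ndarray       # (H, W) uint8 in {0, 1}
    labels: BiomarkerLabelVector | None = None

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        self.tumor_mask = np.asarray(self.tumor_mask)
        if not self.slide_id:
            raise ValueError("slide_id must be nonempty")
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError(f"image must be (H, W, 3), got {self.image.shape}")
        if self.tumor_mask.shape != self.image.shape[:2]:
            raise DimensionMismatchError(
                f"image shape {self.image.shape[:2]} != mask shape "
                f"{self.tumor_mask.shape}"
            )
        bad = set(np.unique(self.tumor_mask)) - {0, 1}
        if bad:
            raise ValueError(f"tumor_mask must be binary, found values {sorted(bad)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape[:2]


def rasterize_polygon(
    vertices: Sequence[tuple[float, float]], shape: tuple[int, int]
) -> np.ndarray:
    """Fill a polygon given as (row, col) vertices into a binary mask."""
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
        raise ValueError("polygon needs >= 3 (row, col) vertices")
    mask = np.zeros(shape, dtype=np.uint8)
    rr, cc = _polygon_fill(verts[:, 0], verts[:, 1], shape=shape)
    mask[rr, cc] = 1
    return mask


def read_slide(
    image_path: str | Path,
    mask_path: str | Path | None = None,
    polygon: Sequence[tuple[float, float]] | None = None,
    slide_id: str | None = None,
    labels: BiomarkerLabelVector | None = None,
) -> SlideRecord:
    """Load an RGB slide plus its tumor mask (raster file or polygon).

    Exactly one of ``mask_path`` / ``polygon`` must be given.  A raster mask
    must match the image dimensions; values > 127 map to 1.
    """
    image_path = Path(image_path)
    image = iio.imread(image_path)
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    if image.shape[-1] == 4:
        image = image[..., :3]
    image = image.astype(np.uint8, copy=False)

    if (mask_path is None) == (polygon is None):
        raise ValueError("provide exactly one of mask_path or polygon")
    if mask_path is not None:
        raw = iio.imread(Path(mask_path))
        if raw.ndim == 3:
            raw = raw[..., 0]
        if raw.shape != image.shape[:2]:
            raise DimensionMismatchError(
                f"image shape {image.shape[:2]} != mask shape {raw.shape}"
            )
        mask = (raw > 127).astype(np.uint8)
    else:
        mask = rasterize_polygon(polygon, image.shape[:2])

    sid = slide_id if slide_id is not None else image_path.stem
    return SlideRecord(slide_id=sid, image=image, tumor_mask=mask, labels=labels)


def write_slide(record: SlideRecord, image_path: str | Path,
                mask_path: str | Path | None = None) -> None:
    iio.imwrite(Path(image_path), record.image)
    if mask_path is not None:
        iio.imwrite(Path(mask_path), (record.tumor_mask * 255).astype(np.uint8))


def read_labels(table_path: str | Path) -> dict[str, BiomarkerLabelVector]:
    """Parse a CSV label table into one vector per slide.

    The header must contain a slide-id column plus all eight biomarkers; extra
    columns are ignored with a warning, non-binary cells and duplicate slide
    ids are errors.
    """
    df = pd.read_csv(table_path, dtype=str)
    id_col = df.columns[0]
    missing = [b for b in BIOMARKERS if b not in df.columns]
    if missing:
        raise LabelParseError(f"label table missing biomarker columns: {missing}")
    extra = [c for c in df.columns[1:] if c not in BIOMARKERS]
    if extra:
        logger.warning("ignoring extra label columns: %s", extra)
    if df[id_col].duplicated().any():
        dups = df[id_col][df[id_col].duplicated()].tolist()
        raise LabelParseError(f"duplicate slide ids: {dups}")

    out: dict[str, BiomarkerLabelVector] = {}
    for row_idx, row in df.iterrows():
        vals = {}
        for b in BIOMARKERS:
            cell = str(row[b]).strip()
            if cell not in ("0", "1"):
                raise LabelParseError(
                    f"non-binary label {cell!r} at row {row_idx}, column {b}"
                )
            vals[b] = int(cell)
        out[str(row[id_col])] = BiomarkerLabelVector.from_mapping(vals)
    return out


def write_labels(labels: Mapping[str, BiomarkerLabelVector],
                 table_path: str | Path) -> None:
    rows = [{"slide_id": sid, **vec.as_dict()} for sid, vec in labels.items()]
    pd.DataFrame(rows, columns=["slide_id", *BIOMARKERS]).to_csv(
        table_path, index=False
    )


def write_metrics(results: Mapping[str, object], out_path: str | Path) -> None:
    """Serialize an evaluation bundle (per-biomarker AUC + ROC points) to JSON."""

    def _clean(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, Mapping):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        return obj

    Path(out_path).write_text(json.dumps(_clean(dict(results)), indent=2))


def read_metrics(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


# --- configuration ---------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "tile": {"size": 512, "bg_max": 0.75, "tumor_min": 0.5,
             "bg_saturation_max": 0.15, "bg_value_min": 0.82,
             "blur_threshold": None, "blur_block": 64,
             "slide_noise_max": 0.75},
    "gmm": {"n_components": 3, "tol": 1.0e-6, "max_iter": 200,
            "covariance_floor": 1.0e-6, "n_init": 3, "color_space": "rgb",
            "covariance_type": "full"},
    "net": {"input_size": 64, "n_filters": 8, "kernel_size": 3,
            "n_residual_blocks": 2, "batch_size": 16, "loss": "bce",
            "learning_rate": 0.05, "l2": 1.0e-4, "epochs": 10},
    "seed": 0,
}


def load_config(path: str | Path | None) -> dict:
    """YAML config merged over defaults (two-level shallow merge)."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def config_hash(cfg: Mapping) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def log_run(command: str, cfg: Mapping, seed: int,
            inputs: Iterable[str | Path] = ()) -> None:
    logger.info("%s: seed=%d config=%s inputs=%s",
                command, seed, config_hash(cfg), [str(p) for p in inputs])
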