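"""Standardization of raw drawings into the model's fused RGB input.

Pipeline: denoise -> segment ink -> crop to content -> geometry normalization
(isotropic rescale + principal-axis rotation) -> fusion of complementary
views into a single ``size x size x 3`` tensor with values in [0, 1].

Conventions used throughout: row-major arrays, origin at the top-left,
0-based indices, half-open bounding boxes, bilinear resampling for resizing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage as ndi
from skimage.filters import gaussian, sobel, threshold_otsu
from skimage.transform import resize, rotate

from .drawgen import TASKS, DrawingImage

__all__ = [
    "NoInkError",
    "BBox",
    "FusedInput",
    "denoise",
    "segment_ink",
    "crop_to_content",
    "normalize_geometry",
    "fuse_to_rgb",
    "preprocess_drawing",
    "load_drawing",
    "build_fused_dataset",
    "preprocess_manifest",
]

#: Connected components smaller than this many pixels are treated as specks.
MIN_COMPONENT_PX = 5
#: Principal-axis rotation only engages above this second-moment eigenvalue
#: ratio; near-isotropic content (spirals) has no meaningful axis.
ANISOTROPY_RATIO = 1.2
#: Fraction of the canvas that the content's longer side is scaled to fill.
FILL_FRACTION = 0.9


class NoInkError(ValueError):
    """Raised when an image contains no segmentable ink."""


@dataclass(frozen=True)
class BBox:
    """Half-open pixel bounds [row_start, row_end) x [col_start, col_end)."""

    row_start: int
    row_end: int
    col_start: int
    col_end: int

    def __post_init__(self) -> None:
        if not (self.row_start < self.row_end and self.col_start < self.col_end):
            raise ValueError("bounding box must be non-empty")


@dataclass
class FusedInput:
    """The standardized network input: (size, size, 3) intensities in [0, 1]."""

    pixels: np.ndarray
    channel_names: tuple

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("fused input must be H x W x 3")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("fused input must be finite")


def _as_array(image) -> np.ndarray:
    if isinstance(image, DrawingImage):
        return image.pixels
    return np.asarray(image, dtype=float)


def denoise(image) -> np.ndarray:
    """Remove impulse noise: 3x3 median filter, then deletion of connected ink
    components smaller than ``MIN_COMPONENT_PX`` pixels. Intensities stay in
    the input's [0, 1] range."""
    arr = _as_array(image)
    if arr.size == 0:
        raise ValueError("image must be non-empty")
    out = ndi.median_filter(arr, size=3)
    mask = out > 0
    if mask.any():
        lab, n = ndi.label(mask, structure=np.ones((3, 3)))
        sizes = np.bincount(lab.ravel())
        keep = np.isin(lab, np.flatnonzero(sizes >= MIN_COMPONENT_PX)) & mask
        out = np.where(keep, out, 0.0)
    return np.clip(out, 0.0, 1.0)


def segment_ink(image) -> np.ndarray:
    """Binary ink mask by Otsu's between-class-variance-maximizing threshold."""
    arr = _as_array(image)
    if arr.max() == arr.min():
        raise NoInkError("constant image has no segmentable ink")
    thresh = threshold_otsu(arr, nbins=256)
    mask = (arr > thresh).astype(np.uint8)
    if not mask.any():
        raise NoInkError("thresholding produced an empty ink mask")
    return mask


def crop_to_content(mask: np.ndarray, margin: int = 0) -> BBox:
    """Tightest half-open box containing all ink, expanded by ``margin`` and
    clipped to the image bounds."""
    mask = np.asarray(mask)
    if margin < 0:
        raise ValueError("margin must be >= 0")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise NoInkError("cannot crop an empty mask")
    return BBox(
        row_start=max(int(rows[0]) - margin, 0),
        row_end=min(int(rows[-1]) + 1 + margin, mask.shape[0]),
        col_start=max(int(cols[0]) - margin, 0),
        col_end=min(int(cols[-1]) + 1 + margin, mask.shape[1]),
    )


def _ink_moments(arr: np.ndarray):
    """Centroid and second-moment (covariance) matrix of the ink intensity."""
    total = arr.sum()
    r = np.arange(arr.shape[0])[:, None]
    c = np.arange(arr.shape[1])[None, :]
    rbar = float((arr * r).sum() / total)
    cbar = float((arr * c).sum() / total)
    mu_rr = float((arr * (r - rbar) ** 2).sum() / total)
    mu_cc = float((arr * (c - cbar) ** 2).sum() / total)
    mu_rc = float((arr * (r - rbar) * (c - cbar)).sum() / total)
    return (rbar, cbar), np.array([[mu_rr, mu_rc], [mu_rc, mu_cc]])


def principal_axis_angle(arr: np.ndarray) -> float:
    """Angle (degrees) of the ink's principal axis relative to the horizontal."""
    _, cov = _ink_moments(arr)
    mu_rr, mu_cc, mu_rc = cov[0, 0], cov[1, 1], cov[0, 1]
    return math.degrees(0.5 * math.atan2(2.0 * mu_rc, mu_cc - mu_rr))


def normalize_geometry(image, fill_fraction: float = FILL_FRACTION,
                       anisotropy_ratio: float = ANISOTROPY_RATIO) -> np.ndarray:
    """Scale/rotation normalization on a fixed canvas.

    If the ink's second-moment eigenvalue ratio exceeds ``anisotropy_ratio``,
    the drawing is rotated so its principal axis is horizontal. The content is
    then isotropically scaled so its longer side fills ``fill_fraction`` of
    the canvas and centred. Near-isotropic content skips the rotation;
    degenerate (single-pixel) content skips the scaling and is only centred.
    Output dimensions equal the input's.
    """
    arr = _as_array(image)
    h, w = arr.shape
    if not (arr > 0).any():
        raise NoInkError("cannot normalize an image with no ink")

    _, cov = _ink_moments(arr)
    evals = np.linalg.eigvalsh(cov)
    if evals[0] > 1e-9 and evals[1] / max(evals[0], 1e-12) > anisotropy_ratio:
        angle = principal_axis_angle(arr)
        arr = rotate(arr, angle, resize=True, order=1, preserve_range=True)
        arr = np.clip(arr, 0.0, 1.0)

    box = crop_to_content(arr > 1e-3, margin=0)
    content = arr[box.row_start:box.row_end, box.col_start:box.col_end]
    ch, cw = content.shape

    out = np.zeros((h, w), dtype=float)
    if ch > 1 or cw > 1:
        scale = fill_fraction * min(h, w) / max(ch, cw)
        nh = max(int(round(ch * scale)), 1)
        nw = max(int(round(cw * scale)), 1)
        content = resize(content, (nh, nw), order=1, preserve_range=True,
                         anti_aliasing=(scale < 1.0))
        ch, cw = content.shape
    r0 = (h - ch) // 2
    c0 = (w - cw) // 2
    out[r0:r0 + ch, c0:c0 + cw] = np.clip(content, 0.0, 1.0)
    return out


def _resize_square(arr: np.ndarray, size: int) -> np.ndarray:
    if arr.shape == (size, size):
        return arr.astype(float)
    return np.clip(resize(arr, (size, size), order=1, preserve_range=True,
                          anti_aliasing=arr.shape[0] > size), 0.0, 1.0)


def fuse_to_rgb(task_images: dict, mode: str = "multitask",
                size: int = 256) -> FusedInput:
    """Fuse complementary drawing views into the (size, size, 3) input.

    ``multitask``: channels are the subject's (spiral, meander, wave)
    drawings in that fixed order. ``single_filtered``: channels are (raw,
    edge-enhanced, Gaussian-smoothed) variants of one drawing (the first
    present in task order).
    """
    if not task_images:
        raise ValueError("task_images must not be empty")
    imgs = {k: _as_array(v) for k, v in task_images.items()}

    if mode == "multitask":
        missing = [t for t in TASKS if t not in imgs]
        if missing:
            raise KeyError(f"multitask fusion requires all tasks; missing {missing}")
        chans = [_resize_square(imgs[t], size) for t in TASKS]
        names = TASKS
    elif mode == "single_filtered":
        task = next(t for t in TASKS if t in imgs) if any(
            t in imgs for t in TASKS) else next(iter(imgs))
        raw = _resize_square(imgs[task], size)
        edges = sobel(raw)
        if edges.max() > 0:
            edges = edges / edges.max()
        smooth = np.clip(gaussian(raw, sigma=1.0), 0.0, 1.0)
        chans = [raw, edges, smooth]
        names = (f"{task}:raw", f"{task}:edges", f"{task}:smoothed")
    else:
        raise ValueError(f"unknown fusion mode {mode!r}")

    return FusedInput(pixels=np.stack(chans, axis=2), channel_names=tuple(names))


def preprocess_drawing(image, margin: int = 4) -> np.ndarray:
    """Full single-image chain: denoise, segment, crop (with margin), normalize.

    Returns a cleaned greyscale array on the original canvas size.
    """
    arr = denoise(image)
    mask = segment_ink(arr)
    box = crop_to_content(mask, margin=margin)
    h, w = arr.shape
    canvas = np.zeros((h, w), dtype=float)
    content = np.where(mask, arr, 0.0)[box.row_start:box.row_end,
                                       box.col_start:box.col_end]
    r0 = (h - content.shape[0]) // 2
    c0 = (w - content.shape[1]) // 2
    canvas[r0:r0 + content.shape[0], c0:c0 + content.shape[1]] = content
    return normalize_geometry(canvas)


def load_drawing(path) -> np.ndarray:
    """Read a PNG (8-bit grey or RGB; RGB converted to luminance) to [0, 1]."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=float) / 255.0
    return arr


def build_fused_dataset(manifest, mode: str = "multitask", size: int = 256):
    """Preprocess and fuse a cohort manifest fully in memory.

    Returns ``(X, y, subject_ids)`` with X of shape (n_subjects, size, size, 3).
    Manifests carry either in-memory images (column ``image``) or PNG paths.
    """
    records = manifest.records if hasattr(manifest, "records") else manifest
    xs, ys, sids = [], [], []
    for sid, group in records.groupby("subject_id", sort=True):
        imgs = {}
        for _, row in group.iterrows():
            raw = row["image"].pixels if "image" in group.columns and \
                isinstance(row.get("image"), DrawingImage) else load_drawing(row["path"])
            imgs[row["task"]] = preprocess_drawing(raw)
        fused = fuse_to_rgb(imgs, mode=mode, size=size)
        xs.append(fused.pixels)
        ys.append(int(group["label"].iloc[0]))
        sids.append(sid)
    return np.stack(xs), np.asarray(ys, dtype=int), list(sids)


def preprocess_manifest(manifest, mode: str = "multitask", size: int = 256,
                        out_dir=None) -> pd.DataFrame:
    """Preprocess a cohort and write fused inputs as RGB PNGs.

    Returns one row per subject with columns
    ``subject_id, label, fused_path``.
    """
    from pathlib import Path

    X, y, sids = build_fused_dataset(manifest, mode=mode, size=size)
    rows = []
    root = Path(out_dir) if out_dir is not None else None
    if root is not None:
        root.mkdir(parents=True, exist_ok=True)
    for i, sid in enumerate(sids):
        fused_path = ""
        if root is not None:
            fused_path = str(root / f"{sid}_fused.png")
            Image.fromarray((X[i] * 255).astype(np.uint8)).save(fused_path)
        rows.append({"subject_id": sid, "label": int(y[i]),
                     "fused_path": fused_path})
    df = pd.DataFrame(rows)
    if root is not None:
        df.to_csv(root / "fused_manifest.csv", index=False)
    return df
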