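"""Superpixel Shapley attribution of the PD posterior.

The drawing is partitioned into SLIC superpixels (k-means in (x, y,
intensity) with connectivity enforcement); each segment is a player in a
cooperative game whose value is the model's PD posterior with the segment's
complement replaced by a baseline (blank paper by default). Shapley values
are computed exactly by coalition enumeration for small segment counts and
by the Kernel-SHAP weighted regression otherwise.

Positive attributions mark regions pushing the prediction toward PD; the
rendering uses a symmetric diverging colour scale centred at zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, factorial

import numpy as np
from matplotlib import colormaps
from skimage.segmentation import slic

__all__ = [
    "SegmentMap",
    "AttributionMap",
    "superpixels",
    "shapley_attribution",
    "render_map",
]


@dataclass
class SegmentMap:
    """H x W grid of contiguous segment ids 0..n_segments-1."""

    labels: np.ndarray
    n_segments: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        ids = np.unique(self.labels)
        if not np.array_equal(ids, np.arange(self.n_segments)):
            raise ValueError("segment ids must be exactly 0..S-1")


@dataclass
class AttributionMap:
    """Per-segment Shapley values of the PD posterior."""

    phi: np.ndarray
    segments: SegmentMap
    f_image: float
    f_baseline: float
    mode: str
    seed: int | None = None


def superpixels(image: np.ndarray, n_segments: int, seed: int = 0,
                compactness: float = 10.0) -> SegmentMap:
    """SLIC superpixel partition with connectivity enforcement.

    The realized segment count may differ slightly from the request and is
    reported on the returned map. Ids are relabelled to be contiguous.
    """
    img = np.asarray(image, dtype=float)
    img = img.pixels if hasattr(img, "pixels") else img
    n_pixels = img.shape[0] * img.shape[1]
    if n_segments < 1 or n_segments > n_pixels:
        raise ValueError("n_segments must lie in [1, pixel count]")
    if n_segments == 1:
        return SegmentMap(np.zeros(img.shape[:2], dtype=int), 1)
    channel_axis = 2 if img.ndim == 3 else None
    labels = slic(img, n_segments=n_segments, compactness=compactness,
                  start_label=0, enforce_connectivity=True,
                  channel_axis=channel_axis)
    ids, labels = np.unique(labels, return_inverse=True)
    labels = labels.reshape(img.shape[:2])
    return SegmentMap(labels, len(ids))


def _masked_images(image, segments, coalitions, baseline):
    """Stack of images: for each coalition (boolean segment mask), segments
    outside the coalition are replaced by the baseline."""
    out = []
    for keep in coalitions:
        pix_keep = keep[segments.labels]
        if image.ndim == 3:
            pix_keep = pix_keep[..., None]
        out.append(np.where(pix_keep, image, baseline))
    return out


def _resolve_baseline(image, policy):
    if isinstance(policy, np.ndarray):
        return policy
    if policy == "zero":
        return np.zeros_like(image)
    if policy == "mean":
        return np.full_like(image, image.mean())
    raise ValueError(f"unknown baseline policy {policy!r}")


def _exact_shapley(values_by_mask: dict, s: int) -> np.ndarray:
    """Shapley formula by enumeration: values_by_mask maps coalition bitmask
    to the game value."""
    phi = np.zeros(s)
    weights = {t: factorial(t) * factorial(s - t - 1) / factorial(s)
               for t in range(s)}
    for i in range(s):
        others = [j for j in range(s) if j != i]
        for t in range(s):
            for subset in combinations(others, t):
                mask = sum(1 << j for j in subset)
                phi[i] += weights[t] * (values_by_mask[mask | (1 << i)]
                                        - values_by_mask[mask])
    return phi


def _kernel_weight(s: int, size: int) -> float:
    # SHAP kernel; infinite at the empty/full coalitions (handled separately)
    return (s - 1) / (comb(s, size) * size * (s - size))


def shapley_attribution(model_fn, image: np.ndarray, segments: SegmentMap,
                        baseline="zero", mode: str = "exact",
                        n_samples: int = 2000, seed: int = 0) -> AttributionMap:
    """Per-segment Shapley values of ``model_fn`` (image -> PD posterior).

    ``exact`` mode enumerates all 2^S coalitions (S <= 14 enforced) and
    satisfies the efficiency axiom: sum(phi) = f(image) - f(baseline).
    ``sampled`` mode estimates the same values by the Kernel-SHAP weighted
    least-squares regression over ``n_samples`` seeded coalitions, always
    including the empty and full coalitions (given effectively infinite
    kernel weight, which pins the regression to the efficiency constraint).
    """
    image = np.asarray(image, dtype=float)
    s = segments.n_segments
    base = _resolve_baseline(image, baseline)
    f_full = float(model_fn(image))
    f_base = float(model_fn(base.copy()))

    if mode == "exact":
        if s > 14:
            raise ValueError("exact mode supports at most 14 segments")
        masks = np.arange(2 ** s)
        coalitions = ((masks[:, None] >> np.arange(s)) & 1).astype(bool)
        values = {}
        for m, keep in zip(masks, coalitions):
            if m == 0:
                values[m] = f_base
            elif m == 2 ** s - 1:
                values[m] = f_full
            else:
                values[m] = float(model_fn(_masked_images(
                    image, segments, [keep], base)[0]))
        phi = _exact_shapley(values, s)
        return AttributionMap(phi, segments, f_full, f_base, "exact", seed)

    if mode != "sampled":
        raise ValueError(f"unknown mode {mode!r}")

    rng = np.random.default_rng(seed)
    if s == 1:
        return AttributionMap(np.array([f_full - f_base]), segments,
                              f_full, f_base, "sampled", seed)
    zs, ws, vs = [], [], []
    big = 1e7
    zs.append(np.zeros(s, bool)); ws.append(big); vs.append(f_base)
    zs.append(np.ones(s, bool)); ws.append(big); vs.append(f_full)
    sizes = np.arange(1, s)
    size_w = np.array([_kernel_weight(s, t) for t in sizes])
    size_p = size_w / size_w.sum()
    for _ in range(max(n_samples - 2, 0)):
        t = int(rng.choice(sizes, p=size_p))
        keep = np.zeros(s, bool)
        keep[rng.choice(s, size=t, replace=False)] = True
        zs.append(keep)
        ws.append(1.0)
        vs.append(float(model_fn(_masked_images(image, segments, [keep], base)[0])))
    Z = np.column_stack([np.ones(len(zs)), np.array(zs, dtype=float)])
    W = np.asarray(ws)
    v = np.asarray(vs)
    A = Z.T * W
    coef, *_ = np.linalg.lstsq(A @ Z, A @ v, rcond=None)
    phi = coef[1:]
    return AttributionMap(phi, segments, f_full, f_base, "sampled", seed)


def render_map(image: np.ndarray, attributions: AttributionMap,
               segments: SegmentMap | None = None, blend: float = 0.0,
               cmap_name: str = "coolwarm") -> np.ndarray:
    """RGB overlay of the attribution map.

    Segment colours come from a symmetric diverging colormap centred at 0
    with extremes at +/- max|phi| (all-zero attributions give a uniformly
    neutral mid-scale image). ``blend`` > 0 mixes in the greyscale drawing.
    """
    segments = segments or attributions.segments
    image = np.asarray(image, dtype=float)
    if image.shape[:2] != segments.labels.shape:
        raise ValueError("image and segment map shapes differ")
    phi = attributions.phi
    vmax = float(np.max(np.abs(phi))) if np.any(phi) else 1.0
    norm = 0.5 + phi[segments.labels] / (2.0 * vmax)
    colors = colormaps[cmap_name](norm)[..., :3]
    if blend > 0:
        grey = image if image.ndim == 2 else image.mean(axis=2)
        colors = (1 - blend) * colors + blend * grey[..., None]
    return colors
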