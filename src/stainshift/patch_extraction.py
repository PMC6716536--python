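"""Heatmap-guided patch extraction from unannotated slide rasters.

A fixed color heuristic turns an RGB slide (nominally at 10X; the
computation itself is resolution-agnostic) into a tissue-likelihood
heatmap in [0, 1]:

    h1 = tanh(2(B - R)/(G + 1) + 0.5) + 0.5
    h2 = tanh((640 - R - G - B)/300 + 0.5) + 0.5
    h  = 0.5 * tanh(h1 * h2 - 1.75) + 0.5

with channels on their raw 0–255 scale.  ``h1`` responds to the
blue-over-red cast of hematoxylin, ``h2`` to overall darkness; white glass
scores ~0.08, saturated black ~0.35, purple tissue >0.65.  Thresholding
``h`` (default 0.65) gives the eligible locations from which patch windows
are sampled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ExtractionConfig",
    "compute_heatmap",
    "sample_locations",
    "extract_patches",
]


@dataclass(frozen=True)
class ExtractionConfig:
    """Patch sampling parameters; ``threshold`` is the heatmap cut-off,
    windows are ``patch_size`` squares whose top-left corner is the
    returned (x, y)."""

    threshold: float = 0.65
    patch_size: int = 64
    n_patches: int = 100
    # "center": threshold the window's center pixel; "mean": its window mean
    mode: str = "center"
    magnification_note: str = "10X"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if self.n_patches < 1 or self.patch_size < 1:
            raise ValueError("n_patches and patch_size must be >= 1")
        if self.mode not in ("center", "mean"):
            raise ValueError("mode must be 'center' or 'mean'")


def compute_heatmap(img: np.ndarray) -> np.ndarray:
    """Tissue-likelihood heatmap in [0, 1] from raw 0–255 RGB channels."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected HxWx3 image, got {img.shape}")
    r = img[..., 0].astype(float)
    g = img[..., 1].astype(float)
    b = img[..., 2].astype(float)
    h1 = np.tanh(2.0 * (b - r) / (g + 1.0) + 0.5) + 0.5
    h2 = np.tanh((640.0 - r - g - b) / 300.0 + 0.5) + 0.5
    return 0.5 * np.tanh(h1 * h2 - 1.75) + 0.5


def sample_locations(
    heatmap: np.ndarray,
    config: ExtractionConfig,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Sample top-left (x, y) window origins whose heatmap score exceeds
    the threshold and whose window lies fully inside the image.

    Sampling is uniform without replacement over eligible origins; if
    fewer are eligible than requested, all eligible origins are returned
    once, topped up with replacement under a warning.  Zero eligible
    origins returns an empty list with a warning.
    """
    hm = np.asarray(heatmap, dtype=float)
    size = config.patch_size
    h, w = hm.shape
    if h < size or w < size:
        warnings.warn("image smaller than the patch window; nothing to sample")
        return []
    if config.mode == "center":
        score = hm[size // 2 : size // 2 + h - size + 1,
                   size // 2 : size // 2 + w - size + 1]
    else:
        c = np.cumsum(np.cumsum(hm, axis=0), axis=1)
        c = np.pad(c, ((1, 0), (1, 0)))
        score = (
            c[size:, size:] - c[:-size, size:] - c[size:, :-size] + c[:-size, :-size]
        ) / (size * size)
    ys, xs = np.nonzero(score > config.threshold)
    n_eligible = len(xs)
    if n_eligible == 0:
        warnings.warn("no heatmap locations above threshold; returning empty list")
        return []
    if n_eligible >= config.n_patches:
        pick = rng.choice(n_eligible, size=config.n_patches, replace=False)
    else:
        warnings.warn(
            f"only {n_eligible} eligible locations for {config.n_patches} "
            "requested patches; sampling with replacement"
        )
        extra = rng.choice(n_eligible, size=config.n_patches - n_eligible, replace=True)
        pick = np.concatenate([np.arange(n_eligible), extra])
    return [(int(xs[i]), int(ys[i])) for i in pick]


def extract_patches(
    img: np.ndarray,
    locations: list[tuple[int, int]],
    patch_size: int,
) -> list[np.ndarray]:
    """Crop half-open windows [x, x+size) x [y, y+size), 0-based top-left
    origins, returned in input order."""
    img = np.asarray(img)
    h, w = img.shape[:2]
    out = []
    for x, y in locations:
        if x < 0 or y < 0 or x + patch_size > w or y + patch_size > h:
            raise ValueError(
                f"window at (x={x}, y={y}) size {patch_size} exceeds "
                f"image bounds {w}x{h}"
            )
        out.append(img[y : y + patch_size, x : x + patch_size].copy())
    return out
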