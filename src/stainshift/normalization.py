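"""Macenko stain-matrix estimation and template-based stain normalization.

The normalization pipeline mirrors the classic color-deconvolution recipe:

1. brightness-standardize the image in CIELAB (rescale L so its 95th
   percentile reaches maximum lightness — at least 5% of pixels end up
   white);
2. estimate the image's own 2x3 stain matrix with the Macenko procedure
   (SVD plane of the tissue optical-density cloud, percentile clipping of
   extreme angles);
3. deconvolve per-pixel H/E concentrations by least squares in OD space;
4. rescale concentrations to a template's robust concentration range and
   re-render the image through the template's stain matrix.

Estimation is sensitive to the template choice, so the template is always
an explicit input, persisted as JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import color as skcolor

from .stain_model import (
    DEFAULT_BACKGROUND,
    StainMatrix,
    render,
    rgb_to_od,
)

__all__ = [
    "NormalizationConfig",
    "NormalizationTemplate",
    "StainEstimationError",
    "standardize_brightness",
    "estimate_stain_matrix",
    "estimate_concentrations",
    "fit_template",
    "normalize",
]


class StainEstimationError(RuntimeError):
    """Raised when an image has too little tissue (or degenerate color
    structure) for stain-matrix estimation."""


@dataclass(frozen=True)
class NormalizationConfig:
    """Estimation knobs.

    od_threshold: optical density below which a pixel counts as background;
        a pixel is kept when any channel exceeds it (an eosin-only pixel has
        legitimately near-zero red absorbance and must not be discarded).
    angle_percentile: percentile used to clip extreme angles in the SVD
        plane; the stain vectors are read at the p-th and (100-p)-th
        percentile angles.
    min_tissue_pixels: minimum retained pixel count before estimation.
    concentration_percentile: robust per-stain concentration scale used for
        template matching.
    """

    od_threshold: float = 0.15
    angle_percentile: float = 1.0
    min_tissue_pixels: int = 100
    concentration_percentile: float = 99.0
    background: float = DEFAULT_BACKGROUND


@dataclass(frozen=True)
class NormalizationTemplate:
    """Color frame every image is mapped into: the template's stain matrix
    and its robust per-stain concentration scale."""

    stain: StainMatrix
    max_conc: np.ndarray
    background: float = DEFAULT_BACKGROUND

    def __post_init__(self) -> None:
        mc = np.asarray(self.max_conc, dtype=float)
        if mc.shape != (2,) or np.any(mc <= 0):
            raise ValueError("max_conc must be a positive 2-vector")
        object.__setattr__(self, "max_conc", mc)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "stain_rows": self.stain.rows.tolist(),
            "max_conc": self.max_conc.tolist(),
            "background": self.background,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationTemplate":
        payload = json.loads(Path(path).read_text())
        return cls(
            stain=StainMatrix(np.array(payload["stain_rows"])),
            max_conc=np.array(payload["max_conc"]),
            background=float(payload["background"]),
        )


def standardize_brightness(img: np.ndarray) -> np.ndarray:
    """Rescale the CIELAB L channel so its 95th percentile reaches maximum
    lightness; afterwards at least 5% of pixels are (near-)white."""
    img = np.asarray(img, dtype=np.uint8)
    lab = skcolor.rgb2lab(img / 255.0)
    p95 = np.percentile(lab[..., 0], 95)
    if p95 > 0:
        lab[..., 0] = np.clip(lab[..., 0] * (100.0 / p95), 0.0, 100.0)
    out = skcolor.lab2rgb(lab)
    return np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)


def _tissue_od(img: np.ndarray, config: NormalizationConfig) -> np.ndarray:
    od = rgb_to_od(img, background=config.background).reshape(-1, 3)
    keep = np.any(od > config.od_threshold, axis=1)
    return od[keep]


def estimate_stain_matrix(
    img: np.ndarray, config: NormalizationConfig = NormalizationConfig()
) -> StainMatrix:
    """Macenko estimation of the 2x3 stain matrix.

    Background pixels are discarded in OD space; the remaining cloud is
    reduced to its two principal directions (SVD of the mean-centered
    pixels); pixels are projected into that plane and the stain vectors are
    read off at the extreme (percentile-clipped) angles of the projected
    cloud.  Rows are unit-normalized; the row with the larger red-channel
    absorbance is labeled hematoxylin (hematoxylin absorbs strongly in red
    and green, transmitting blue, while eosin absorbs mostly green).
    """
    od = _tissue_od(img, config)
    if od.shape[0] < config.min_tissue_pixels:
        raise StainEstimationError(
            f"only {od.shape[0]} tissue pixels above OD {config.od_threshold} "
            f"(need {config.min_tissue_pixels})"
        )
    centered = od - od.mean(axis=0)
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    # quantization noise sits near 4e-3 of the leading singular value; a
    # genuine second stain direction sits far above this cut
    if svals[1] < 0.02 * max(svals[0], 1e-30):
        raise StainEstimationError(
            "optical-density cloud is collinear (single stain?); "
            "cannot span a two-stain plane"
        )
    basis = vt[:2]  # plane through the OD centroid; directions only
    # orient the basis so projections of the (uncentered) cloud are positive
    proj = od @ basis.T
    for k in range(2):
        if np.median(proj[:, k]) < 0:
            basis[k] = -basis[k]
            proj[:, k] = -proj[:, k]
    angles = np.arctan2(proj[:, 1], proj[:, 0])
    lo = np.percentile(angles, config.angle_percentile)
    hi = np.percentile(angles, 100.0 - config.angle_percentile)
    v_lo = np.cos(lo) * basis[0] + np.sin(lo) * basis[1]
    v_hi = np.cos(hi) * basis[0] + np.sin(hi) * basis[1]
    rows = np.stack([v_lo, v_hi])
    rows = np.maximum(rows, 0.0)  # absorbance cannot be negative
    norms = np.linalg.norm(rows, axis=1)
    if np.any(norms < 1e-8):
        raise StainEstimationError("degenerate stain direction estimated")
    rows = rows / norms[:, None]
    if rows[0, 0] < rows[1, 0]:  # hematoxylin first (larger red absorbance)
        rows = rows[::-1]
    return StainMatrix(rows)


def estimate_concentrations(img: np.ndarray, stain: StainMatrix,
                            background: float = DEFAULT_BACKGROUND) -> np.ndarray:
    """Per-pixel H/E concentrations: least-squares solution of
    ``OD = C . S`` with negatives clipped to zero.  Returns HxWx2."""
    od = rgb_to_od(img, background=background)
    h, w, _ = od.shape
    s = stain.rows  # (2, 3)
    gram = s @ s.T
    if np.linalg.cond(gram) > 1e8:
        raise np.linalg.LinAlgError("stain matrix is (near-)singular")
    conc = od.reshape(-1, 3) @ s.T @ np.linalg.inv(gram)
    return np.maximum(conc, 0.0).reshape(h, w, 2)


def fit_template(
    img: np.ndarray, config: NormalizationConfig = NormalizationConfig()
) -> NormalizationTemplate:
    """Build a normalization template from a reference image: brightness
    standardization, Macenko stain estimation, and the robust
    (99th-percentile) per-stain concentration scale."""
    std = standardize_brightness(img)
    stain = estimate_stain_matrix(std, config)
    conc = estimate_concentrations(std, stain, background=config.background)
    max_conc = np.percentile(
        conc.reshape(-1, 2), config.concentration_percentile, axis=0
    )
    max_conc = np.maximum(max_conc, 1e-6)
    return NormalizationTemplate(
        stain=stain, max_conc=max_conc, background=config.background
    )


def normalize(
    img: np.ndarray,
    template: NormalizationTemplate,
    config: NormalizationConfig = NormalizationConfig(),
    source_id: str | None = None,
) -> np.ndarray:
    """Map ``img`` into the template's color frame.

    The source image is brightness-standardized, its own stain matrix and
    concentrations are estimated, concentrations are rescaled channel-wise
    to the template's robust range, and the image is re-rendered through
    the *template* stain matrix.
    """
    try:
        std = standardize_brightness(img)
        stain = estimate_stain_matrix(std, config)
        conc = estimate_concentrations(std, stain, background=config.background)
    except (StainEstimationError, np.linalg.LinAlgError) as err:
        tag = f" (source {source_id})" if source_id else ""
        raise StainEstimationError(f"normalization failed{tag}: {err}") from err
    src_max = np.percentile(conc.reshape(-1, 2), config.concentration_percentile, axis=0)
    src_max = np.maximum(src_max, 1e-6)
    conc = conc * (template.max_conc / src_max)
    return render(template.stain, conc, background=template.background)
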