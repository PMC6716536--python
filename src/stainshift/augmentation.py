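"""Random channel-wise scale-and-shift color augmentation.

Each presentation of a training patch gets fresh per-channel constants
``a_c`` (scale) and ``b_c`` (shift) and is transformed as
``I'_c = a_c * I_c + b_c``.  The affine map can be applied in RGB
(default), HSV, or the fixed-basis HED deconvolution space; in non-RGB
spaces the channels are first mapped onto a nominal 0–255 scale so the
``a``/``b`` ranges mean the same thing everywhere.  The width of the
``a``/``b`` ranges controls how much staining variation the classifier is
exposed to.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color as skcolor

__all__ = ["AugmentationParams", "AugmentationConfig", "sample_params", "apply"]

_SPACES = ("RGB", "HSV", "HED")


@dataclass(frozen=True)
class AugmentationParams:
    """One draw of the per-channel affine constants."""

    a: np.ndarray
    b: np.ndarray
    space: str = "RGB"

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if a.shape != (3,) or b.shape != (3,):
            raise ValueError("a and b must be 3-vectors")
        if self.space not in _SPACES:
            raise ValueError(f"space must be one of {_SPACES}")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)


@dataclass(frozen=True)
class AugmentationConfig:
    """Sampling ranges for the affine constants.

    Defaults (a in [0.9, 1.1], b in [-10, +10] intensity levels, RGB) are
    conservative: strong enough to blur center signatures, weak enough to
    keep tissue plausibly H&E-colored.  ``per_image`` keeps the standard
    practice of drawing fresh constants for every patch presentation;
    setting it False draws once per batch.
    """

    a_range: tuple[float, float] = (0.9, 1.1)
    b_range: tuple[float, float] = (-10.0, 10.0)
    space: str = "RGB"
    per_image: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.a_range[0] <= self.a_range[1]:
            raise ValueError("need 0 < a_min <= a_max")
        if self.b_range[0] > self.b_range[1]:
            raise ValueError("need b_min <= b_max")
        if self.space not in _SPACES:
            raise ValueError(f"space must be one of {_SPACES}")


def sample_params(config: AugmentationConfig, rng: np.random.Generator) -> AugmentationParams:
    """Draw ``a`` and ``b`` independently and uniformly per channel."""
    return AugmentationParams(
        a=rng.uniform(config.a_range[0], config.a_range[1], size=3),
        b=rng.uniform(config.b_range[0], config.b_range[1], size=3),
        space=config.space,
    )


def apply(img: np.ndarray, params: AugmentationParams) -> np.ndarray:
    """Apply the per-channel affine map in the configured color space.

    RGB operates directly on the 0–255 intensities (identity parameters are
    bit-exact identity).  HSV and HED channels are scaled to a nominal
    0–255 range before the affine map so the same parameter ranges apply,
    then converted back to RGB.  Output is always uint8 in [0, 255].
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected HxWx3 image, got {img.shape}")
    a, b = params.a, params.b
    if params.space == "RGB":
        out = img.astype(float) * a + b
        return np.clip(np.rint(out), 0, 255).astype(np.uint8)
    if params.space == "HSV":
        hsv = skcolor.rgb2hsv(img / 255.0) * 255.0
        hsv = np.clip(hsv * a + b, 0.0, 255.0)
        out = skcolor.hsv2rgb(hsv / 255.0)
    else:  # HED: fixed canonical deconvolution basis, unbounded OD-like axes
        hed = skcolor.rgb2hed(img / 255.0) * 255.0
        hed = hed * a + b
        out = skcolor.hed2rgb(hed / 255.0)
    return np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)
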