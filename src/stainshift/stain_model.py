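"""Beer–Lambert color physics for two-stain (H&E) brightfield images.

A brightfield scanner records transmitted light: a pixel stained with
hematoxylin and eosin at concentrations ``C = (c_H, c_E)`` has channel
intensity

    I_c = I_0 * exp(-S_c . C),   c in {R, G, B}

where ``S`` is the 2x3 matrix of per-channel absorbance coefficients of the
two stains and ``I_0`` the background (unstained glass) intensity.  Working
in optical density ``OD_c = -ln(I_c / I_0)`` makes stain contributions add
linearly, which is what every deconvolution and normalization step in this
package relies on.

Conventions (package-wide): natural logarithm; stain rows stored with unit
Euclidean norm so that concentration carries all magnitude; background
defaults to 255 on every channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image

__all__ = [
    "StainMatrix",
    "DEFAULT_BACKGROUND",
    "INTENSITY_FLOOR",
    "rgb_to_od",
    "od_to_rgb",
    "render",
    "read_patch",
    "write_patch",
]

#: Default background intensity I_0 (unstained glass, close to white).
DEFAULT_BACKGROUND: float = 255.0

#: Raw intensity 0 is clamped to this value before the logarithm so the
#: optical density stays bounded.
INTENSITY_FLOOR: float = 1.0

# Classical H&E absorbance reference vectors (unnormalized), widely used as
# deconvolution defaults.
CANONICAL_HEMATOXYLIN = np.array([0.65, 0.70, 0.29])
CANONICAL_EOSIN = np.array([0.07, 0.99, 0.11])


@dataclass(frozen=True)
class StainMatrix:
    """The 2x3 absorbance matrix S: row 0 hematoxylin, row 1 eosin (RGB).

    Rows are unit-normalized on construction; they must be non-negative and
    linearly independent.
    """

    rows: np.ndarray = field(
        default_factory=lambda: np.stack([CANONICAL_HEMATOXYLIN, CANONICAL_EOSIN])
    )

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, dtype=float)
        if rows.shape != (2, 3):
            raise ValueError(f"stain matrix must be 2x3, got {rows.shape}")
        if np.any(rows < 0):
            raise ValueError("stain absorbance coefficients must be non-negative")
        norms = np.linalg.norm(rows, axis=1)
        if np.any(norms == 0):
            raise ValueError("stain rows must be non-zero")
        rows = rows / norms[:, None]
        if np.linalg.matrix_rank(rows, tol=1e-8) < 2:
            raise ValueError("stain rows must be linearly independent")
        object.__setattr__(self, "rows", rows)

    @property
    def hematoxylin(self) -> np.ndarray:
        return self.rows[0]

    @property
    def eosin(self) -> np.ndarray:
        return self.rows[1]

    def angular_distance(self, other: "StainMatrix") -> np.ndarray:
        """Per-row angle (degrees) between this matrix and ``other``."""
        dots = np.clip(np.sum(self.rows * other.rows, axis=1), -1.0, 1.0)
        return np.degrees(np.arccos(dots))


def _check_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected HxWx3 RGB image, got shape {img.shape}")
    return img


def rgb_to_od(img: np.ndarray, background: float = DEFAULT_BACKGROUND) -> np.ndarray:
    """Convert 8-bit RGB intensities to optical density (absorbance).

    ``OD_c = -ln(max(I_c, floor) / I_0)``.  Intensity 0 is clamped to
    :data:`INTENSITY_FLOOR` so the result is finite everywhere.  Intensities
    above the background map to small negative OD and are clipped at 0.
    """
    if background <= 0:
        raise ValueError(f"background intensity must be positive, got {background}")
    img = _check_rgb(img).astype(float)
    od = -np.log(np.maximum(img, INTENSITY_FLOOR) / background)
    return np.maximum(od, 0.0)


def od_to_rgb(od: np.ndarray, background: float = DEFAULT_BACKGROUND) -> np.ndarray:
    """Invert :func:`rgb_to_od`: ``I_c = round(I_0 * exp(-OD_c))``, uint8."""
    if background <= 0:
        raise ValueError(f"background intensity must be positive, got {background}")
    od = np.asarray(od, dtype=float)
    if np.any(od < 0):
        raise ValueError("optical density must be non-negative")
    rgb = np.rint(background * np.exp(-od))
    return np.clip(rgb, 0, 255).astype(np.uint8)


def render(
    stain: StainMatrix,
    conc: np.ndarray,
    background: float = DEFAULT_BACKGROUND,
) -> np.ndarray:
    """Render an RGB image from a stain matrix and an HxWx2 concentration map.

    Per pixel the optical density is ``C . S`` (2-vector times 2x3 matrix);
    zero concentration everywhere yields a uniform background image.
    """
    conc = np.asarray(conc, dtype=float)
    if conc.ndim != 3 or conc.shape[2] != 2:
        raise ValueError(f"concentration map must be HxWx2, got shape {conc.shape}")
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    od = conc @ stain.rows  # (H, W, 2) @ (2, 3) -> (H, W, 3)
    return od_to_rgb(od, background=background)


def read_patch(path) -> np.ndarray:
    """Read an 8-bit RGB patch (PNG/TIFF) as an HxWx3 uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.uint8)


def write_patch(path, img: np.ndarray) -> None:
    """Write an HxWx3 uint8 array as PNG/TIFF (format from the extension)."""
    img = _check_rgb(img)
    Image.fromarray(img.astype(np.uint8), mode="RGB").save(path)
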