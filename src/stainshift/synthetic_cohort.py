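"""Synthetic multi-center H&E-like patch cohort.

Real multi-center patch datasets carry two independent signals: the task
signal (e.g. mitotic figures — dark, hematoxylin-rich nuclear objects on a
pink eosin stroma) and the center signal (each lab's staining protocol and
scanner leave a color signature).  This generator reproduces exactly that
statistical structure so the whole normalization / augmentation /
domain-adversarial pipeline can be exercised without any slide downloads:

* **class signal** lives only in morphology — the number and size of
  nucleus-like elliptical blobs in the hematoxylin concentration channel
  (positive patches have many small blobs, negatives few larger ones);
* **center signal** lives only in appearance — centers sit on a
  one-dimensional "staining protocol" axis controlling a rotation of the
  classical H&E stain vectors, a brightness offset, per-channel gains and
  an over/under-staining concentration multiplier, plus per-center pixel
  noise;
* **external shift** — external-test centers sit further along the *same*
  protocol axis than any training center (larger stain-vector rotation,
  stronger photometric offsets, visibly weaker staining), so the external
  partition's stain parameters are outside the training centers' range.

The mean hematoxylin load of positive patches is only mildly higher than
that of negatives (the class-conditional totals overlap heavily), so mean
color is a poor class predictor while remaining a strong center predictor —
the regime in which domain-adversarial training is interesting.

No attempt is made at photorealistic histology; only the statistical
structure the pipeline assumes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .stain_model import (
    CANONICAL_EOSIN,
    CANONICAL_HEMATOXYLIN,
    StainMatrix,
    render,
    write_patch,
)

__all__ = [
    "BlobParams",
    "CenterProfile",
    "CohortConfig",
    "PatchRecord",
    "make_centers",
    "make_patch",
    "make_cohort",
    "make_slide",
    "PARTITIONS",
]

PARTITIONS = ("train", "validation", "internal_test", "external_test")


@dataclass(frozen=True)
class BlobParams:
    """Nucleus-blob statistics for one class: count range, radius range,
    eccentricity range (minor/major axis ratio)."""

    count_range: tuple[int, int]
    radius_range: tuple[float, float]
    eccentricity_range: tuple[float, float] = (0.6, 1.0)


@dataclass(frozen=True)
class CenterProfile:
    """One center's appearance parameters."""

    center_id: str
    stain: StainMatrix
    brightness_offset: float
    channel_gain: np.ndarray
    noise_sd: float
    concentration_scale: float = 1.0  # over/under-staining multiplier

    def __post_init__(self) -> None:
        gain = np.asarray(self.channel_gain, dtype=float)
        if gain.shape != (3,) or np.any(gain <= 0):
            raise ValueError("channel_gain must be a positive 3-vector")
        object.__setattr__(self, "channel_gain", gain)


@dataclass(frozen=True)
class CohortConfig:
    """Full description of a synthetic cohort; the cohort is a pure
    function of this config (including ``seed``).

    Patch counts are per class-balanced unit: each center contributes
    ``n_patches`` patches to each of its partitions, with a positive
    fraction of ``class_ratio``.  Training centers feed the train /
    validation / internal_test partitions; external centers feed only
    external_test, with disjoint center ids.
    """

    n_train_centers: int = 3
    n_external_centers: int = 1
    n_train: int = 250
    n_validation: int = 80
    n_internal_test: int = 150
    n_external_test: int = 300
    patch_size: int = 64
    class_ratio: float = 0.2
    negative_blobs: BlobParams = field(
        default_factory=lambda: BlobParams((3, 6), (2.5, 4.0))
    )
    # radius ranges chosen so expected total blob area matches the negative
    # class: the classes differ in granularity, not in overall stained area
    positive_blobs: BlobParams = field(
        default_factory=lambda: BlobParams((9, 15), (1.6, 2.6))
    )
    # Centers sit on a one-dimensional "staining protocol" axis: training
    # centers span protocol coordinates t in [-1, 1], external centers sit
    # at t = external_shift / within_shift, i.e. further along the *same*
    # axes of variation (stain-vector rotation, brightness, channel gain)
    # — outside the training range the way a new lab/scanner is.
    # within_shift: stain-row rotation (degrees) at |t| = 1.
    # external_shift: stain-row rotation (degrees) of external centers.
    within_shift: float = 4.0
    external_shift: float = 15.0
    brightness_scale: float = 8.0  # intensity offset at |t| = 1
    gain_scale: float = 0.05  # per-channel gain deviation at |t| = 1
    # stain-strength multiplier deviation at |t| = 1: over/under-staining
    # and section-thickness differences scale all concentrations; the
    # coordinate saturates at |t| = 2.5 (protocol differences in staining
    # amount are bounded in a way color casts are not)
    stain_strength_scale: float = -0.08
    stain_strength_t_cap: float = 2.5
    noise_sd_range: tuple[float, float] = (1.0, 3.0)
    external_noise_sd_range: tuple[float, float] = (2.0, 4.0)
    # Eosin stroma texture: mean / sd of the smooth background field.
    eosin_mean: float = 0.35
    eosin_sd: float = 0.08
    # Hematoxylin mass budget: base total, count-coupling exponent, jitter.
    hematoxylin_mass: float = 140.0
    mass_count_exponent: float = 0.05
    mass_jitter: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.class_ratio < 1.0:
            raise ValueError("class_ratio must be in (0, 1)")
        if self.external_shift <= self.within_shift:
            raise ValueError(
                "external_shift must strictly exceed the within-center shift"
            )
        if self.n_train_centers < 1 or self.n_external_centers < 1:
            raise ValueError("need at least one training and one external center")


@dataclass
class PatchRecord:
    """One labeled patch: pixels (or a file reference), origin, task label,
    center (domain) label and partition."""

    image: np.ndarray | str
    x: int
    y: int
    task_label: int
    domain_label: str
    partition: str

    def __post_init__(self) -> None:
        if self.partition not in PARTITIONS:
            raise ValueError(f"unknown partition {self.partition!r}")
        if self.task_label not in (0, 1):
            raise ValueError("task_label must be 0 or 1")


def _rotation_direction(v: np.ndarray, pos_angle_deg: float,
                        neg_angle_deg: float, rng: np.random.Generator,
                        max_tries: int = 2000) -> np.ndarray:
    """Random unit direction orthogonal to ``v`` such that rotating ``v``
    by up to ``pos_angle_deg`` forward and ``neg_angle_deg`` backward stays
    in the non-negative orthant."""
    for _ in range(max_tries):
        w = rng.normal(size=3)
        w -= np.dot(w, v) * v
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            continue
        w /= nw
        for cand in (w, -w):
            ok = True
            for ang in (pos_angle_deg, -neg_angle_deg):
                theta = np.radians(ang)
                if np.any(np.cos(theta) * v + np.sin(theta) * cand < 0):
                    ok = False
                    break
            if ok:
                return cand
    raise RuntimeError(
        f"no orthant-safe rotation direction for +{pos_angle_deg}/"
        f"-{neg_angle_deg} deg"
    )


def _rotate(v: np.ndarray, w: np.ndarray, angle_deg: float) -> np.ndarray:
    theta = np.radians(angle_deg)
    return np.cos(theta) * v + np.sin(theta) * w


def make_centers(config: CohortConfig) -> list[CenterProfile]:
    """Draw the center profiles along the staining-protocol axis.

    A fixed (per-cohort) rotation direction is drawn for each stain row
    together with a fixed gain direction; a center at protocol coordinate
    ``t`` rotates the canonical H/E rows by ``t * within_shift`` degrees
    along those directions, offsets brightness by ``t * brightness_scale``
    and scales channels by ``1 + t * gain_scale * g``.  Training centers
    span ``t`` in [-1, 1]; external centers sit at ``t = external_shift /
    within_shift`` (and beyond), so every external stain row is at least
    ``external_shift - within_shift`` degrees from every training row.
    Deterministic given ``config.seed``.

    The rotation direction must keep both canonical rows inside the
    non-negative orthant over the whole protocol range; the eosin vector's
    small red/blue components make this infeasible for ``within_shift``
    much above ~6 degrees, in which case center construction raises.
    """
    rng = np.random.default_rng(config.seed)
    canon_h = CANONICAL_HEMATOXYLIN / np.linalg.norm(CANONICAL_HEMATOXYLIN)
    canon_e = CANONICAL_EOSIN / np.linalg.norm(CANONICAL_EOSIN)
    t_ext_base = config.external_shift / config.within_shift
    pos_angle = config.external_shift * 1.2
    neg_angle = config.within_shift
    w_h = _rotation_direction(canon_h, pos_angle, neg_angle, rng)
    w_e = _rotation_direction(canon_e, pos_angle, neg_angle, rng)
    gain_dir = rng.uniform(-1.0, 1.0, size=3)
    gain_dir /= np.max(np.abs(gain_dir))

    def draw(center_id: str, t: float, noise_range) -> CenterProfile:
        rows = np.stack([
            _rotate(canon_h, w_h, t * config.within_shift),
            _rotate(canon_e, w_e, t * config.within_shift),
        ])
        gains = np.clip(1.0 + t * config.gain_scale * gain_dir, 0.5, 2.0)
        return CenterProfile(
            center_id=center_id,
            stain=StainMatrix(np.maximum(rows, 0.0)),
            brightness_offset=t * config.brightness_scale,
            channel_gain=gains,
            noise_sd=rng.uniform(*noise_range),
            concentration_scale=max(
                1.0
                + np.clip(t, -config.stain_strength_t_cap,
                          config.stain_strength_t_cap)
                * config.stain_strength_scale,
                0.2,
            ),
        )

    n = config.n_train_centers
    spread = np.linspace(-1.0, 1.0, n) if n > 1 else np.array([0.0])
    t_train = np.clip(spread + rng.uniform(-0.1, 0.1, size=n), -1.0, 1.0)
    centers = [
        draw(f"train_{i}", float(t), config.noise_sd_range)
        for i, t in enumerate(t_train)
    ]
    for i in range(config.n_external_centers):
        t = t_ext_base + rng.uniform(0.0, 0.2 * t_ext_base)
        centers.append(
            draw(f"external_{i}", float(t), config.external_noise_sd_range)
        )
    return centers


def _eosin_field(size: int, mean: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth positive stroma texture: coarse Gaussian grid, cubic upsample."""
    coarse_n = max(size // 8, 2)
    coarse = rng.normal(mean, sd, size=(coarse_n, coarse_n))
    zoom = size / coarse_n
    field = ndimage.zoom(coarse, zoom, order=3)[:size, :size]
    return np.maximum(field, 0.0)


def _blob_field(size: int, params: BlobParams, rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Sum of anti-aliased elliptical blob kernels; returns (field, count)."""
    n = int(rng.integers(params.count_range[0], params.count_range[1] + 1))
    field = np.zeros((size, size))
    yy, xx = np.mgrid[0:size, 0:size]
    for _ in range(n):
        r = rng.uniform(*params.radius_range)
        ecc = rng.uniform(*params.eccentricity_range)
        phi = rng.uniform(0.0, np.pi)
        cx = rng.uniform(r, size - r)
        cy = rng.uniform(r, size - r)
        dx, dy = xx - cx, yy - cy
        u = dx * np.cos(phi) + dy * np.sin(phi)
        v = -dx * np.sin(phi) + dy * np.cos(phi)
        d2 = (u / r) ** 2 + (v / (r * ecc)) ** 2
        # compact smooth profile; the soft edge anti-aliases the ellipse
        field += np.maximum(0.0, 1.0 - d2) ** 1.5
    return field, n


def make_patch(
    center: CenterProfile,
    task_label: int,
    config: CohortConfig,
    rng: np.random.Generator,
    partition: str = "train",
) -> PatchRecord:
    """Generate one patch for ``center``.

    Concentration maps: eosin = smooth positive stroma texture; hematoxylin
    = blob field whose count/size statistics depend on ``task_label``,
    rescaled so the total hematoxylin mass is ``hematoxylin_mass *
    (count / 8)^mass_count_exponent`` with multiplicative jitter — positives
    carry mildly more hematoxylin on average but the totals overlap.
    Rendered through the center's stain matrix, then brightness offset,
    channel gains and Gaussian pixel noise are applied and the result is
    clipped to [0, 255].
    """
    size = config.patch_size
    eosin = _eosin_field(size, config.eosin_mean, config.eosin_sd, rng)
    params = config.positive_blobs if task_label == 1 else config.negative_blobs
    blobs, count = _blob_field(size, params, rng)
    total = blobs.sum()
    if total > 0:
        target = (
            config.hematoxylin_mass
            * (count / 8.0) ** config.mass_count_exponent
            * rng.uniform(1.0 - config.mass_jitter, 1.0 + config.mass_jitter)
        )
        blobs *= target / total
    # nuclei displace cytoplasm: attenuate eosin under strong hematoxylin
    eosin = eosin * np.exp(-1.5 * blobs)
    conc = np.stack([blobs, eosin], axis=-1) * center.concentration_scale
    img = render(center.stain, conc).astype(float)
    img = img * center.channel_gain + center.brightness_offset
    if center.noise_sd > 0:
        img = img + rng.normal(0.0, center.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    x, y = (int(v) for v in rng.integers(0, 4096, size=2))
    return PatchRecord(
        image=img,
        x=x,
        y=y,
        task_label=task_label,
        domain_label=center.center_id,
        partition=partition,
    )


def _labels_for(n: int, ratio: float, rng: np.random.Generator) -> np.ndarray:
    n_pos = int(round(n * ratio))
    labels = np.array([1] * n_pos + [0] * (n - n_pos))
    rng.shuffle(labels)
    return labels


def make_cohort(
    config: CohortConfig,
    out_dir: str | Path | None = None,
) -> tuple[list[PatchRecord], pd.DataFrame]:
    """Generate the full cohort.

    Returns the patch records (in-memory images, or file references when
    ``out_dir`` is given) and the manifest with columns
    ``path, x, y, task_label, domain_label, partition``.  When ``out_dir``
    is set, patches are written there as PNG and ``manifest.csv`` alongside.
    """
    rng = np.random.default_rng(config.seed + 1)
    centers = make_centers(config)
    train_centers = [c for c in centers if c.center_id.startswith("train")]
    ext_centers = [c for c in centers if c.center_id.startswith("external")]

    plan = []
    for c in train_centers:
        plan += [
            (c, "train", config.n_train),
            (c, "validation", config.n_validation),
            (c, "internal_test", config.n_internal_test),
        ]
    plan += [(c, "external_test", config.n_external_test) for c in ext_centers]

    records: list[PatchRecord] = []
    for center, partition, n in plan:
        for label in _labels_for(n, config.class_ratio, rng):
            records.append(make_patch(center, int(label), config, rng, partition))

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(records):
        if out_path is not None:
            fname = f"patch_{i:05d}.png"
            write_patch(out_path / fname, rec.image)
            rec.image = fname
            path = fname
        else:
            path = f"patch_{i:05d}"
        rows.append(
            {
                "path": path,
                "x": rec.x,
                "y": rec.y,
                "task_label": rec.task_label,
                "domain_label": rec.domain_label,
                "partition": rec.partition,
            }
        )
    manifest = pd.DataFrame(rows)
    if out_path is not None:
        manifest.to_csv(out_path / "manifest.csv", index=False)
    return records, manifest


def load_cohort(manifest_path: str | Path) -> list[PatchRecord]:
    """Load a written cohort back into memory from its manifest CSV."""
    from .stain_model import read_patch

    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    records = []
    for row in manifest.itertuples():
        records.append(
            PatchRecord(
                image=read_patch(base / row.path),
                x=int(row.x),
                y=int(row.y),
                task_label=int(row.task_label),
                domain_label=str(row.domain_label),
                partition=str(row.partition),
            )
        )
    return records


def make_deconvolution_phantom(
    stain: StainMatrix,
    size: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a phantom patch for stain-estimation studies.

    Per-pixel concentrations are drawn as magnitude ``m ~ U(0.2, 1.5)``
    split between the stains by ``t ~ Beta(0.5, 0.5)`` — the U-shaped
    mixing law puts plenty of near-pure pixels of both stains in the image,
    as real tissue does (nuclei nearly pure hematoxylin, stroma nearly pure
    eosin).  8% of pixels are unstained glass, so the image is already
    brightness-standard.  Returns ``(rgb, concentration_map)``.
    """
    t = rng.beta(0.5, 0.5, size=(size, size))
    m = rng.uniform(0.2, 1.5, size=(size, size))
    m[rng.random(size=(size, size)) < 0.08] = 0.0
    conc = np.stack([m * t, m * (1.0 - t)], axis=-1)
    return render(stain, conc), conc


def make_slide(
    center: CenterProfile,
    config: CohortConfig,
    rng: np.random.Generator,
    size: int = 512,
    tissue_fraction: float = 0.35,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a synthetic low-resolution slide: white glass background with
    one roughly circular tissue region carrying stroma texture and nuclear
    blobs.  Returns ``(rgb, tissue_mask)`` where the mask marks pixels with
    non-zero rendered concentration."""
    radius = np.sqrt(tissue_fraction / np.pi) * size
    cy, cx = rng.uniform(radius, size - radius, size=2)
    yy, xx = np.mgrid[0:size, 0:size]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2

    eosin = _eosin_field(size, config.eosin_mean, config.eosin_sd, rng)
    scaled = dataclasses.replace(
        config,
        negative_blobs=BlobParams((60, 90), (2.0, 4.0)),
        hematoxylin_mass=config.hematoxylin_mass * (size / config.patch_size) ** 2,
    )
    blobs, _ = _blob_field(size, scaled.negative_blobs, rng)
    total = blobs.sum()
    if total > 0:
        blobs *= scaled.hematoxylin_mass / total
    conc = np.stack([blobs, eosin], axis=-1)
    conc[~mask] = 0.0
    rgb = render(center.stain, conc)
    tissue = conc.sum(axis=-1) > 0
    return rgb, tissue
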