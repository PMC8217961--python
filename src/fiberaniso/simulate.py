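"""Synthetic fiber-image generator for calibrating the anisotropy method.

Each calibration image emulates a second-harmonic-generation field of view:
50 straight fibers drawn as rectangles on a dark background, with

* centres uniform over the full 512×512 px frame (fibers may be clipped),
* lengths uniform in 40–60 µm,
* a fixed diameter per image (2, 4, 6 or 8 µm in the standard design),
* orientations uniform in a configurable range [θmin, θmax] degrees,
  θ measured counterclockwise from the +x (column) axis, θ = 90° vertical.

Rectangles are rendered anti-aliased (fractional edge coverage) and
composited by maximum, so intersecting fibers form a binary-like union.
The rendered frame is then degraded by a normalised pillbox (circular
averaging) filter of radius 3 px followed by a normalised linear motion
kernel of length 5 px at a per-image random direction.  An optional white
noise stage adds a uniform non-negative field whose mean is a chosen
multiple of the image mean.

The standard calibration design spans 19 nested angle ranges, widening
by 5° per side from perfect alignment ([90°, 90°]) through [85°, 95°] down
to no alignment ([0°, 180°]), at 4 diameters with 100 images per cell:
7600 images and 18 consecutive range pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.ndimage
import yaml

from .image import DEFAULT_PIXEL_SIZE_UM, IntensityImage, save_image

__all__ = [
    "FiberSimConfig",
    "NoiseConfig",
    "ANGLE_RANGES",
    "DIAMETERS_UM",
    "simulate_fiber_image",
    "render_fibers",
    "sample_fibers",
    "degrade",
    "add_white_noise",
    "white_noise_image",
    "pillbox_kernel",
    "motion_kernel",
    "calibration_manifest",
    "generate_calibration_set",
]

#: The 19 nested orientation ranges of the calibration design (degrees),
#: widening by 5 deg per side from perfect alignment to none.  Nineteen
#: groups give the 18 consecutive pairs of the sensitivity analysis.
ANGLE_RANGES: tuple[tuple[int, int], ...] = tuple(
    (90 - 5 * k, 90 + 5 * k) for k in range(19))

#: Fiber diameters of the calibration design (µm).
DIAMETERS_UM: tuple[float, ...] = (2.0, 4.0, 6.0, 8.0)


@dataclass(frozen=True)
class FiberSimConfig:
    """Parameters of one synthetic fiber image."""

    n_fibers: int = 50
    diameter_um: float = 4.0
    length_range_um: tuple[float, float] = (40.0, 60.0)
    angle_range_deg: tuple[float, float] = (0.0, 180.0)
    image_px: int = 512
    fov_um: float = 180.0
    foreground: float = 255.0
    background: float = 0.0
    blur_radius_px: int = 3
    motion_len_px: int = 5
    motion_angle_deg: float | None = None  # None: drawn uniformly per image
    seed: int = 0

    def __post_init__(self) -> None:
        tmin, tmax = self.angle_range_deg
        if not (0 <= tmin <= tmax <= 180):
            raise ValueError("angle range must satisfy 0 <= min <= max <= 180")
        lo, hi = self.length_range_um
        if not (0 < lo <= hi):
            raise ValueError("length bounds must be positive and ordered")
        if self.diameter_um <= 0:
            raise ValueError("diameter must be positive")
        if self.n_fibers < 0:
            raise ValueError("n_fibers must be >= 0")

    @property
    def pixel_size_um(self) -> float:
        return self.fov_um / self.image_px


@dataclass(frozen=True)
class NoiseConfig:
    """Additive white-noise stage: mean = ``multiple`` × image mean."""

    multiple: float = 0.0
    distribution: str = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.multiple < 0:
            raise ValueError("noise multiple must be >= 0")
        if self.distribution != "uniform":
            raise ValueError(f"unknown distribution {self.distribution!r}")


# --- fiber sampling and rendering ---------------------------------------

def sample_fibers(config: FiberSimConfig,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Draw the per-fiber ground truth: angle, length, centre position.

    Columns: angle_deg, length_um, center_row, center_col.  Consuming the
    generator in one fixed order keeps the manifest and the renderer in
    lockstep for a given seed.
    """
    n = config.n_fibers
    tmin, tmax = config.angle_range_deg
    lo, hi = config.length_range_um
    return pd.DataFrame({
        "angle_deg": rng.uniform(tmin, tmax, n),
        "length_um": rng.uniform(lo, hi, n),
        "center_row": rng.uniform(0, config.image_px, n),
        "center_col": rng.uniform(0, config.image_px, n),
    })


def render_fibers(fibers: pd.DataFrame, config: FiberSimConfig) -> np.ndarray:
    """Rasterise fibers as anti-aliased rotated rectangles, overlap = max."""
    n_px = config.image_px
    img = np.full((n_px, n_px), float(config.background))
    half_w = 0.5 * config.diameter_um / config.pixel_size_um
    amp = float(config.foreground - config.background)
    for rec in fibers.itertuples(index=False):
        theta = math.radians(rec.angle_deg)
        half_l = 0.5 * rec.length_um / config.pixel_size_um
        # fiber axis in (row, col): x = +col, y points up (-row)
        u = (-math.sin(theta), math.cos(theta))
        v = (-math.cos(theta), -math.sin(theta))  # perpendicular
        reach = half_l + half_w + 1.5
        r0 = max(int(math.floor(rec.center_row - reach)), 0)
        r1 = min(int(math.ceil(rec.center_row + reach)) + 1, n_px)
        c0 = max(int(math.floor(rec.center_col - reach)), 0)
        c1 = min(int(math.ceil(rec.center_col + reach)) + 1, n_px)
        if r0 >= r1 or c0 >= c1:
            continue  # entirely outside the frame: silent clipping
        rr, cc = np.meshgrid(np.arange(r0, r1) - rec.center_row,
                             np.arange(c0, c1) - rec.center_col,
                             indexing="ij")
        d_long = np.abs(rr * u[0] + cc * u[1])
        d_perp = np.abs(rr * v[0] + cc * v[1])
        cover = (np.clip(half_l + 0.5 - d_long, 0.0, 1.0)
                 * np.clip(half_w + 0.5 - d_perp, 0.0, 1.0))
        patch = img[r0:r1, c0:c1]
        np.maximum(patch, config.background + amp * cover, out=patch)
    return img


def pillbox_kernel(radius: int) -> np.ndarray:
    """Circular (pillbox) averaging kernel, anti-aliased rim, sums to 1."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    off = np.arange(-radius, radius + 1)
    dist = np.hypot(off[:, None], off[None, :])
    k = np.clip(radius + 0.5 - dist, 0.0, 1.0)
    return k / k.sum()


def motion_kernel(length: int, angle_deg: float) -> np.ndarray:
    """Linear motion-blur kernel: a 1-px-wide anti-aliased segment, sums to 1."""
    if length < 1:
        raise ValueError("length must be >= 1")
    half = (length - 1) / 2.0
    r = int(math.ceil(half)) + 1
    off = np.arange(-r, r + 1)
    rr, cc = np.meshgrid(off, off, indexing="ij")
    theta = math.radians(angle_deg)
    u = (-math.sin(theta), math.cos(theta))
    v = (-math.cos(theta), -math.sin(theta))
    d_long = np.abs(rr * u[0] + cc * u[1])
    d_perp = np.abs(rr * v[0] + cc * v[1])
    k = (np.clip(half + 0.5 - d_long, 0.0, 1.0)
         * np.clip(1.0 - d_perp, 0.0, 1.0))
    return k / k.sum()


def degrade(image: IntensityImage | np.ndarray, config: FiberSimConfig,
            motion_angle_deg: float = 0.0):
    """Pillbox average then motion blur; both kernels are normalised so the
    interior mean is preserved (reflective boundary handling)."""
    arr = image.pixels if isinstance(image, IntensityImage) else np.asarray(image, float)
    out = scipy.ndimage.convolve(arr, pillbox_kernel(config.blur_radius_px),
                                 mode="reflect")
    if config.motion_len_px > 1:
        out = scipy.ndimage.convolve(
            out, motion_kernel(config.motion_len_px, motion_angle_deg),
            mode="reflect")
    if isinstance(image, IntensityImage):
        return IntensityImage(out, image.pixel_size_um, label=image.label)
    return out


def simulate_fiber_image(config: FiberSimConfig,
                         return_fibers: bool = False):
    """Render one degraded fiber image; bit-identical for a fixed seed.

    The motion-blur direction is drawn uniformly in [0°, 180°) per image
    after the fiber draws, from the same seeded stream.
    """
    rng = np.random.default_rng(config.seed)
    fibers = sample_fibers(config, rng)
    drawn = float(rng.uniform(0.0, 180.0))
    motion_angle = drawn if config.motion_angle_deg is None else \
        float(config.motion_angle_deg)
    raw = render_fibers(fibers, config)
    px = degrade(raw, config, motion_angle)
    img = IntensityImage(px, config.pixel_size_um,
                         label=f"sim-seed{config.seed}")
    if return_fibers:
        fibers = fibers.assign(motion_angle_deg=motion_angle)
        return img, fibers
    return img


# --- white noise ---------------------------------------------------------

def add_white_noise(image: IntensityImage, config: NoiseConfig) -> IntensityImage:
    """Add a uniform white-noise field of mean ``multiple × mean(image)``.

    The field is uniform on [0, 2kµ] so pixels stay non-negative without
    clipping bias.  ``multiple = 0`` returns the image unchanged.
    """
    if config.multiple == 0:
        return image
    mu = float(image.pixels.mean())
    if mu <= 0:
        raise ValueError("image mean is zero: noise target mean undefined")
    rng = np.random.default_rng(config.seed)
    noise = rng.uniform(0.0, 2.0 * config.multiple * mu, image.pixels.shape)
    return IntensityImage(image.pixels + noise, image.pixel_size_um,
                          label=image.label)


def white_noise_image(mean: float, shape: tuple[int, int] = (512, 512),
                      seed: int = 0,
                      pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
                      ) -> IntensityImage:
    """A pure white-noise field, uniform on [0, 2·mean] (isotropic)."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    rng = np.random.default_rng(seed)
    return IntensityImage(rng.uniform(0.0, 2.0 * mean, shape), pixel_size_um,
                          label=f"whitenoise-seed{seed}")


# --- calibration design --------------------------------------------------

def _derive_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic per-image seeds below 2**31 from one master seed."""
    return np.random.SeedSequence(master_seed).generate_state(n) % (2 ** 31)


def calibration_manifest(diameters_um=DIAMETERS_UM,
                         angle_ranges=ANGLE_RANGES,
                         n_per_cell: int = 100,
                         seed: int = 0,
                         base_config: FiberSimConfig | None = None
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Image-level and fiber-level ground truth of the calibration design.

    Returns ``(images, fibers)``: one row per image (image_id, seed,
    diameter_um, theta_min, theta_max) and one row per fiber.  The default
    design is 4 diameters × 19 ranges × 100 images = 7600 rows.
    """
    if n_per_cell < 1:
        raise ValueError("n_per_cell must be >= 1")
    base = base_config or FiberSimConfig()
    n_images = len(diameters_um) * len(angle_ranges) * n_per_cell
    seeds = _derive_seeds(seed, n_images)
    img_rows, fib_rows = [], []
    i = 0
    for diam in diameters_um:
        for (tmin, tmax) in angle_ranges:
            for rep in range(n_per_cell):
                image_id = f"d{diam:g}_r{tmin:g}-{tmax:g}_{rep:04d}"
                cfg = replace(base, diameter_um=float(diam),
                              angle_range_deg=(float(tmin), float(tmax)),
                              seed=int(seeds[i]))
                rng = np.random.default_rng(cfg.seed)
                fibers = sample_fibers(cfg, rng)
                drawn = float(rng.uniform(0.0, 180.0))
                motion_angle = drawn if cfg.motion_angle_deg is None else \
                    float(cfg.motion_angle_deg)
                img_rows.append({
                    "image_id": image_id, "seed": cfg.seed,
                    "diameter_um": diam, "theta_min": tmin,
                    "theta_max": tmax, "rep": rep,
                    "motion_angle_deg": motion_angle,
                })
                fib_rows.append(fibers.assign(image_id=image_id))
                i += 1
    images = pd.DataFrame(img_rows)
    fibers = pd.concat(fib_rows, ignore_index=True)
    return images, fibers


def generate_calibration_set(out_dir, diameters_um=DIAMETERS_UM,
                             angle_ranges=ANGLE_RANGES,
                             n_per_cell: int = 100, seed: int = 0,
                             base_config: FiberSimConfig | None = None,
                             force: bool = False) -> pd.DataFrame:
    """Render the calibration images to TIFF plus CSV manifests.

    Refuses to overwrite an existing manifest unless ``force`` is set.
    Same master seed → identical manifests and images.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.csv"
    if manifest_path.exists() and not force:
        raise FileExistsError(f"{manifest_path} exists; pass force=True to "
                              "overwrite")
    base = base_config or FiberSimConfig()
    images, fibers = calibration_manifest(diameters_um, angle_ranges,
                                          n_per_cell, seed, base)
    for rec in images.itertuples(index=False):
        cfg = replace(base, diameter_um=float(rec.diameter_um),
                      angle_range_deg=(float(rec.theta_min),
                                       float(rec.theta_max)),
                      seed=int(rec.seed))
        img = simulate_fiber_image(cfg)
        save_image(img, out_dir / f"{rec.image_id}.tif")
    images.to_csv(manifest_path, index=False)
    fibers.to_csv(out_dir / "fibers.csv", index=False)
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump({
            "n_fibers": base.n_fibers,
            "length_range_um": list(base.length_range_um),
            "image_px": base.image_px, "fov_um": base.fov_um,
            "blur_radius_px": base.blur_radius_px,
            "motion_len_px": base.motion_len_px,
            "diameters_um": [float(d) for d in diameters_um],
            "angle_ranges": [[float(a), float(b)] for a, b in angle_ranges],
            "n_per_cell": n_per_cell, "seed": seed,
        }, fh)
    return images
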