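"""Synthetic fruit-image generator with planted ground truth.

Real photographs of fruit shot apex-side-up on a black background are
emulated by a shaded disk: the class-discriminative signal is a small set
of low-amplitude colour blemishes whose radial placement (near the apex,
i.e. the disk centre, or near the outer contour) is controlled.  Because
the blemishes are planted, every image carries a pixel-exact truth mask,
which is what lets the saliency and geometry stages be tested against
known ground truth.

The class signal lives *only* in the blemishes: at ``blemish_amplitude=0``
positive and negative images are drawn from the same distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CameraProfile",
    "SceneConfig",
    "LabeledImage",
    "render_fruit",
    "generate_dataset",
    "save_dataset",
]


@dataclass(frozen=True)
class CameraProfile:
    """Per-channel affine sensor model: gain * white_balance * pixel."""

    brightness_gain: float = 1.0
    white_balance: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def gains(self) -> np.ndarray:
        return self.brightness_gain * np.asarray(self.white_balance, dtype=np.float64)


DEFAULT_CAMERAS = {
    "A": CameraProfile(1.0, (1.0, 1.0, 1.0)),
    "B": CameraProfile(0.92, (1.06, 1.0, 0.90)),
}

# (weight, d_low, d_high) mixture over normalized contour distance d:
# d=0 on the contour, d=1 at the apex (disk centre).  Default plants
# blemishes either near the apex or in the thin peripheral ring.
DEFAULT_PLACEMENT = ((0.5, 0.75, 1.0), (0.5, 0.0, 0.1))


@dataclass(frozen=True)
class SceneConfig:
    image_side: int = 224
    fruit_radius_range: tuple[float, float] | None = None  # px; default ~0.31-0.40 side
    background_level: float = 0.02
    base_color: tuple[float, float, float] = (0.85, 0.55, 0.20)
    color_jitter_sd: float = 0.03
    camera_profiles: dict = field(default_factory=lambda: dict(DEFAULT_CAMERAS))
    blemish_count_range: tuple[int, int] = (1, 3)
    blemish_amplitude: float = 0.05
    blemish_radius_range: tuple[float, float] | None = None  # px; default ~0.05-0.08 side
    blemish_placement: tuple = DEFAULT_PLACEMENT
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.image_side <= 0:
            raise ValueError("image_side must be positive")
        if self.fruit_radius_range is None:
            object.__setattr__(
                self, "fruit_radius_range",
                (0.31 * self.image_side, 0.40 * self.image_side),
            )
        if self.blemish_radius_range is None:
            object.__setattr__(
                self, "blemish_radius_range",
                (0.05 * self.image_side, 0.08 * self.image_side),
            )
        for w, lo, hi in self.blemish_placement:
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError("blemish placement support must lie in [0, 1]")


@dataclass
class LabeledImage:
    pixels: np.ndarray  # H x W x 3 float in [0, 1]
    label: int  # 1 = positive (rapid softening), 0 = negative (control)
    truth_mask: np.ndarray  # H x W bool, union of planted blemish disks
    camera_id: str
    fruit_id: str


# Blemish colour direction: slight darkening biased to green/blue, i.e.
# a brownish discolouration against the orange base.
_BLEMISH_DIR = np.array([0.3, 1.0, 0.8])


def _sample_placement(placement, rng: np.random.Generator) -> float:
    weights = np.array([w for w, _, _ in placement], dtype=float)
    weights /= weights.sum()
    k = rng.choice(len(placement), p=weights)
    _, lo, hi = placement[k]
    return float(rng.uniform(lo, hi))


def render_fruit(config: SceneConfig, label: int, rng: np.random.Generator,
                 camera_id: str = "A", fruit_id: str = "fruit0000") -> LabeledImage:
    """Render one fruit.  The rng stream is consumed identically for every
    camera, so the same generator state under two camera ids yields images
    that differ only by the cameras' gain/white-balance transform."""
    side = config.image_side
    if camera_id not in config.camera_profiles:
        raise KeyError(f"unknown camera_id {camera_id!r}")

    radius = rng.uniform(*config.fruit_radius_range)
    cy = side / 2 + rng.uniform(-0.02, 0.02) * side
    cx = side / 2 + rng.uniform(-0.02, 0.02) * side
    yy, xx = np.mgrid[0:side, 0:side]
    rho = np.hypot(yy - cy, xx - cx)
    fruit = rho <= radius

    jitter = 1.0 + rng.normal(0.0, config.color_jitter_sd, size=3)
    color = np.clip(np.asarray(config.base_color) * jitter, 0.0, 1.0)
    shading = 1.0 - 0.35 * np.clip(rho / radius, 0.0, 1.0) ** 2

    img = np.full((side, side, 3), config.background_level, dtype=np.float64)
    img[fruit] = color[None, :] * shading[fruit, None]

    truth = np.zeros((side, side), dtype=bool)
    if label == 1:
        lo, hi = config.blemish_count_range
        n_blem = int(rng.integers(lo, hi + 1))
        for _ in range(n_blem):
            brad = rng.uniform(*config.blemish_radius_range)
            if brad > radius:
                raise ValueError("blemish radius exceeds fruit radius")
            d = _sample_placement(config.blemish_placement, rng)
            # normalized contour distance d maps to radial position (1-d)*R
            brho = (1.0 - d) * radius
            theta = rng.uniform(0.0, 2.0 * np.pi)
            by = cy + brho * np.sin(theta)
            bx = brho * np.cos(theta) + cx
            dist = np.hypot(yy - by, xx - bx)
            disk = (dist <= brad) & fruit
            profile = np.clip(1.0 - (dist / brad) ** 2, 0.0, 1.0)
            img -= (config.blemish_amplitude
                    * profile[:, :, None] * _BLEMISH_DIR[None, None, :]) * fruit[:, :, None]
            truth |= disk
    else:
        # consume the same number of top-level draws as a typical positive
        # would not matter for class exchangeability; nothing to plant.
        pass

    img += rng.normal(0.0, config.noise_sd, size=img.shape)
    img *= config.camera_profiles[camera_id].gains()[None, None, :]
    np.clip(img, 0.0, 1.0, out=img)
    return LabeledImage(img, int(label), truth, camera_id, fruit_id)


def generate_dataset(config: SceneConfig, n_pos: int, n_neg: int,
                     camera_id: str = "A", seed: int | None = None) -> list[LabeledImage]:
    """Labelled images under one camera profile, reproducible given seed.

    Fruit ``i`` always consumes its own child rng (spawn key ``i``), so two
    datasets generated with the same seed under different cameras pair up
    fruit-by-fruit.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("counts must be nonnegative")
    if camera_id not in config.camera_profiles:
        raise KeyError(f"unknown camera_id {camera_id!r}")
    seed = config.seed if seed is None else seed
    labels = [1] * n_pos + [0] * n_neg
    children = np.random.SeedSequence(seed).spawn(len(labels))
    out = []
    for i, (lab, ss) in enumerate(zip(labels, children)):
        rng = np.random.Generator(np.random.PCG64(ss))
        out.append(render_fruit(config, lab, rng, camera_id=camera_id,
                                fruit_id=f"fruit{i:04d}"))
    return out


def save_dataset(images: list[LabeledImage], out_dir) -> "pandas.DataFrame":
    """Write PNGs plus a TSV manifest; returns the manifest."""
    import pandas as pd
    import imageio.v3 as iio
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for im in images:
        img_path = out_dir / f"{im.fruit_id}_{im.camera_id}.png"
        mask_path = out_dir / f"{im.fruit_id}_{im.camera_id}_mask.png"
        iio.imwrite(img_path, (im.pixels * 255).round().astype(np.uint8))
        iio.imwrite(mask_path, (im.truth_mask * 255).astype(np.uint8))
        rows.append(dict(fruit_id=im.fruit_id, camera_id=im.camera_id,
                         label="positive" if im.label else "negative",
                         image_path=img_path.name, mask_path=mask_path.name))
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return manifest
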