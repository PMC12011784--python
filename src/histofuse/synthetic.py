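"""Synthetic two-class H&E-like image generator.

Emulates the essential structure of haematoxylin & eosin histopathology
photomicrographs at a level sufficient to exercise a colour/texture
classification pipeline: an eosin-pink background carrying a smooth
multiplicative texture field, scattered haematoxylin-purple nucleus-like
blobs (anti-aliased filled ellipses with Gaussian-perturbed radii), and
per-channel sensor noise.  The two classes of a preset differ in controllable
colour-distribution and texture parameters (background hue, nucleus density
and size, texture correlation length), mimicking the normal-vs-malignant
contrast of real slide collections.

Determinism: every image is drawn from ``numpy.random.Generator(PCG64)``.
Dataset generation derives the per-image seed from the master seed and the
image index via ``SeedSequence((master_seed, image_index))``, so fixtures are
bit-stable across runs and platforms.

Class label coding throughout the package: 1 = normal tissue, 2 = malignant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.color import hsv2rgb

__all__ = [
    "ClassAppearance",
    "LabeledDataset",
    "PRESETS",
    "generate_image",
    "generate_dataset",
    "generate_preset_dataset",
    "save_dataset",
]

#: minimum image side accepted by :func:`generate_image`
MIN_SIZE = 32

#: HSV saturation / value used for nucleus interiors
_NUCLEUS_SAT = 0.55
_NUCLEUS_VAL = 0.45
_BACKGROUND_VAL = 0.92
_TEXTURE_STRENGTH = 0.06


@dataclass(frozen=True)
class ClassAppearance:
    """Controllable colour and texture statistics of one tissue class.

    Parameters
    ----------
    background_hue_deg:
        Hue of the eosin-like background in degrees, [0, 360).
    background_sat:
        Background saturation fraction in [0, 1].
    nucleus_hue_deg:
        Hue of nucleus blobs in degrees.
    nucleus_density:
        Expected blobs per 10^4 pixels; the rendered count is the rounded
        expectation (deterministic given the image area).
    nucleus_radius_px:
        (mean, sd) of the per-axis ellipse radius in pixels.
    texture_grain:
        Correlation length (Gaussian-filter sigma, px) of the multiplicative
        background noise field.
    jitter_sd:
        Per-channel Gaussian noise sd in 8-bit units.
    """

    background_hue_deg: float
    background_sat: float
    nucleus_hue_deg: float
    nucleus_density: float
    nucleus_radius_px: tuple[float, float] = (4.0, 1.0)
    texture_grain: float = 8.0
    jitter_sd: float = 3.0

    def __post_init__(self):
        if not 0.0 <= self.background_sat <= 1.0:
            raise ValueError("background_sat must lie in [0, 1]")
        if self.nucleus_density < 0:
            raise ValueError("nucleus_density must be non-negative")
        mean_r, sd_r = self.nucleus_radius_px
        if mean_r <= 0 or sd_r <= 0:
            raise ValueError("nucleus radius mean and sd must be positive")
        if self.texture_grain <= 0 or self.jitter_sd <= 0:
            raise ValueError("texture_grain and jitter_sd must be positive")


@dataclass
class LabeledDataset:
    """A list of RGB images with {1, 2} labels and free-text source tags."""

    images: list[np.ndarray]
    labels: np.ndarray
    tags: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels must have equal length")
        if len(self.labels) and not np.isin(self.labels, (1, 2)).all():
            raise ValueError("labels must be drawn from {1, 2}")
        if not self.tags:
            self.tags = [""] * len(self.images)
        if len(self.tags) != len(self.images):
            raise ValueError("tags must match images in length")

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, indices) -> "LabeledDataset":
        indices = np.asarray(indices, dtype=int)
        return LabeledDataset(
            images=[self.images[i] for i in indices],
            labels=self.labels[indices],
            tags=[self.tags[i] for i in indices],
        )


#: named two-class presets: (normal appearance, malignant appearance).
#: "easy" separates classes by a 40 degree background-hue gap plus distinct
#: texture grain and nucleus density; "hard" narrows the hue gap to 10 degrees
#: and brings the texture statistics closer together.
PRESETS: dict[str, tuple[ClassAppearance, ClassAppearance]] = {
    "easy": (
        ClassAppearance(330.0, 0.30, 272.0, nucleus_density=10.0,
                        nucleus_radius_px=(4.0, 1.0), texture_grain=8.0),
        ClassAppearance(290.0, 0.30, 272.0, nucleus_density=22.0,
                        nucleus_radius_px=(5.5, 1.5), texture_grain=2.5),
    ),
    "hard": (
        ClassAppearance(330.0, 0.30, 272.0, nucleus_density=10.0,
                        nucleus_radius_px=(4.0, 1.0), texture_grain=8.0),
        ClassAppearance(320.0, 0.30, 272.0, nucleus_density=14.0,
                        nucleus_radius_px=(4.5, 1.2), texture_grain=6.0),
    ),
}


def _blend_hue(bg_deg: float, fg_deg: float, alpha: np.ndarray) -> np.ndarray:
    """Circular interpolation between two hues, weighted by ``alpha``."""
    tb, tf = np.deg2rad(bg_deg), np.deg2rad(fg_deg)
    x = (1.0 - alpha) * np.cos(tb) + alpha * np.cos(tf)
    y = (1.0 - alpha) * np.sin(tb) + alpha * np.sin(tf)
    return np.mod(np.rad2deg(np.arctan2(y, x)), 360.0)


def generate_image(appearance: ClassAppearance, size: tuple[int, int],
                   seed) -> np.ndarray:
    """Render one H&E-like 8-bit RGB image of shape ``(H, W, 3)``.

    Deterministic for fixed ``(appearance, size, seed)``.  The number of
    nucleus blobs is ``round(density * H * W / 1e4)``, so an image contains at
    least one blob whenever that expectation reaches 1.
    """
    H, W = int(size[0]), int(size[1])
    if H < MIN_SIZE or W < MIN_SIZE:
        raise ValueError(f"image size must be at least {MIN_SIZE}x{MIN_SIZE}, got {H}x{W}")
    rng = np.random.default_rng(seed)

    noise = gaussian_filter(rng.standard_normal((H, W)), appearance.texture_grain)
    sd = noise.std()
    if sd > 0:
        noise *= _TEXTURE_STRENGTH / sd
    val = np.clip(_BACKGROUND_VAL * (1.0 + noise), 0.0, 1.0)
    sat = np.full((H, W), appearance.background_sat)

    # nucleus coverage map: max of anti-aliased ellipse masks
    alpha = np.zeros((H, W))
    mean_r, sd_r = appearance.nucleus_radius_px
    n_blobs = int(round(appearance.nucleus_density * H * W / 1e4))
    yy, xx = np.mgrid[0:H, 0:W]
    for _ in range(n_blobs):
        cx, cy = rng.uniform(0, W), rng.uniform(0, H)
        rx = max(1.2, rng.normal(mean_r, sd_r))
        ry = max(1.2, rng.normal(mean_r, sd_r))
        theta = rng.uniform(0.0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        # bounding box keeps the per-blob work O(radius^2)
        r = int(np.ceil(max(rx, ry))) + 2
        y0, y1 = max(0, int(cy) - r), min(H, int(cy) + r + 1)
        x0, x1 = max(0, int(cx) - r), min(W, int(cx) + r + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        dx = xx[y0:y1, x0:x1] - cx
        dy = yy[y0:y1, x0:x1] - cy
        u = (dx * ct + dy * st) / rx
        v = (-dx * st + dy * ct) / ry
        d = np.sqrt(u * u + v * v)
        a = np.clip((1.0 - d) * min(rx, ry), 0.0, 1.0)
        np.maximum(alpha[y0:y1, x0:x1], a, out=alpha[y0:y1, x0:x1])

    hue = _blend_hue(appearance.background_hue_deg, appearance.nucleus_hue_deg, alpha)
    sat = sat * (1.0 - alpha) + _NUCLEUS_SAT * alpha
    val = val * (1.0 - alpha) + _NUCLEUS_VAL * alpha

    hsv = np.stack([hue / 360.0, sat, val], axis=-1)
    rgb = hsv2rgb(hsv) * 255.0
    rgb += rng.normal(0.0, appearance.jitter_sd, rgb.shape)
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def _image_seed(master_seed: int, index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence((int(master_seed), int(index)))


def generate_dataset(class1: ClassAppearance, class2: ClassAppearance,
                     n_per_class: int, size: tuple[int, int], seed: int,
                     tag: str = "") -> LabeledDataset:
    """Generate a balanced two-class dataset of ``2 * n_per_class`` images.

    Per-image seeds derive from ``SeedSequence((seed, index))`` where the
    index enumerates class-1 images first, so the dataset is reproducible
    from the master seed alone.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be at least 1")
    images, labels = [], []
    for j, appearance in enumerate((class1, class2)):
        for i in range(n_per_class):
            idx = j * n_per_class + i
            images.append(generate_image(appearance, size, _image_seed(seed, idx)))
            labels.append(j + 1)
    tags = [tag] * len(images)
    return LabeledDataset(images=images, labels=np.array(labels), tags=tags)


def generate_preset_dataset(preset: str, n_per_class: int, size: tuple[int, int],
                            seed: int) -> LabeledDataset:
    """Generate a dataset from a named preset ("easy" or "hard")."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    c1, c2 = PRESETS[preset]
    return generate_dataset(c1, c2, n_per_class, size, seed, tag=preset)


def save_dataset(dataset: LabeledDataset, out_dir) -> Path:
    """Write images as PNG plus a ``manifest.csv`` (path, label, tag)."""
    from . import imaging  # local import: imaging owns file I/O

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (img, label, tag) in enumerate(zip(dataset.images, dataset.labels, dataset.tags)):
        name = f"img_{i:05d}_c{label}.png"
        imaging.save_image(out_dir / name, img)
        rows.append((name, int(label), tag))
    manifest = out_dir / "manifest.csv"
    imaging.write_manifest(manifest, rows)
    return manifest


def vary_hue_gap(base: ClassAppearance, gap_deg: float) -> ClassAppearance:
    """Second-class appearance shifted in background hue by ``gap_deg``."""
    return replace(base, background_hue_deg=(base.background_hue_deg - gap_deg) % 360.0)
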