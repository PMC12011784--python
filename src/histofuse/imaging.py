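"""Image I/O, augmentation, grayscale conversion and dataset partitioning.

Augmentation follows the standard histopathology recipe: horizontal and
vertical flips, random rotation within +/-15 degrees, and random brightness /
contrast / saturation adjustments.  Rotation uses bilinear resampling with
reflect padding, cropped back to the input size, so batch tensors stay
rectangular.  All random draws come from a single seeded PCG64 generator in a
documented order (hflip, vflip, angle, brightness, contrast, saturation), so
a fixed seed reproduces the augmentation exactly.

The train/validation/test partition uses floor-then-largest-remainder
rounding (ties broken in split order train, val, test), optionally stratified
by class label.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .synthetic import LabeledDataset

__all__ = [
    "AugmentSpec",
    "SplitSpec",
    "load_image",
    "save_image",
    "read_manifest",
    "write_manifest",
    "load_manifest_dataset",
    "augment",
    "sample_augment_params",
    "to_grayscale",
    "partition",
    "largest_remainder_sizes",
]

MANIFEST_COLUMNS = ("path", "label", "tag")


@dataclass(frozen=True)
class AugmentSpec:
    """Stochastic augmentation parameters; all-zero spec is the identity."""

    hflip_prob: float = 0.5
    vflip_prob: float = 0.5
    max_rotation_deg: float = 15.0
    brightness_delta: float = 0.1
    contrast_delta: float = 0.1
    saturation_delta: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.hflip_prob <= 1.0 and 0.0 <= self.vflip_prob <= 1.0):
            raise ValueError("flip probabilities must lie in [0, 1]")
        if self.max_rotation_deg < 0:
            raise ValueError("max_rotation_deg must be non-negative")
        if min(self.brightness_delta, self.contrast_delta, self.saturation_delta) < 0:
            raise ValueError("deltas must be non-negative")


@dataclass(frozen=True)
class SplitSpec:
    """Train/val/test ratios (must sum to 1) with optional stratification."""

    ratios: tuple[float, float, float] = (0.70, 0.15, 0.15)
    stratify: bool = True
    seed: int = 0

    def __post_init__(self):
        if len(self.ratios) != 3 or min(self.ratios) < 0:
            raise ValueError("ratios must be three non-negative fractions")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("ratios must sum to 1")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def load_image(path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG as 8-bit RGB (grayscale replicated, alpha dropped)."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            rgb = im.convert("RGB")
            return np.asarray(rgb, dtype=np.uint8)
    except FileNotFoundError:
        raise
    except OSError as exc:
        raise OSError(f"cannot decode image file {path}: {exc}") from exc


def save_image(path, image: np.ndarray) -> None:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an HxWx3 RGB array")
    Image.fromarray(image.astype(np.uint8), mode="RGB").save(Path(path))


def write_manifest(path, rows) -> None:
    """Write (path, label, tag) rows as CSV with the documented header."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for r in rows:
            writer.writerow(r)


def read_manifest(path) -> list[tuple[str, int, str]]:
    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(MANIFEST_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
        for rec in reader:
            rows.append((rec["path"], int(rec["label"]), rec.get("tag", "")))
    return rows


def load_manifest_dataset(manifest_path) -> LabeledDataset:
    """Load every image referenced by a manifest (paths relative to it)."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    rows = read_manifest(manifest_path)
    images = [load_image(base / p) for p, _, _ in rows]
    labels = np.array([lab for _, lab, _ in rows], dtype=int)
    tags = [tag for _, _, tag in rows]
    return LabeledDataset(images=images, labels=labels, tags=tags)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentDraws:
    """Concrete values drawn from an :class:`AugmentSpec` for one image."""

    hflip: bool
    vflip: bool
    angle_deg: float
    brightness: float  # multiplicative factor
    contrast: float
    saturation: float


def sample_augment_params(spec: AugmentSpec) -> AugmentDraws:
    """Draw one set of augmentation parameters (documented draw order)."""
    rng = np.random.default_rng(spec.seed)
    hflip = rng.uniform() < spec.hflip_prob
    vflip = rng.uniform() < spec.vflip_prob
    angle = rng.uniform(-spec.max_rotation_deg, spec.max_rotation_deg)
    bright = 1.0 + rng.uniform(-spec.brightness_delta, spec.brightness_delta)
    contrast = 1.0 + rng.uniform(-spec.contrast_delta, spec.contrast_delta)
    sat = 1.0 + rng.uniform(-spec.saturation_delta, spec.saturation_delta)
    return AugmentDraws(hflip, vflip, angle, bright, contrast, sat)


_LUMA = np.array([0.299, 0.587, 0.114])


def augment(image: np.ndarray, spec: AugmentSpec) -> np.ndarray:
    """Apply the flip/rotate/colour-jitter recipe; same output shape as input.

    A spec with zero probabilities and zero deltas is the pixelwise identity.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an HxWx3 RGB array")
    draws = sample_augment_params(spec)
    out = image.astype(np.float64)
    if draws.hflip:
        out = out[:, ::-1, :]
    if draws.vflip:
        out = out[::-1, :, :]
    if draws.angle_deg != 0.0:
        out = ndimage.rotate(out, draws.angle_deg, axes=(1, 0), reshape=False,
                             order=1, mode="reflect")
    if draws.brightness != 1.0:
        out = out * draws.brightness
    if draws.contrast != 1.0:
        mean = out.mean()
        out = (out - mean) * draws.contrast + mean
    if draws.saturation != 1.0:
        gray = out @ _LUMA
        out = gray[..., None] + (out - gray[..., None]) * draws.saturation
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Luminance grayscale with 0.299/0.587/0.114 weights, round-half-to-even."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an HxWx3 RGB array")
    gray = image.astype(np.float64) @ _LUMA
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# partitioning
# ---------------------------------------------------------------------------

def largest_remainder_sizes(n: int, ratios) -> list[int]:
    """Split ``n`` into integer sizes: floor targets, then distribute the
    remainder by largest fractional part (ties broken in ratio order)."""
    targets = [n * r for r in ratios]
    sizes = [int(np.floor(t)) for t in targets]
    remainder = n - sum(sizes)
    fracs = sorted(range(len(ratios)), key=lambda i: (-(targets[i] - sizes[i]), i))
    for i in fracs[:remainder]:
        sizes[i] += 1
    return sizes


def partition(dataset: LabeledDataset, spec: SplitSpec):
    """Partition into (train, val, test): disjoint, covering, seed-shuffled."""
    n = len(dataset)
    if n == 0:
        raise ValueError("cannot partition an empty dataset")
    rng = np.random.default_rng(spec.seed)

    def split_indices(indices: np.ndarray) -> list[np.ndarray]:
        indices = rng.permutation(indices)
        sizes = largest_remainder_sizes(len(indices), spec.ratios)
        bounds = np.cumsum([0] + sizes)
        return [indices[bounds[i]:bounds[i + 1]] for i in range(3)]

    if spec.stratify:
        parts = [[], [], []]
        for label in sorted(np.unique(dataset.labels)):
            cls_idx = np.flatnonzero(dataset.labels == label)
            for i, chunk in enumerate(split_indices(cls_idx)):
                parts[i].append(chunk)
        chunks = [np.concatenate(p) if p else np.array([], dtype=int) for p in parts]
    else:
        chunks = split_indices(np.arange(n))
    return tuple(dataset.subset(np.sort(c)) for c in chunks)
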