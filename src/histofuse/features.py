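"""Handcrafted colour and texture descriptors for H&E histology images.

Three expert feature families are extracted per image and concatenated into
one 818-dimensional vector:

* **FCH** — fuzzy colour histogram, 768 values.  Pixels are mapped to HSV and
  binned on a 12 (hue) x 8 (saturation) x 8 (value) grid with triangular
  membership functions peaking at bin centres and overlapping the two nearest
  bins per axis; hue wraps circularly, saturation/value clamp at the range
  ends.  Each pixel distributes exactly unit mass over at most 8 bins, so the
  normalised histogram sums to 1 regardless of how many fuzzy bins a pixel
  touches.  Fuzzy binning makes the descriptor robust to small staining
  shifts, the dominant nuisance axis in H&E material.
* **LBP** — rotation-invariant uniform local binary patterns with P=24
  circular neighbours at radius R=3 (bilinear neighbour interpolation,
  comparator "neighbour >= centre").  The code histogram has P+2 = 26 bins:
  one per uniform-pattern bit count 0..24 plus a non-uniform catch-all.
  Codes are collected from interior pixels only (a 3 px border is excluded).
  Sampling offsets are rounded to 8 decimals so the P=24 ring is exactly
  symmetric under quarter-turn rotations, and the comparator allows a 1e-6
  slack; together these make the histogram numerically invariant under
  90/180/270-degree image rotations instead of merely approximately so.
* **GLCM** — grey-level co-occurrence statistics.  The luminance image is
  quantised to 64 levels; symmetric normalised co-occurrence matrices are
  built at distance 1 for angles 0/45/90/135 degrees (pixel offsets
  (dr, dc) = (round(sin a), round(cos a))); for each angle six statistics are
  reported in the fixed order contrast, dissimilarity, homogeneity, energy,
  correlation, entropy — 24 values, angle-major.  Energy is the angular
  second moment; entropy uses the natural log with 0*log 0 = 0; correlation
  is defined as 0 when either marginal standard deviation is 0.

Layout of the fused vector: ``FCH[0:768] || LBP[768:794] || GLCM[794:818]``.
Every extractor is deterministic.
"""

from __future__ import annotations

import numpy as np
from skimage.color import rgb2hsv
from skimage.feature import graycomatrix

from .imaging import to_grayscale

__all__ = [
    "FCH_BINS",
    "LBP_P",
    "LBP_R",
    "GLCM_LEVELS",
    "GLCM_ANGLES_DEG",
    "GLCM_STATS",
    "fch_features",
    "lbp_features",
    "glcm_features",
    "handcrafted_vector",
    "feature_names",
]

FCH_BINS = (12, 8, 8)  # hue, saturation, value -> 768 bins
LBP_P = 24
LBP_R = 3
GLCM_LEVELS = 64
GLCM_ANGLES_DEG = (0, 45, 90, 135)
GLCM_STATS = ("contrast", "dissimilarity", "homogeneity", "energy",
              "correlation", "entropy")

FCH_DIM = int(np.prod(FCH_BINS))
LBP_DIM = LBP_P + 2
GLCM_DIM = len(GLCM_ANGLES_DEG) * len(GLCM_STATS)
HANDCRAFTED_DIM = FCH_DIM + LBP_DIM + GLCM_DIM


def _axis_memberships(coord: np.ndarray, k: int, circular: bool):
    """Triangular memberships of ``coord`` in [0, 1] over ``k`` bins.

    Returns two (index, weight) pairs per pixel; weights sum to 1.
    """
    u = coord * k - 0.5
    base = np.floor(u)
    frac = u - base
    i0 = base.astype(int)
    i1 = i0 + 1
    if circular:
        i0 %= k
        i1 %= k
    else:
        i0 = np.clip(i0, 0, k - 1)
        i1 = np.clip(i1, 0, k - 1)
    return (i0, 1.0 - frac), (i1, frac)


def fch_features(image: np.ndarray) -> np.ndarray:
    """768-bin fuzzy colour histogram; non-negative, sums to 1."""
    image = np.asarray(image)
    hsv = rgb2hsv(image.astype(np.float64) / 255.0)
    h = hsv[..., 0].ravel()
    s = hsv[..., 1].ravel()
    v = hsv[..., 2].ravel()
    kh, ks, kv = FCH_BINS
    hm = _axis_memberships(h, kh, circular=True)
    sm = _axis_memberships(s, ks, circular=False)
    vm = _axis_memberships(v, kv, circular=False)
    hist = np.zeros(kh * ks * kv)
    for hi, hw in hm:
        for si, sw in sm:
            for vi, vw in vm:
                np.add.at(hist, (hi * ks + si) * kv + vi, hw * sw * vw)
    return hist / h.size


_LBP_CMP_TOL = 1e-6


def _lbp_codes(gray: np.ndarray) -> np.ndarray:
    """Uniform-pattern bin per interior pixel (0..P uniform, P+1 catch-all)."""
    H, W = gray.shape
    R, P = LBP_R, LBP_P
    g = gray.astype(np.float64)
    center = g[R:H - R, R:W - R]
    # one-pixel edge pad so integral offsets (fraction 0) can still slice the
    # unused +1 row/col; its weight is exactly 0
    gp = np.pad(g, ((0, 1), (0, 1)), mode="edge")
    bits = np.empty((P,) + center.shape, dtype=bool)
    for k in range(P):
        theta = 2.0 * np.pi * k / P
        # rounding keeps the sample ring bit-symmetric under quarter turns
        dc = round(R * np.cos(theta), 8)
        dr = round(-R * np.sin(theta), 8)
        r0, c0 = int(np.floor(dr)), int(np.floor(dc))
        fr, fc = dr - r0, dc - c0
        block = gp[R + r0:H - R + r0 + 1, R + c0:W - R + c0 + 1]
        h, w = center.shape
        v = ((1 - fr) * (1 - fc) * block[:h, :w]
             + (1 - fr) * fc * block[:h, 1:w + 1]
             + fr * (1 - fc) * block[1:h + 1, :w]
             + fr * fc * block[1:h + 1, 1:w + 1])
        bits[k] = v >= center - _LBP_CMP_TOL
    transitions = np.zeros(center.shape, dtype=int)
    for k in range(P):
        transitions += bits[k] != bits[(k + 1) % P]
    counts = bits.sum(axis=0)
    return np.where(transitions <= 2, counts, P + 1)


def lbp_features(image: np.ndarray) -> np.ndarray:
    """26-bin rotation-invariant uniform LBP histogram over interior pixels."""
    image = np.asarray(image)
    gray = to_grayscale(image)
    if gray.shape[0] < 2 * LBP_R + 1 or gray.shape[1] < 2 * LBP_R + 1:
        raise ValueError(
            f"image must be at least {2 * LBP_R + 1} px per side for LBP radius {LBP_R}")
    codes = _lbp_codes(gray)
    hist = np.bincount(codes.ravel(), minlength=LBP_DIM).astype(float)
    return hist / hist.sum()


def _glcm_stats(p: np.ndarray) -> list[float]:
    """The six statistics of one normalised symmetric co-occurrence matrix."""
    g = p.shape[0]
    i = np.arange(g)[:, None]
    j = np.arange(g)[None, :]
    diff = i - j
    contrast = float((p * diff ** 2).sum())
    dissimilarity = float((p * np.abs(diff)).sum())
    homogeneity = float((p / (1.0 + diff ** 2)).sum())
    energy = float((p ** 2).sum())
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    var_i = float((p * (i - mu_i) ** 2).sum())
    var_j = float((p * (j - mu_j) ** 2).sum())
    if var_i <= 0.0 or var_j <= 0.0:
        correlation = 0.0  # declared zero-variance convention
    else:
        correlation = float((p * (i - mu_i) * (j - mu_j)).sum()
                            / np.sqrt(var_i * var_j))
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    return [contrast, dissimilarity, homogeneity, energy, correlation, entropy]


def glcm_features(image: np.ndarray) -> np.ndarray:
    """24 co-occurrence statistics: 4 angles x 6 statistics, angle-major."""
    image = np.asarray(image)
    gray = to_grayscale(image)
    quantized = (gray.astype(int) * GLCM_LEVELS) // 256
    angles = [np.deg2rad(a) for a in GLCM_ANGLES_DEG]
    mats = graycomatrix(quantized.astype(np.uint8), distances=[1], angles=angles,
                        levels=GLCM_LEVELS, symmetric=True, normed=True)
    out = []
    for a in range(len(angles)):
        out.extend(_glcm_stats(mats[:, :, 0, a]))
    return np.asarray(out)


def handcrafted_vector(image: np.ndarray) -> np.ndarray:
    """Concatenation FCH || LBP || GLCM, length 818."""
    return np.concatenate([fch_features(image), lbp_features(image),
                           glcm_features(image)])


def feature_names() -> list[str]:
    """Column names matching :func:`handcrafted_vector`'s layout."""
    names = [f"fch_{i:03d}" for i in range(FCH_DIM)]
    names += [f"lbp_{i:02d}" for i in range(LBP_DIM)]
    names += [f"glcm_{i:02d}" for i in range(GLCM_DIM)]
    return names
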