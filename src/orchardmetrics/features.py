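"""Per-tree color-moment and GLCM texture features from index images.

For each tree region's rectangular pixel window on each vegetation-index
grayscale image we compute the three low-order color moments (mean mu,
standard deviation sigma, signed cube-root third moment s) and four
Haralick-style texture statistics of the gray-level co-occurrence matrix
(contrast CON, correlation COR, angular second moment ASM, inverse
difference moment INM).  Feature vectors for the yield model are built by
concatenating these blocks across the ten indices, optionally with the
morphometric block (H, S_XOY, V, P).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.feature import graycomatrix

from .indices import INDEX_NAMES, IndexImage
from .segmentation import TreeRegion

#: Default GLCM configuration: 16 gray levels, distance 1, the four
#: standard directions.  Angles follow skimage's convention; the matching
#: (dy, dx) pixel offsets are listed alongside.
DEFAULT_LEVELS = 16
DEFAULT_ANGLES = (0.0, math.pi / 4, math.pi / 2, 3 * math.pi / 4)
DEFAULT_OFFSETS = ((0, 1), (1, 1), (1, 0), (1, -1))

TEXTURE_NAMES = ("CON", "COR", "ASM", "INM")
MOMENT_NAMES = ("mu", "sigma", "s")

#: Input modes of the yield model.  input1_<IDX> uses one index's moments
#: and textures plus the 3-value morphology block (H, S, V); input2 is the
#: 4-value morphology block alone; input3/4/5 are moments / textures /
#: both across all ten indices; input6 adds the morphology block to input5.
INPUT_MODES = ("input1", "input2", "input3", "input4", "input5", "input6")


@dataclass
class ColorMoments:
    mu: float
    sigma: float
    s: float


@dataclass
class TextureFeatures:
    CON: float
    COR: float
    ASM: float
    INM: float
    levels_N: int
    offsets: tuple[tuple[int, int], ...]
    cor_defined: bool = True


def color_moments(patch: np.ndarray) -> ColorMoments:
    """First three color moments of a grayscale patch.

    mu is the mean, sigma the root mean squared deviation, and s the
    signed cube root of the mean cubed deviation (sign preserved so
    negatively skewed patches get negative s).
    """
    patch = np.asarray(patch, dtype=np.float64)
    if patch.size == 0:
        raise ValueError("patch must be non-empty")
    mu = float(patch.mean())
    d = patch - mu
    sigma = float(np.sqrt(np.mean(d**2)))
    m3 = float(np.mean(d**3))
    s = math.copysign(abs(m3) ** (1.0 / 3.0), m3) if m3 != 0 else 0.0
    return ColorMoments(mu=mu, sigma=sigma, s=s)


def quantize(patch: np.ndarray, levels: int = DEFAULT_LEVELS) -> np.ndarray:
    """Uniformly bin a 0-255 grayscale patch into ``levels`` classes."""
    if levels < 2:
        raise ValueError("levels must be >= 2")
    q = (np.asarray(patch, dtype=np.int64) * levels) // 256
    return np.clip(q, 0, levels - 1).astype(np.uint8)


def glcm(
    patch: np.ndarray,
    levels: int = DEFAULT_LEVELS,
    distances: tuple[int, ...] = (1,),
    angles: tuple[float, ...] = DEFAULT_ANGLES,
) -> np.ndarray:
    """Normalized gray-level co-occurrence matrix of a quantized patch.

    Ordered neighbor pairs are counted for every (distance, angle) offset,
    summed across offsets, and normalized to total mass 1.  The patch must
    be large enough for at least one pair at the configured reach.
    """
    patch = np.asarray(patch)
    if patch.ndim != 2:
        raise ValueError("patch must be 2-D")
    reach = max(distances)
    if min(patch.shape) <= reach:
        raise ValueError(
            f"patch {patch.shape} smaller than the co-occurrence reach {reach}"
        )
    q = quantize(patch, levels)
    counts = graycomatrix(q, distances, angles, levels=levels,
                          symmetric=False, normed=False)
    p = counts.sum(axis=(2, 3)).astype(np.float64)
    total = p.sum()
    if total == 0:
        raise ValueError("no valid co-occurrence pairs in patch")
    return p / total


def texture_features(
    p: np.ndarray,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
) -> TextureFeatures:
    """CON, COR, ASM, INM of a normalized co-occurrence matrix.

    COR uses the marginal means and variances of p; a constant patch has
    zero marginal variance, in which case COR is reported as 0 with
    ``cor_defined=False`` rather than raising, so batch extraction never
    aborts on dead trees.
    """
    p = np.asarray(p, dtype=np.float64)
    N = p.shape[0]
    i = np.arange(N)[:, None]
    j = np.arange(N)[None, :]
    diff = np.abs(i - j)
    CON = float(np.sum(diff**2 * p))
    ASM = float(np.sum(p**2))
    INM = float(np.sum(p / (1.0 + diff)))
    mu_i = float(np.sum(i * p))
    mu_j = float(np.sum(j * p))
    var_i = float(np.sum(p * (i - mu_i) ** 2))
    var_j = float(np.sum(p * (j - mu_j) ** 2))
    denom = math.sqrt(var_i * var_j)
    if denom == 0:
        COR, defined = 0.0, False
    else:
        COR = float((np.sum(i * j * p) - mu_i * mu_j) / denom)
        defined = True
    return TextureFeatures(CON=CON, COR=COR, ASM=ASM, INM=INM, levels_N=N,
                           offsets=tuple(offsets), cor_defined=defined)


def region_features(
    patch: np.ndarray,
    levels: int = DEFAULT_LEVELS,
) -> tuple[ColorMoments, TextureFeatures]:
    """Moments + textures for one patch."""
    cm = color_moments(patch)
    tf = texture_features(glcm(patch, levels=levels))
    return cm, tf


def _parse_mode(mode: str) -> tuple[str, str | None]:
    mode = mode.lower()
    if mode.startswith("input1"):
        parts = mode.split("_", 1)
        if len(parts) != 2 or parts[1].upper() not in INDEX_NAMES:
            raise ValueError(
                "input1 requires an index name, e.g. 'input1_NG'"
            )
        return "input1", parts[1].upper()
    if mode in INPUT_MODES:
        return mode, None
    raise ValueError(f"unknown input mode {mode!r}")


def build_feature_vectors(
    index_images: dict[str, IndexImage],
    regions: list[TreeRegion],
    morph: pd.DataFrame,
    mode: str = "input6",
    levels: int = DEFAULT_LEVELS,
) -> tuple[np.ndarray, list[str]]:
    """Assemble per-tree feature matrices for the yield model.

    Feature counts by mode: input1_<IDX> 10 (7 spectral + H, S, V);
    input2 4 (H, S, V, P); input3 30 (moments of all ten indices);
    input4 40 (textures); input5 70 (moments + textures); input6 74
    (input5 + the 4-value morphology block).  The returned column names
    encode the block ordering.
    """
    kind, idx1 = _parse_mode(mode)
    spectral_indices: tuple[str, ...]
    if kind == "input1":
        spectral_indices = (idx1,)
        want_moments, want_texture, morph_cols = True, True, ("H_m", "S_m2", "V_m3")
    elif kind == "input2":
        spectral_indices = ()
        want_moments = want_texture = False
        morph_cols = ("H_m", "S_m2", "V_m3", "P")
    elif kind == "input3":
        spectral_indices = INDEX_NAMES
        want_moments, want_texture, morph_cols = True, False, ()
    elif kind == "input4":
        spectral_indices = INDEX_NAMES
        want_moments, want_texture, morph_cols = False, True, ()
    elif kind == "input5":
        spectral_indices = INDEX_NAMES
        want_moments, want_texture, morph_cols = True, True, ()
    else:  # input6
        spectral_indices = INDEX_NAMES
        want_moments, want_texture = True, True
        morph_cols = ("H_m", "S_m2", "V_m3", "P")
    for name in spectral_indices:
        if name not in index_images:
            raise ValueError(f"index image {name} missing from index_images")
    names: list[str] = []
    for name in spectral_indices:
        if want_moments:
            names += [f"{name}_{m}" for m in MOMENT_NAMES]
        if want_texture:
            names += [f"{name}_{t}" for t in TEXTURE_NAMES]
    names += list(morph_cols)

    morph = morph.set_index(["row", "col"]) if {"row", "col"}.issubset(morph.columns) else morph
    X = np.empty((len(regions), len(names)), dtype=np.float64)
    for k, reg in enumerate(regions):
        vals: list[float] = []
        if spectral_indices:
            if reg.pixel_window is None:
                raise ValueError("regions lack pixel windows; spectral features need them")
            r0, r1, c0, c1 = reg.pixel_window
            for name in spectral_indices:
                patch = index_images[name].gray[r0:r1, c0:c1]
                if patch.size == 0:
                    block = [np.nan] * (3 * want_moments + 4 * want_texture)
                    vals += block
                    continue
                if want_moments:
                    cm = color_moments(patch)
                    vals += [cm.mu, cm.sigma, cm.s]
                if want_texture:
                    tf = texture_features(glcm(patch, levels=levels))
                    vals += [tf.CON, tf.COR, tf.ASM, tf.INM]
        if morph_cols:
            row = morph.loc[(reg.row_index, reg.col_index)]
            vals += [float(row[c]) for c in morph_cols]
        X[k] = vals
    return X, names
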