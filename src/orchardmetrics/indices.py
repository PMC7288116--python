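"""Vegetation indices from multispectral reflectance bands.

Ten standard indices are computed pixel-wise from the four Parrot
Sequoia-style bands (GRE, RED, REG, NIR; reflectance in [0, 1]) and
rescaled to 0-255 grayscale for the projection-based segmentation stage.
The REG (red-edge) band is carried in the stack for completeness but none
of the ten formulas uses it.

Note on segmentation semantics: NG = GRE/(NIR+RED+GRE) is *soil-bright* —
vegetation has high NIR which depresses NG — which is what makes the
soil strips between tree rows grayscale maxima of the projection profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical index ordering used throughout (feature blocks, CLI, reports).
INDEX_NAMES = ("NG", "NR", "NDVI", "GNDVI", "DVI", "CIG", "OSAVI", "RDVI", "NLI", "WDRVI")


@dataclass
class BandStack:
    """Four co-registered single-band reflectance rasters plus geometry.

    Parameters
    ----------
    gre, red, reg, nir : ndarray
        2-D reflectance rasters in [0, 1], identical shapes.
    gsd : float
        Ground sampling distance in cm/px.
    origin_xy : tuple of float
        World coordinates (metres) of the south-west corner of the raster.
    band_scale : int
        Divisor used when the bands are file-encoded as 16-bit integers.
    """

    gre: np.ndarray
    red: np.ndarray
    reg: np.ndarray
    nir: np.ndarray
    gsd: float
    origin_xy: tuple[float, float] = (0.0, 0.0)
    band_scale: int = 10000

    def __post_init__(self) -> None:
        shapes = {b.shape for b in (self.gre, self.red, self.reg, self.nir)}
        if len(shapes) != 1:
            raise ValueError(f"band rasters must share one shape, got {shapes}")
        if self.gsd <= 0:
            raise ValueError("gsd must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.gre.shape

    @property
    def gsd_m(self) -> float:
        """Pixel size in metres."""
        return self.gsd / 100.0

    @property
    def extent_xy(self) -> tuple[float, float]:
        """Geographic raster extent (x length, y width) in metres."""
        m, n = self.shape
        return n * self.gsd_m, m * self.gsd_m


@dataclass
class IndexImage:
    """One vegetation index as float raster plus its 0-255 grayscale twin."""

    name: str
    values: np.ndarray
    gray: np.ndarray
    gsd: float
    invalid_mask: np.ndarray = field(default=None, repr=False)

    @property
    def n_invalid(self) -> int:
        return 0 if self.invalid_mask is None else int(self.invalid_mask.sum())


def _safe_divide(num: np.ndarray, den: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-wise num/den with zero denominators mapped to 0 and masked."""
    mask = den == 0
    out = np.zeros_like(num, dtype=np.float64)
    np.divide(num, den, out=out, where=~mask)
    return out, mask


def _formula(name: str, gre: np.ndarray, red: np.ndarray, nir: np.ndarray):
    if name == "NG":
        return _safe_divide(gre, nir + red + gre)
    if name == "NR":
        return _safe_divide(red, nir + red + gre)
    if name == "NDVI":
        return _safe_divide(nir - red, nir + red)
    if name == "GNDVI":
        return _safe_divide(nir - gre, nir + gre)
    if name == "DVI":
        return nir - red, np.zeros(nir.shape, dtype=bool)
    if name == "CIG":
        v, mask = _safe_divide(nir, gre)
        v = np.where(mask, 0.0, v - 1.0)
        return v, mask
    if name == "OSAVI":
        return _safe_divide(1.16 * (nir - red), nir + red + 0.16)
    if name == "RDVI":
        # (NIR - RED)/sqrt(NIR + RED), the standard renormalized-DVI form.
        s = nir + red
        v, mask = _safe_divide(nir - red, np.sqrt(np.maximum(s, 0.0)))
        return v, mask
    if name == "NLI":
        return _safe_divide(nir**2 - red, nir**2 + red)
    if name == "WDRVI":
        return _safe_divide(0.2 * nir - red, 0.2 * nir + red)
    raise ValueError(f"unknown vegetation index {name!r}; expected one of {INDEX_NAMES}")


def to_grayscale(values: np.ndarray) -> np.ndarray:
    """Min-max rescale a float raster to integer 0-255.

    gray = round(255 * (v - v_min)/(v_max - v_min)), with rounding half away
    from zero; a constant raster maps to all zeros.
    """
    values = np.asarray(values, dtype=np.float64)
    vmin = values.min()
    vmax = values.max()
    if vmax == vmin:
        return np.zeros(values.shape, dtype=np.uint8)
    scaled = 255.0 * (values - vmin) / (vmax - vmin)
    return np.floor(scaled + 0.5).astype(np.uint8)


def compute_index(bands: BandStack, name: str) -> IndexImage:
    """Compute one vegetation index image from a band stack.

    Zero-denominator pixels (non-physical for real reflectance scenes) get
    value 0 and are recorded in ``invalid_mask``.
    """
    name = name.upper()
    gre = np.asarray(bands.gre, dtype=np.float64)
    red = np.asarray(bands.red, dtype=np.float64)
    nir = np.asarray(bands.nir, dtype=np.float64)
    values, mask = _formula(name, gre, red, nir)
    return IndexImage(
        name=name,
        values=values,
        gray=to_grayscale(values),
        gsd=bands.gsd,
        invalid_mask=mask,
    )


def compute_all_indices(bands: BandStack, names=INDEX_NAMES) -> dict[str, IndexImage]:
    """Compute several index images keyed by name."""
    return {n.upper(): compute_index(bands, n) for n in names}
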