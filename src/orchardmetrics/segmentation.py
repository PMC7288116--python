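"""Row/column detection by cumulative grayscale projection (RCGP).

The detector projects a vegetation-index grayscale image onto each axis by
summing pixel values (the cumulative grayscale profile), smooths the
profile with a Gaussian kernel of bandwidth ``h`` pixels, and takes local
maxima of the smoothed profile as segmentation positions: for a
soil-bright index such as NG, the bare-soil strips between tree rows (and
between trees within a row) are grayscale maxima, so consecutive peaks
bracket exactly one tree.  Rows are detected on the whole image's Y
profile; columns are detected independently inside each row band.  Pixel
boundary positions are converted to point-cloud metre coordinates by pure
proportional scaling, which unifies the 2-D raster and 3-D cloud
segmentation.

Conventions (stated so point counts are reproducible): pixel row 0 is the
maximum-Y edge of the scene (north-up orthophoto); boundary arrays are
strictly increasing with first/last entries at the image edges (0 and the
full extent); cells are half-open [lo, hi).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .indices import IndexImage
from .synthetic import PointCloud, TreeTruth

logger = logging.getLogger(__name__)

#: Canopy-bright indices whose profiles must be inverted so that the
#: soil strips between trees are again profile maxima.
_CANOPY_BRIGHT = {"NDVI", "GNDVI", "DVI", "CIG", "OSAVI", "RDVI", "NLI", "WDRVI"}


@dataclass
class GrayProfile:
    """Cumulative grayscale projection of an index image onto one axis."""

    axis: str  # 'row' or 'column'
    raw: np.ndarray
    smoothed: np.ndarray | None = None
    bandwidth_h: float | None = None
    kernel: str = "gaussian"


@dataclass
class GridSegmentation:
    """Row and per-row column boundaries in pixel and metre coordinates.

    ``L_2D``/``C_2D`` are pixel positions on the index image; ``L_3D``/
    ``C_3D`` their metre twins on the point cloud; ``m_*`` are the Y-axis
    sizes (image rows / cloud width) and ``n_*`` the X-axis sizes.
    """

    L_2D: np.ndarray | None
    C_2D: list[np.ndarray] | None
    m_2D: int
    n_2D: int
    m_3D: float
    n_3D: float
    L_3D: np.ndarray | None = None
    C_3D: list[np.ndarray] | None = None

    @property
    def n_row_bands(self) -> int:
        L = self.L_3D if self.L_3D is not None else self.L_2D
        return len(L) - 1


@dataclass
class TreeRegion:
    """One rectangular grid cell with its pixel window and point subset."""

    row_index: int
    col_index: int
    pixel_window: tuple[int, int, int, int] | None  # (r0, r1, c0, c1), half-open
    metre_window: tuple[float, float, float, float]  # (x0, x1, y0, y1), half-open
    points: np.ndarray = field(default=None, repr=False)
    P: int = 0
    empty: bool = False


@dataclass
class DetectionScore:
    """Detection accuracy C = NC/N x 100 and error rate E = NE/N x 100."""

    NC: int
    NE: int
    N: int

    @property
    def C(self) -> float:
        return 100.0 * self.NC / self.N if self.N else 0.0

    @property
    def E(self) -> float:
        return 100.0 * self.NE / self.N if self.N else 0.0


def project_profile(gray: np.ndarray, axis: str) -> GrayProfile:
    """Cumulative grayscale profile: sum of the image along the other axis."""
    gray = np.asarray(gray)
    if gray.size == 0:
        raise ValueError("cannot project an empty image")
    if axis == "row":
        raw = gray.sum(axis=1, dtype=np.float64)
    elif axis == "column":
        raw = gray.sum(axis=0, dtype=np.float64)
    else:
        raise ValueError(f"axis must be 'row' or 'column', got {axis!r}")
    return GrayProfile(axis=axis, raw=raw)


def smooth_profile(profile: GrayProfile, h: float) -> GrayProfile:
    """Gaussian-kernel smoothing of the positional profile, bandwidth ``h`` px.

    Reflect padding at the ends; the symmetric kernel plus symmetric
    padding preserves total profile mass exactly.
    """
    if h <= 0:
        raise ValueError("bandwidth h must be > 0")
    smoothed = gaussian_filter1d(profile.raw.astype(np.float64), sigma=h, mode="reflect")
    return replace(profile, smoothed=smoothed, bandwidth_h=float(h))


def estimate_spacing_px(raw: np.ndarray) -> float:
    """Dominant period of a projection profile via the FFT magnitude peak."""
    x = np.asarray(raw, dtype=np.float64)
    x = x - x.mean()
    spec = np.abs(np.fft.rfft(x))
    if len(spec) < 2:
        return float(len(x))
    k = int(np.argmax(spec[1:])) + 1
    return len(x) / k


def detect_boundaries(
    profile: GrayProfile,
    min_prominence: float | None = None,
    min_separation_px: float | None = None,
    expected_spacing_px: float | None = None,
    subdivide_wide_cells: bool = True,
    wide_cell_factor: float = 1.5,
) -> np.ndarray:
    """Local maxima of the smoothed profile as segmentation positions.

    Interior boundaries are peaks passing prominence (default 5% of the
    smoothed profile's dynamic range) and separation (default half the
    expected spacing) filters; the image edges are appended so consecutive
    boundaries always bracket one cell.  Returns strictly increasing
    integer positions ``[0, ..., len(profile)]``.

    A standardized orchard has a constant planting interval, so a cell
    between two *detected* interior boundaries that is wider than
    ``wide_cell_factor`` times the expected spacing must span more than
    one planting position — typically a dead tree whose canopy dip is too
    faint to anchor a gap peak.  With ``subdivide_wide_cells`` such cells
    get evenly spaced boundaries inserted (rounded to the implied number
    of planting positions).  Edge cells are exempt: the field margins are
    legitimately wide.
    """
    if profile.smoothed is None:
        raise ValueError("profile must be smoothed before boundary detection")
    y = profile.smoothed
    n = len(y)
    if expected_spacing_px is None:
        expected_spacing_px = estimate_spacing_px(profile.raw)
    if min_separation_px is None:
        min_separation_px = 0.5 * expected_spacing_px
    if min_prominence is None:
        rng = float(y.max() - y.min())
        min_prominence = 0.05 * rng
    peaks, _ = find_peaks(
        y,
        distance=max(int(round(min_separation_px)), 1),
        prominence=min_prominence if min_prominence > 0 else None,
    )
    if len(peaks) == 0:
        logger.warning("no interior profile maxima found; returning image edges only")
    if subdivide_wide_cells and len(peaks) >= 2:
        extra = []
        for lo, hi in zip(peaks[:-1], peaks[1:]):
            width = hi - lo
            if width > wide_cell_factor * expected_spacing_px:
                k = int(round(width / expected_spacing_px))
                extra.extend(lo + width * np.arange(1, k) / k)
        if extra:
            peaks = np.concatenate([peaks, np.round(extra)])
    bounds = np.unique(np.concatenate(([0], peaks, [n])))
    return bounds.astype(np.int64)


def convert_to_3d(seg: GridSegmentation, cloud_extent: tuple[float, float] | None = None) -> GridSegmentation:
    """Convert pixel boundaries to point-cloud metre coordinates.

    L_3D(i) = |L_2D(i)| * m_3D / m_2D and likewise for columns — pure
    proportional scaling between raster size and cloud extent.  The
    north-up row-orientation flip is applied later when cells are mapped
    to point subsets, not here.
    """
    if cloud_extent is not None:
        seg = replace(seg, n_3D=float(cloud_extent[0]), m_3D=float(cloud_extent[1]))
    if seg.m_2D <= 0 or seg.n_2D <= 0:
        raise ValueError("image dimensions must be positive for 2D->3D conversion")
    L_3D = np.abs(np.asarray(seg.L_2D, dtype=np.float64)) * seg.m_3D / seg.m_2D
    C_3D = [
        np.abs(np.asarray(c, dtype=np.float64)) * seg.n_3D / seg.n_2D for c in seg.C_2D
    ]
    return replace(seg, L_3D=L_3D, C_3D=C_3D)


def _detect_axis(gray: np.ndarray, axis: str, spacing_px: float | None,
                 bandwidth: float | None, bandwidth_frac: float,
                 separation_frac: float, prominence_frac: float) -> np.ndarray:
    prof = project_profile(gray, axis)
    if spacing_px is None:
        spacing_px = estimate_spacing_px(prof.raw)
    h = bandwidth if bandwidth is not None else max(bandwidth_frac * spacing_px, 1.0)
    prof = smooth_profile(prof, h)
    rng = float(prof.smoothed.max() - prof.smoothed.min())
    return detect_boundaries(
        prof,
        min_prominence=prominence_frac * rng,
        min_separation_px=separation_frac * spacing_px,
        expected_spacing_px=spacing_px,
    )


#: Detector defaults.  The smoothing bandwidth (an eighth of the expected
#: spacing) and the relative prominence floor (2% of the smoothed profile's
#: dynamic range) are set so that the faint dips of small-radius and dead
#: canopies survive smoothing while reflectance-noise wiggles do not.
DEFAULT_BANDWIDTH_FRAC = 0.125
DEFAULT_PROMINENCE_FRAC = 0.02
DEFAULT_SEPARATION_FRAC = 0.5


def segment_image(
    index_image: IndexImage,
    row_spacing_px: float | None = None,
    plant_spacing_px: float | None = None,
    mode: str = "auto",
    bandwidth: float | None = None,
    bandwidth_frac: float = DEFAULT_BANDWIDTH_FRAC,
    separation_frac: float = DEFAULT_SEPARATION_FRAC,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
) -> GridSegmentation:
    """RCGP detection on a grayscale index image.

    Rows are detected on the full-image Y profile; column boundaries are
    then detected independently within each row band.  ``mode`` is
    ``'peaks'`` (soil-bright index: NG, NR), ``'invert'`` (canopy-bright:
    NDVI family — minima become boundaries), or ``'auto'`` which picks by
    index name.
    """
    if mode == "auto":
        mode = "invert" if index_image.name in _CANOPY_BRIGHT else "peaks"
    if mode not in ("peaks", "invert"):
        raise ValueError(f"mode must be 'peaks', 'invert' or 'auto', got {mode!r}")
    gray = index_image.gray.astype(np.int64)
    if mode == "invert":
        gray = 255 - gray
    m, n = gray.shape
    L_2D = _detect_axis(gray, "row", row_spacing_px, bandwidth,
                        bandwidth_frac, separation_frac, prominence_frac)
    C_2D = []
    for i in range(len(L_2D) - 1):
        band = gray[L_2D[i]:L_2D[i + 1], :]
        C_2D.append(_detect_axis(band, "column", plant_spacing_px, bandwidth,
                                 bandwidth_frac, separation_frac, prominence_frac))
    return GridSegmentation(L_2D=L_2D, C_2D=C_2D, m_2D=m, n_2D=n, m_3D=0.0, n_3D=0.0)


def extract_regions(seg: GridSegmentation, cloud: PointCloud | None) -> list[TreeRegion]:
    """Cut the scene into rectangular tree regions and attach point subsets.

    Cell [L(i), L(i+1)) x [C{i}(j), C{i}(j+1)) in metre coordinates; the
    row interval is flipped to world Y (pixel row 0 = max Y).  Points
    outside the extent are dropped; within it the cells partition the
    cloud, so cell counts P_ij sum to the in-extent cloud size.
    """
    if seg.L_3D is None or seg.C_3D is None:
        raise ValueError("segmentation lacks metre coordinates; run convert_to_3d first")
    pts = cloud.points if cloud is not None else np.empty((0, 3))
    # Row band for each point from its flipped Y coordinate.
    yq = seg.m_3D - pts[:, 1] if len(pts) else np.empty(0)
    L = np.asarray(seg.L_3D)
    in_y = (yq >= L[0]) & (yq < L[-1])
    band_of = np.searchsorted(L, yq, side="right") - 1
    regions: list[TreeRegion] = []
    for i in range(len(L) - 1):
        C = np.asarray(seg.C_3D[i])
        sel = in_y & (band_of == i)
        px = pts[sel]
        in_x = (px[:, 0] >= C[0]) & (px[:, 0] < C[-1])
        px = px[in_x]
        cell_of = np.searchsorted(C, px[:, 0], side="right") - 1
        y_hi = seg.m_3D - L[i]
        y_lo = seg.m_3D - L[i + 1]
        for j in range(len(C) - 1):
            cell_pts = px[cell_of == j]
            if seg.L_2D is not None and seg.C_2D is not None:
                pw = (int(seg.L_2D[i]), int(seg.L_2D[i + 1]),
                      int(seg.C_2D[i][j]), int(seg.C_2D[i][j + 1]))
            else:
                pw = None
            regions.append(
                TreeRegion(
                    row_index=i,
                    col_index=j,
                    pixel_window=pw,
                    metre_window=(float(C[j]), float(C[j + 1]), float(y_lo), float(y_hi)),
                    points=cell_pts,
                    P=len(cell_pts),
                    empty=len(cell_pts) == 0,
                )
            )
    return regions


def segment_scene(
    index_image: IndexImage,
    cloud: PointCloud | None,
    extent_xy: tuple[float, float],
    row_spacing_px: float | None = None,
    plant_spacing_px: float | None = None,
    mode: str = "auto",
    **detect_kwargs,
) -> tuple[GridSegmentation, list[TreeRegion]]:
    """Full RCGP segmentation: detect boundaries, convert, cut regions.

    ``extent_xy`` is the scene extent (x length, y width) in metres; it
    must agree with the cloud's bounding box to within 5%.
    """
    n_3D, m_3D = float(extent_xy[0]), float(extent_xy[1])
    if cloud is not None and len(cloud):
        bb_min = cloud.points.min(axis=0)
        bb_max = cloud.points.max(axis=0)
        tol_x, tol_y = 0.05 * n_3D, 0.05 * m_3D
        if (bb_min[0] < -tol_x or bb_max[0] > n_3D + tol_x
                or bb_min[1] < -tol_y or bb_max[1] > m_3D + tol_y):
            raise ValueError("cloud bounding box disagrees with the stated extent by > 5%")
    seg = segment_image(
        index_image,
        row_spacing_px=row_spacing_px,
        plant_spacing_px=plant_spacing_px,
        mode=mode,
        **detect_kwargs,
    )
    seg = convert_to_3d(seg, cloud_extent=(n_3D, m_3D))
    regions = extract_regions(seg, cloud)
    return seg, regions


def _center_in(window: tuple[float, float, float, float], xy: tuple[float, float]) -> bool:
    x0, x1, y0, y1 = window
    return x0 <= xy[0] < x1 and y0 <= xy[1] < y1


def score_detection(regions: list[TreeRegion], trees: list[TreeTruth]) -> DetectionScore:
    """Score grid cells against truth tree centres.

    A region is correct when it contains exactly one truth centre (dead or
    live); regions with zero or multiple centres count as erroneous
    recognitions.
    """
    centers = [t.center_xy for t in trees]
    NC = NE = 0
    for reg in regions:
        k = sum(_center_in(reg.metre_window, c) for c in centers)
        if k == 1:
            NC += 1
        else:
            NE += 1
    return DetectionScore(NC=NC, NE=NE, N=len(regions))


def score_row_bands(seg: GridSegmentation, trees: list[TreeTruth]) -> DetectionScore:
    """Score detected row bands: a band is correct when it contains all of
    exactly one truth row's tree centres and nothing else."""
    if seg.L_3D is None:
        raise ValueError("segmentation lacks metre coordinates")
    L = np.asarray(seg.L_3D)
    row_sizes: dict[int, int] = {}
    for t in trees:
        row_sizes[t.row_index] = row_sizes.get(t.row_index, 0) + 1
    NC = NE = 0
    for i in range(len(L) - 1):
        y_lo, y_hi = seg.m_3D - L[i + 1], seg.m_3D - L[i]
        inside = [t.row_index for t in trees if y_lo <= t.center_xy[1] < y_hi]
        rows = set(inside)
        if len(rows) == 1 and len(inside) == row_sizes[next(iter(rows))]:
            NC += 1
        else:
            NE += 1
    return DetectionScore(NC=NC, NE=NE, N=len(L) - 1)
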