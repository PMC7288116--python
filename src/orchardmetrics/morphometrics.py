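"""Per-tree canopy morphometrics from segmented point clouds.

Three quantities per tree region: canopy height H = Zmax - Zmin (ground
returns in the region anchor Zmin at the soil surface, so H is total tree
height); projected area S_XOY as the shoelace area of the convex hull of
the XOY-projected points; and the circumscribed-ellipsoid volume
V = (2/3) (H - trunk_height) S_XOY, i.e. a spheroid with vertical
semi-axis (H - trunk)/2 and horizontal radius taken from the equivalent
circle of the hull area.  The default trunk height is 0.6 m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .segmentation import TreeRegion

DEFAULT_TRUNK_HEIGHT = 0.6


@dataclass
class Morphometrics:
    H: float
    S_XOY: float
    V: float
    hull: np.ndarray | None
    trunk_height: float = DEFAULT_TRUNK_HEIGHT
    flags: tuple[str, ...] = ()


def tree_height(region: TreeRegion | np.ndarray) -> tuple[float, bool]:
    """Canopy height H = Zmax - Zmin over the region's points.

    Returns (H, ok).  Fewer than two points leave the height undefined
    (H = nan, ok False); it is never silently zeroed.
    """
    pts = region.points if isinstance(region, TreeRegion) else np.asarray(region)
    if pts is None or len(pts) < 2:
        return float("nan"), False
    z = pts[:, 2]
    return float(z.max() - z.min()), True


def shoelace_area(vertices: np.ndarray) -> float:
    """Polygon area by the shoelace formula over ordered vertices,
    closing the ring (x_{N+1} = x_1); counter-clockwise order gives a
    positive value."""
    v = np.asarray(vertices, dtype=np.float64)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - y * np.roll(x, -1)))


def hull_area(region: TreeRegion | np.ndarray) -> tuple[float, np.ndarray | None]:
    """Convex hull of the XOY projection and its shoelace area.

    Returns (S_XOY, hull vertices in counter-clockwise order).  Degenerate
    input (fewer than 3 points, or collinear) yields (0.0, None).
    """
    pts = region.points if isinstance(region, TreeRegion) else np.asarray(region)
    if pts is None or len(pts) < 3:
        return 0.0, None
    xy = np.asarray(pts, dtype=np.float64)[:, :2]
    try:
        hull = ConvexHull(xy)
    except QhullError:
        return 0.0, None
    verts = xy[hull.vertices]  # CCW for 2-D hulls
    return shoelace_area(verts), verts


def ellipsoid_volume(H: float, S_XOY: float, trunk_height: float = DEFAULT_TRUNK_HEIGHT) -> float:
    """Circumscribed-ellipsoid canopy volume.

    V = (4/3) pi * ((H - trunk)/2) * (S_XOY / pi) = (2/3)(H - trunk) S_XOY.
    A height at or below the trunk gives a zero vertical semi-axis, hence
    V = 0.
    """
    if S_XOY < 0:
        raise ValueError("S_XOY must be >= 0")
    if math.isnan(H) or math.isnan(S_XOY):
        return float("nan")
    h_canopy = max(H - trunk_height, 0.0)
    return (2.0 / 3.0) * h_canopy * S_XOY


#: Ground returns sit at z ~ 0 (plus noise) while live canopies start at
#: the trunk top (0.6 m); points below this cutoff are treated as ground:
#: they anchor Zmin for the height but are excluded from the projected
#: hull, which describes the canopy outline only.
DEFAULT_CANOPY_Z_CUTOFF = 0.3


def measure_region(
    region: TreeRegion,
    trunk_height: float = DEFAULT_TRUNK_HEIGHT,
    canopy_z_cutoff: float = DEFAULT_CANOPY_Z_CUTOFF,
) -> Morphometrics:
    """All three morphometrics for one region, with degeneracy flags."""
    flags = []
    H, ok = tree_height(region)
    if not ok:
        flags.append("height_undefined")
    pts = region.points
    canopy_pts = pts[pts[:, 2] > canopy_z_cutoff] if pts is not None and len(pts) else pts
    S, hull = hull_area(canopy_pts)
    if hull is None:
        flags.append("area_degenerate")
        if region.P >= 3:
            flags.append("collinear")
    if ok and H < trunk_height:
        flags.append("below_trunk")
    V = ellipsoid_volume(H, S, trunk_height) if ok else float("nan")
    if region.empty or region.P == 0:
        flags.append("empty")
    return Morphometrics(H=H, S_XOY=S, V=V, hull=hull, trunk_height=trunk_height,
                         flags=tuple(flags))


def morph_table(
    regions: list[TreeRegion],
    trunk_height: float = DEFAULT_TRUNK_HEIGHT,
    canopy_z_cutoff: float = DEFAULT_CANOPY_Z_CUTOFF,
) -> pd.DataFrame:
    """One row of (H, S_XOY, V, P, flags) per tree region.

    Missing values propagate as NaN so downstream consumers can exclude or
    impute flagged trees explicitly.
    """
    rows = []
    for k, reg in enumerate(regions):
        m = measure_region(reg, trunk_height, canopy_z_cutoff)
        rows.append(
            {
                "tree_id": k,
                "row": reg.row_index,
                "col": reg.col_index,
                "H_m": m.H,
                "S_m2": m.S_XOY,
                "V_m3": m.V,
                "P": reg.P,
                "flags": ";".join(m.flags),
            }
        )
    return pd.DataFrame(rows)
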