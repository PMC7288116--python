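"""Synthetic orchard scene generator.

Emulates the study system: a modern standardized apple orchard laid out on
a regular grid (rows x columns of roughly ellipsoidal canopies over bare
soil, with a few dead trees), imaged by a nadir UAV multispectral camera
and reconstructed by structure-from-motion.  The generator produces the
three artifacts the measurement pipeline consumes —

* four co-registered reflectance band rasters (GRE, RED, REG, NIR) at a
  chosen ground sampling distance (GSD, cm/px),
* a 3-D point cloud whose volumetric canopy density follows the reference-campaign
  GSD-to-density calibration table,
* per-tree ground truth (position, height, radius, dead flag, yield),

with soil/canopy spectral contrast such that the NG index is brighter over
soil than over canopy (the property the projection segmenter relies on).

Default field geometry follows the reference orchard: a 140 m x 25 m block
of five rows (5 m row spacing, 4 m plant spacing) carrying 30-34 trees per
row, 160 trees total with 8 expected dead positions, and 0.6 m trunks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .indices import BandStack

#: Volumetric canopy point densities (points/m^3) by GSD (cm/px), the
#: field calibration the generator emulates.
DENSITY_BY_GSD = {2.13: 364.77, 3.31: 75.55, 4.39: 32.01, 5.43: 17.22, 6.69: 8.65}

#: Soil and live-canopy baseline reflectances per band.
SOIL_REFLECTANCE = {"gre": 0.18, "red": 0.22, "reg": 0.28, "nir": 0.30}
CANOPY_REFLECTANCE = {"gre": 0.10, "red": 0.06, "reg": 0.35, "nir": 0.55}

_MAX_RASTER_PIXELS = 200_000_000


@dataclass
class OrchardLayout:
    """Planting plan of a gridded orchard block."""

    n_rows: int = 5
    trees_per_row: tuple[int, ...] = (30, 31, 32, 33, 34)
    row_spacing: float = 5.0
    plant_spacing: float = 4.0
    field_length: float = 140.0
    field_width: float = 25.0
    dead_fraction: float = 8 / 160
    trunk_height: float = 0.6

    def __post_init__(self) -> None:
        self.trees_per_row = tuple(int(t) for t in self.trees_per_row)
        if self.n_rows < 1:
            raise ValueError("n_rows must be >= 1")
        if len(self.trees_per_row) != self.n_rows:
            raise ValueError(
                f"trees_per_row has {len(self.trees_per_row)} entries for n_rows={self.n_rows}"
            )
        if min(self.trees_per_row) < 1:
            raise ValueError("trees_per_row entries must be >= 1")
        for name in ("row_spacing", "plant_spacing", "field_length", "field_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.dead_fraction < 1:
            raise ValueError("dead_fraction must be in [0, 1)")
        # The grid plus a half-spacing margin must fit inside the field.
        if max(self.trees_per_row) * self.plant_spacing > self.field_length + 1e-9:
            raise ValueError("field_length too small for trees_per_row at plant_spacing")
        if self.n_rows * self.row_spacing > self.field_width + 1e-9:
            raise ValueError("field_width too small for n_rows at row_spacing")

    @property
    def n_trees(self) -> int:
        return sum(self.trees_per_row)

    def row_center_y(self, i: int) -> float:
        y0 = (self.field_width - self.n_rows * self.row_spacing) / 2.0
        return y0 + (i + 0.5) * self.row_spacing


@dataclass
class TreeTruth:
    """Ground truth for one grid position."""

    row_index: int
    col_index: int
    center_xy: tuple[float, float]
    trunk_height: float = 0.6
    canopy_height_total: float = 2.75  # total tree height H, metres
    canopy_radius: float = 1.3
    is_dead: bool = False
    yield_kg: float = 0.0
    vigor: float = 1.0  # scales canopy NIR; links spectra to the yield signal

    @property
    def ellipsoid_volume(self) -> float:
        """Truth canopy volume: spheroid of semi-axes (r, r, (H - trunk)/2)."""
        c = max(self.canopy_height_total - self.trunk_height, 0.0) / 2.0
        return (4.0 / 3.0) * math.pi * self.canopy_radius**2 * c

    @property
    def disc_area(self) -> float:
        return math.pi * self.canopy_radius**2

    def canopy_reflectance(self, band: str) -> float:
        """Per-tree reflectance: NIR scales with vigor; dead trees are a
        weak soil/canopy blend (trunk plus few leaves)."""
        base = CANOPY_REFLECTANCE[band]
        if band == "nir":
            base = min(base * self.vigor, 0.95)
        if self.is_dead:
            return 0.5 * SOIL_REFLECTANCE[band] + 0.5 * base
        return base

    @property
    def ng_value(self) -> float:
        """Noise-free NG of this tree's canopy reflectance (greenness proxy)."""
        g = self.canopy_reflectance("gre")
        r = self.canopy_reflectance("red")
        n = self.canopy_reflectance("nir")
        return g / (n + r + g)


@dataclass
class PointCloud:
    """Bare 3-D point container (x, y, z in metres)."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        if self.points.size and self.points.shape[1] != 3:
            raise ValueError("points must have shape (N, 3)")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class SceneBundle:
    """A complete synthetic scene: layout + truth + rasters + cloud."""

    layout: OrchardLayout
    trees: list[TreeTruth]
    bands: BandStack | None
    cloud: PointCloud | None
    seed: int


def generate_layout(
    layout: OrchardLayout,
    seed: int,
    height_range: tuple[float, float] = (2.0, 3.5),
    radius_range: tuple[float, float] = (0.8, 1.8),
    dead_height_range: tuple[float, float] = (0.8, 1.4),
    dead_radius_range: tuple[float, float] = (0.1, 0.3),
    center_jitter: float = 0.3,
    vigor_range: tuple[float, float] = (0.8, 1.2),
    yield_noise_sd: float | None = None,
) -> list[TreeTruth]:
    """Draw per-tree truth for every grid position.

    Tree centres sit on the regular grid with uniform jitter of
    +/- ``center_jitter`` m (so segmentation is not trivially exact); canopy
    dimensions are uniform draws; dead positions are i.i.d. Bernoulli with
    probability ``layout.dead_fraction``.  Yields are then assigned by
    :func:`assign_yields`.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA11]))
    trees: list[TreeTruth] = []
    for i in range(layout.n_rows):
        n_i = layout.trees_per_row[i]
        x0 = (layout.field_length - (n_i - 1) * layout.plant_spacing) / 2.0
        yc = layout.row_center_y(i)
        for j in range(n_i):
            jitter = rng.uniform(-center_jitter, center_jitter, size=2)
            is_dead = bool(rng.random() < layout.dead_fraction)
            if is_dead:
                height = rng.uniform(*dead_height_range)
                radius = rng.uniform(*dead_radius_range)
            else:
                height = rng.uniform(*height_range)
                radius = rng.uniform(*radius_range)
            trees.append(
                TreeTruth(
                    row_index=i,
                    col_index=j,
                    center_xy=(x0 + j * layout.plant_spacing + jitter[0], yc + jitter[1]),
                    trunk_height=layout.trunk_height,
                    canopy_height_total=height,
                    canopy_radius=radius,
                    is_dead=is_dead,
                    vigor=rng.uniform(*vigor_range),
                )
            )
    return assign_yields(trees, noise_sd=yield_noise_sd, seed=seed)


def yield_signal(tree: TreeTruth, b0: float = 45.0, b1: float = 6.0, b2: float = -100.0) -> float:
    """Deterministic yield signal of a live tree (kg).

    Yield grows with canopy volume and with greenness (lower NG means more
    vigorous, NIR-rich foliage, hence the negative NG coefficient).  With
    the default canopy dimension ranges the population mean is about 80 kg.
    """
    return b0 + b1 * tree.ellipsoid_volume + b2 * tree.ng_value


def assign_yields(
    trees: list[TreeTruth],
    noise_sd: float | None = None,
    seed: int = 0,
    target_r2: float = 0.90,
    b0: float = 45.0,
    b1: float = 6.0,
    b2: float = -100.0,
) -> list[TreeTruth]:
    """Assign per-tree yields: signal + Gaussian noise, clipped at zero.

    When ``noise_sd`` is None it is calibrated from the live-tree signal so
    that the population R^2 between noise-free signal and yield is
    ``target_r2`` (default 0.90): sd_noise = sd_signal * sqrt((1-R2)/R2).
    Dead trees always get yield 0.
    """
    if noise_sd is not None and noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x71E1D]))
    live = [t for t in trees if not t.is_dead]
    signals = np.array([yield_signal(t, b0, b1, b2) for t in live])
    if noise_sd is None:
        sd_signal = float(np.std(signals)) if len(signals) > 1 else 0.0
        noise_sd = sd_signal * math.sqrt((1.0 - target_r2) / target_r2)
    out: list[TreeTruth] = []
    k = 0
    for t in trees:
        if t.is_dead:
            out.append(replace(t, yield_kg=0.0))
        else:
            y = signals[k] + rng.normal(0.0, noise_sd) if noise_sd > 0 else signals[k]
            out.append(replace(t, yield_kg=float(max(y, 0.0))))
            k += 1
    return out


def render_bands(
    trees: list[TreeTruth],
    layout: OrchardLayout,
    gsd: float = 2.13,
    noise_sd_reflectance: float = 0.01,
    seed: int = 0,
) -> BandStack:
    """Render the four reflectance band rasters at the given GSD.

    Rasters are ceil(width*100/gsd) rows x ceil(length*100/gsd) columns,
    north-up (pixel row 0 is the maximum-Y edge).  Each band starts at the
    soil baseline; every tree paints an anti-aliased canopy disc of its own
    reflectance; i.i.d. Gaussian reflectance noise is added and values are
    clipped to [0, 1].
    """
    if gsd <= 0:
        raise ValueError("gsd must be > 0")
    gsd_m = gsd / 100.0
    m = math.ceil(layout.field_width * 100.0 / gsd)
    n = math.ceil(layout.field_length * 100.0 / gsd)
    if m * n > _MAX_RASTER_PIXELS:
        raise ValueError(f"raster {m}x{n} exceeds the {_MAX_RASTER_PIXELS}-pixel cap")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xBA2D]))
    bands = {}
    # Pixel-centre world coordinates along each axis.
    xs = (np.arange(n) + 0.5) * gsd_m
    ys = layout.field_width - (np.arange(m) + 0.5) * gsd_m
    # Per-tree alpha discs are identical across bands; paint all four at once.
    rasters = {
        b: np.full((m, n), SOIL_REFLECTANCE[b], dtype=np.float32) for b in SOIL_REFLECTANCE
    }
    for t in trees:
        r = t.canopy_radius
        if r <= 0:
            continue
        cx, cy = t.center_xy
        j0 = max(int((cx - r) / gsd_m) - 1, 0)
        j1 = min(int((cx + r) / gsd_m) + 2, n)
        i0 = max(int((layout.field_width - cy - r) / gsd_m) - 1, 0)
        i1 = min(int((layout.field_width - cy + r) / gsd_m) + 2, m)
        if j0 >= j1 or i0 >= i1:
            continue
        dx = xs[j0:j1] - cx
        dy = ys[i0:i1] - cy
        d = np.sqrt(dx[None, :] ** 2 + dy[:, None] ** 2)
        # One-pixel anti-aliased edge: alpha ramps 1 -> 0 across the rim.
        alpha = np.clip((r - d) / gsd_m + 0.5, 0.0, 1.0).astype(np.float32)
        for b, raster in rasters.items():
            win = raster[i0:i1, j0:j1]
            win += alpha * (np.float32(t.canopy_reflectance(b)) - win)
    for b, raster in rasters.items():
        if noise_sd_reflectance > 0:
            raster += rng.standard_normal((m, n), dtype=np.float32) * np.float32(
                noise_sd_reflectance
            )
        bands[b] = np.clip(raster, 0.0, 1.0)
    return BandStack(gre=bands["gre"], red=bands["red"], reg=bands["reg"], nir=bands["nir"], gsd=gsd)


def density_for_gsd(gsd: float) -> float:
    """Canopy point density (points/m^3) for a GSD, log-linearly interpolated
    (and edge-slope extrapolated) through the calibration table."""
    if gsd <= 0:
        raise ValueError("gsd must be > 0")
    gsds = np.array(sorted(DENSITY_BY_GSD))
    logd = np.log([DENSITY_BY_GSD[g] for g in gsds])
    if gsd <= gsds[0]:
        slope = (logd[1] - logd[0]) / (gsds[1] - gsds[0])
        return float(np.exp(logd[0] + slope * (gsd - gsds[0])))
    if gsd >= gsds[-1]:
        slope = (logd[-1] - logd[-2]) / (gsds[-1] - gsds[-2])
        return float(np.exp(logd[-1] + slope * (gsd - gsds[-1])))
    return float(np.exp(np.interp(gsd, gsds, logd)))


def render_cloud(
    trees: list[TreeTruth],
    layout: OrchardLayout,
    gsd: float = 2.13,
    xyz_noise_sd: float = 0.02,
    seed: int = 0,
    ground_density: float = 4.0,
    surface_fraction: float = 0.7,
    dead_trunk_points: int = 5,
    density: float | None = None,
) -> PointCloud:
    """Sample a SfM-style orchard point cloud.

    Canopy points for each live tree are sampled inside its truth ellipsoid
    at the volumetric density mapped from the GSD (``density`` overrides).
    The sampler emulates nadir SfM reconstruction: a ``surface_fraction``
    share of points lies on the upper crown envelope (the surface the
    camera actually sees) and the rest is uniform in the full ellipsoid
    (foliage gaps).  Sparse ground returns at z ~ 0 (``ground_density``
    points/m^2) make per-region Z minima reflect the ground plane.  All
    points get isotropic Gaussian jitter of sd ``xyz_noise_sd``.
    """
    if xyz_noise_sd < 0:
        raise ValueError("xyz_noise_sd must be >= 0")
    if not 0.0 <= surface_fraction <= 1.0:
        raise ValueError("surface_fraction must be in [0, 1]")
    rho = density_for_gsd(gsd) if density is None else float(density)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC10D]))
    chunks: list[np.ndarray] = []
    for t in trees:
        cx, cy = t.center_xy
        if t.is_dead:
            n_pts = dead_trunk_points
            if n_pts > 0:
                pts = np.empty((n_pts, 3))
                pts[:, 0] = cx + rng.normal(0.0, 0.05, n_pts)
                pts[:, 1] = cy + rng.normal(0.0, 0.05, n_pts)
                pts[:, 2] = rng.uniform(0.0, t.trunk_height, n_pts)
                chunks.append(pts)
            continue
        c = max(t.canopy_height_total - t.trunk_height, 0.0) / 2.0
        r = t.canopy_radius
        vol = (4.0 / 3.0) * math.pi * r * r * c
        n_pts = max(int(rng.poisson(rho * vol)), 1)
        zc = t.trunk_height + c
        n_surf = int(round(surface_fraction * n_pts))
        n_int = n_pts - n_surf
        parts = []
        if n_surf:
            # Upper-envelope surface points: uniform cos(theta) over the
            # upper hemisphere, azimuth uniform.
            cos_t = rng.uniform(0.0, 1.0, n_surf)
            sin_t = np.sqrt(1.0 - cos_t**2)
            phi = rng.uniform(0.0, 2.0 * math.pi, n_surf)
            parts.append(
                np.column_stack(
                    (r * sin_t * np.cos(phi), r * sin_t * np.sin(phi), c * cos_t)
                )
            )
        if n_int:
            # Uniform in the full ellipsoid via scaled unit ball.
            v = rng.standard_normal((n_int, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            v *= rng.uniform(0.0, 1.0, (n_int, 1)) ** (1.0 / 3.0)
            parts.append(v * np.array([r, r, c]))
        pts = np.vstack(parts)
        pts += np.array([cx, cy, zc])
        chunks.append(pts)
    if ground_density > 0:
        area = layout.field_length * layout.field_width
        n_g = int(rng.poisson(ground_density * area))
        if n_g:
            g = np.empty((n_g, 3))
            g[:, 0] = rng.uniform(0.0, layout.field_length, n_g)
            g[:, 1] = rng.uniform(0.0, layout.field_width, n_g)
            g[:, 2] = 0.0
            chunks.append(g)
    points = np.vstack(chunks) if chunks else np.empty((0, 3))
    if xyz_noise_sd > 0 and len(points):
        points = points + rng.normal(0.0, xyz_noise_sd, points.shape)
    if len(points):
        # Crop to the field footprint (SfM output is clipped to the
        # processing area), keeping the cloud inside the raster extent.
        np.clip(points[:, 0], 0.0, layout.field_length, out=points[:, 0])
        np.clip(points[:, 1], 0.0, layout.field_width, out=points[:, 1])
    return PointCloud(points=points)


def simulate_scene(
    layout: OrchardLayout | None = None,
    gsd: float = 2.13,
    seed: int = 0,
    with_bands: bool = True,
    with_cloud: bool = True,
    noise_sd_reflectance: float = 0.01,
    xyz_noise_sd: float = 0.02,
    **cloud_kwargs,
) -> SceneBundle:
    """Generate a full scene (truth + optionally bands and cloud).

    Deterministic: identical (parameters, seed) reproduce the scene
    byte-identically.  ``with_bands``/``with_cloud`` skip expensive stages
    when a study only needs one modality.
    """
    layout = layout if layout is not None else OrchardLayout()
    trees = generate_layout(layout, seed)
    bands = (
        render_bands(trees, layout, gsd=gsd, noise_sd_reflectance=noise_sd_reflectance, seed=seed)
        if with_bands
        else None
    )
    cloud = (
        render_cloud(trees, layout, gsd=gsd, xyz_noise_sd=xyz_noise_sd, seed=seed, **cloud_kwargs)
        if with_cloud
        else None
    )
    return SceneBundle(layout=layout, trees=trees, bands=bands, cloud=cloud, seed=seed)


def truth_segmentation(trees: list[TreeTruth], layout: OrchardLayout):
    """Grid segmentation aligned to the ground truth.

    Row boundaries are the mid-lines between planted rows; column
    boundaries within each row are midpoints between adjacent (jittered)
    tree centres; outer boundaries are the field edges.  Used to isolate
    morphometric recovery error from detection error.
    """
    from .segmentation import GridSegmentation

    y0 = (layout.field_width - layout.n_rows * layout.row_spacing) / 2.0
    row_edges_y = [0.0]
    for i in range(1, layout.n_rows):
        row_edges_y.append(y0 + i * layout.row_spacing)
    row_edges_y.append(layout.field_width)
    # Image row coordinate increases as Y decreases (north-up).
    L_3D = np.array([layout.field_width - y for y in sorted(row_edges_y, reverse=True)])
    C_3D = []
    for i in range(layout.n_rows):
        xs = np.sort([t.center_xy[0] for t in trees if t.row_index == i])
        edges = [0.0] + [0.5 * (a + b) for a, b in zip(xs, xs[1:])] + [layout.field_length]
        C_3D.append(np.asarray(edges))
    return GridSegmentation(
        L_2D=None,
        C_2D=None,
        m_2D=0,
        n_2D=0,
        m_3D=layout.field_width,
        n_3D=layout.field_length,
        L_3D=np.sort(L_3D),
        C_3D=C_3D,
    )
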