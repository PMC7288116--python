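# Methods

`orchardmetrics` implements a UAV multimodal measurement chain for modern
standardized orchards: vegetation-index imagery and an SfM point cloud of a
gridded orchard block are segmented into per-tree regions by cumulative
grayscale projection, each tree's canopy is summarized by three
morphometrics and seventy spectral features, and a small neural network
maps those features to fruit yield. A synthetic scene generator with known
ground truth closes the loop so every stage can be validated numerically.

## Row/column detection by grayscale projection (RCGP)

The detector works on a 0–255 grayscale vegetation-index image. For a
*soil-bright* index — NG = GRE/(NIR+RED+GRE), which is depressed over
vegetation by the high NIR of healthy foliage — the bare-soil strips
between tree rows, and between trees within a row, are maxima of the
cumulative grayscale profile

    G_L(i) = sum_j I(i, j)        (rows; analogously G_C(j) for columns).

The profile is smoothed by a normalized Gaussian kernel (reflect padding;
the symmetric kernel and padding preserve total mass exactly) and local
maxima of the smoothed profile are taken as segmentation positions. Rows
are detected on the whole image's Y profile; columns independently inside
each row band. Consecutive positions, together with the image edges,
bound half-open cells that each should contain one tree. Pixel boundaries
convert to point-cloud metres by pure proportional scaling
`L_3D = L_2D * m_3D / m_2D` (and likewise for columns), which unifies the
2-D and 3-D segmentations; the north-up row-orientation flip is applied
when cells are mapped to point subsets.

Canopy-bright indices (NDVI family) are handled by an `invert` mode that
negates the grayscale before projection.

Tunable parameters (all in `segment_image` / CLI flags):

| parameter | default | rationale |
|---|---|---|
| smoothing bandwidth `h` | 0.125 × expected spacing (px) | wide enough to suppress reflectance-noise wiggles in the projection, narrow enough that the dip of a 0.8 m-radius crown survives; 0.25 × spacing demonstrably erases small-crown dips |
| min peak separation | 0.5 × expected spacing | two boundaries cannot be closer than half a planting interval |
| min prominence | 2% of the smoothed profile's dynamic range | keeps faint gap peaks next to small crowns; pure noise peaks after smoothing are far below this |
| wide-cell subdivision | on, threshold 1.5 × spacing | see below |
| expected spacing | from the planting plan, else FFT dominant period of the profile | standardized orchards have a constant planting interval |

**Wide-cell subdivision.** A dead tree (bare trunk, few leaves) produces
almost no profile dip, so the two soil gaps flanking it merge into one
cell spanning two planting positions. Because the constant planting
interval is the premise of a standardized orchard, any cell between two
*detected* interior boundaries wider than 1.5 × the expected spacing is
split into the implied number of planting positions by evenly spaced
boundaries. Edge cells are exempt — field margins are legitimately wide —
which leaves one known failure mode: a dead tree adjacent to the field
margin merges into the edge cell. On full-scale synthetic scenes this
costs ≈ 0.4% of cells and is the analogue of border-area misrecognition
in real campaigns.

Detection is scored against truth by containment: a cell is correct when
it contains exactly one true tree centre (dead or live); C = NC/N × 100
and E = NE/N × 100 count correct and erroneous (zero or multiple centre)
cells. A row band is correct when it contains all of exactly one row's
centres.

## Canopy morphometrics

Per tree region, from its point subset:

* **Height** H = Zmax − Zmin, literally. Ground returns inside the cell
  anchor Zmin at the soil surface, so H is total tree height including
  the trunk. This makes H sensitive to ground-point availability and to
  the extreme-value statistics of vertical noise (see *Known
  limitations*). A percentile-clipped variant is available but off by
  default.
* **Projected area** S_XOY: shoelace area over the counter-clockwise
  convex hull (scipy Qhull) of the XOY-projected *canopy* points. Points
  below z = 0.3 m are treated as ground and excluded from the hull —
  ground sits at ~0 m ± noise and live canopies start at the 0.6 m trunk
  top, so the cutoff separates the two cleanly; without it the hull of
  any cell would be the cell rectangle.
* **Volume** V = (4/3)π · ((H − h_trunk)/2) · (S_XOY/π)
  = (2/3)(H − h_trunk) S_XOY: a spheroid whose vertical semi-axis is half
  the canopy depth and whose horizontal radius comes from the equivalent
  circle of the hull area. Default trunk height 0.6 m, configurable.

Degenerate regions (under two points for H, collinear or under three
canopy points for S) propagate NaN plus a flag, never a silent zero.

## Spectral features

Ten vegetation indices (NG, NR, NDVI, GNDVI, DVI, CIG, OSAVI, RDVI, NLI,
WDRVI) are computed pixel-wise from the reflectance bands and min–max
rescaled to 0–255 per image (rounding half away from zero). Zero
denominators yield value 0 plus a logged mask. RDVI is read as
(NIR − RED)/√(NIR + RED), the standard renormalized-DVI form.

Per tree, on each index's grayscale inside the region's rectangular pixel
window (rectangles, not canopy masks — the segmentation produces
rectangles; masking exists as an option):

* **Color moments**: mean μ, rms deviation σ, and the signed cube root of
  the third central moment (sign kept so negative skew stays negative).
* **GLCM textures**: the co-occurrence matrix over 16 uniform gray bins,
  distance 1, four directions (offsets (0,1), (1,1), (1,0), (1,−1))
  summed and normalized; contrast CON = Σ|i−j|²p, correlation COR
  (marginal-moment form; reported as 0 + flag for constant patches so
  dead trees never abort a batch), angular second moment ASM = Σp², and
  inverse difference moment INM = Σp/(1+|i−j|).

Input modes for the yield model concatenate blocks in a fixed order:
`input1_<IDX>` = 7 features of one index + (H, S, V) → 10;
`input2` = (H, S, V, P) → 4; `input3` = moments of all ten → 30;
`input4` = textures of all ten → 40; `input5` = both → 70;
`input6` = input5 + (H, S, V, P) → 74. The vector always reports its true
length.

## Yield network

A three-layer perceptron (m inputs → h tanh hidden units → linear
output) minimizes MSE by Levenberg–Marquardt: residual Jacobians by
backprop, step (JᵀJ + λI)δ = Jᵀr, λ starting at 100 with a ×10/÷10
schedule. The large initial damping keeps early steps short so the
best-validation snapshot has fine granularity; with near-zero initial
damping the first Gauss–Newton steps jump straight to an overfit training
minimum on wide feature sets. Training stops when validation MSE has not
improved for 6 epochs (the conventional max-fail setting for this
optimizer) and the best-validation weights are kept. An `adam` backend is
available.

Hidden width follows h = ceil(√(m+n)) + a with a ∈ 1..10; `a = "auto"`
trains all ten and keeps the lowest validation RMSE. Data split
60/15/25 train/validation/test by seeded shuffle with largest-remainder
rounding (160 trees → 96/24/40). Inputs and target are z-scored on the
training split only and the scalers frozen — tanh saturates on raw 0–255
moment features — and test indices are never touched before final
scoring. Dead trees and feature rows with missing values are excluded
from modelling by default. Metrics: R², RMSE, and relative average
deviation RAD = mean(|ŷ−y|/y) × 100 (max/min also reported), each
computed per split and labelled.

## Synthetic orchard generator

The generator emulates the reference field campaign: a 140 m × 25 m block
of five rows (5 m row spacing, 4 m plant spacing) with 30–34 trees per
row — 160 positions, 8 expected dead — and 0.6 m trunks. Tree centres get
±0.3 m uniform jitter so segmentation is never trivially exact. Live
crowns draw total height from U(2.0, 3.5) m and radius from U(0.8, 1.8) m;
dead trees are small (radius U(0.1, 0.3) m) with half-strength spectral
contrast (trunk plus a few leaves).

**Bands.** Rasters of ceil(extent/GSD) pixels per band start at soil
reflectance (GRE 0.18, RED 0.22, REG 0.28, NIR 0.30), canopy discs
(GRE 0.10, RED 0.06, REG 0.35, NIR 0.55 × per-tree vigor) are alpha
blended with a one-pixel rim, and i.i.d. Gaussian reflectance noise
(default sd 0.01, the order of a calibrated multispectral camera's
reflectance error) is added and clipped to [0, 1]. With these values NG
is ≈ 0.26 over soil versus ≈ 0.14 over canopy, the contrast the detector
needs.

**Cloud.** Canopy points are sampled per live tree at the volumetric
density mapped from GSD through the calibration table
{2.13 → 364.77, 3.31 → 75.55, 4.39 → 32.01, 5.43 → 17.22,
6.69 → 8.65} points/m³ (log-linear interpolation between entries). The
sampler emulates nadir SfM reconstruction: 70% of points on the upper
crown envelope (uniform cos θ over the hemisphere), 30% uniform in the
ellipsoid (foliage gaps); this mix keeps noise-free recovery of H within
1% and S within 5% at the highest density. Ground returns (4 points/m²)
at z ≈ 0 make per-region minima reflect the soil. All points get
isotropic Gaussian jitter (default sd 0.02 m) and the cloud is cropped to
the field footprint. Dead trees contribute five trunk points.

**Yields.** Live-tree yield is b₀ + b₁·V_truth + b₂·NG_canopy + noise,
clipped at 0, with b = (45, 6, −100) chosen so the population mean is
≈ 80 kg per tree; the vigor that scales canopy NIR enters both the
spectral rasters and the yield, so the spectral features carry real
signal. By default the noise sd is calibrated from the realized signal
spread so the population R² between noise-free signal and yield is 0.90 —
the model's attainable ceiling is therefore known by construction.

Everything above is deterministic given (parameters, seed): per-stage
streams derive from the scene seed, and regenerating a scene is
byte-identical.

**What the generator does not emulate**, hence what passing tests do not
show about real data: radiometry (BRDF, atmosphere, shadows), SfM
reconstruction artifacts (holes, doubled surfaces, georeferencing error),
terrain relief (the ground is a plane), crown asymmetry and overlap
biology (crowns are spheroids), and hand-measurement error in the ground
truth (truth is exact). Detection rates near 100% here mean the projection
logic is correct, not that any orchard image will segment perfectly.

## Numerical choices and degenerate inputs

Grayscale rounding is half-away-from-zero (stated so tests are exact);
constant rasters map to all-zero grayscale. Cells are half-open [lo, hi)
with ties toward the lower cell; boundary arrays end at the full image
extent so cells tile the raster exactly and region point counts sum to
the in-extent cloud size. Zero-denominator pixels, empty regions,
collinear hulls, constant patches and zero-variance targets all produce
flagged values rather than exceptions. The LM solver retries with
increased damping on singular normal equations and aborts with a
diagnostic on non-finite loss.

## Known limitations

* H = Zmax − Zmin is an extreme-value statistic: with vertical noise sd
  σ it overestimates systematically by roughly (2.4σ from the ground
  minimum + 2σ at the apex). At σ = 0.02 m that is ≈ +3% of a 2.75 m
  tree — visible in the morphometric study — and no amount of point
  density removes it. Percentile clipping would, at the cost of the
  literal definition.
* The convex hull likewise rides the outer noise envelope of rim points
  (≈ +4% area at σ = 0.02 m), and neighbouring crowns wider than half the
  planting interval leak points across cell boundaries.
* Dead trees bordering the field margin cannot be separated from the
  margin without prior knowledge of the row's tree count.
* The yield network's test split holds ~40 trees; per-seed test R²
  scatters by ±0.05 around its median even at a fixed scene.
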