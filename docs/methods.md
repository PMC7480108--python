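# Methods

This note documents the models, conventions, parameters and numerical
choices behind the package, and what the synthetic validation does and
does not demonstrate about real microscopy data.

## Coordinate and unit conventions

Rasters are indexed (C, T, Z, Y, X); pixel indices are 0-based with the
origin at the top-left and y increasing downward. Physical units are
micrometres and minutes everywhere in the library; conversion happens
only at I/O. Angles are reported in degrees in the half-open interval
(−180°, 180°]; positive angles are counter-clockwise in standard math
coordinates (x right, y up) obtained by flipping the raster y-axis. In
the nucleus-velocity frame this means: a spot directly ahead of the
nucleus along its displacement is at θ = 0°, directly behind at 180°,
and — with the y-flip — a spot offset (dy, dx) = (+1, 0) from a nucleus
moving along +x sits at −90°. The transform is oracle-tested against an
explicit rotation-matrix construction.

## Synthetic scene model

All fixtures share a minimal but standard fluorescence image model:
expected photon image = PSF-blurred object intensity + uniform
background; Poisson shot noise is applied to the photon image, then
additive Gaussian read noise; negative values are clipped. The PSF is an
isotropic 2D Gaussian (default σ = 0.3 µm). There is no photobleaching,
stage drift, depth-dependent aberration or 3D PSF; movies are single-z
because the analysis operates on maximal projections.

**Polarity movies.** Nuclei (uniform disks, radius 4 µm) perform a
persistent random walk: per-interval turning angles are von Mises with
concentration 4p/(1−p) for persistence parameter p ∈ [0, 1] (p = 0
uncorrelated headings, p = 1 straight); step length is speed ×
frame interval. Walks reflect at a margin wide enough that the whole
endosome cloud stays in the field of view; the ground truth records the
*realized* displacement, so reflections do not corrupt the reference
frame. At each frame, endosome angles are drawn from the configured law
(uniform, or von Mises(µ, κ)) measured from the realized displacement of
the interval ending at that frame — the same convention the analysis
uses — and radii from a normal law (mean 6 µm, SD 1.5 µm, floor 2 µm).

Defaults emulate live imaging of single breast-carcinoma cells in 3D
collagen: 0.25 µm pixels, 384×384 fields, frames every 10 min, nucleus
speed 0.3 µm/min, persistence 0.7, 20 endosomes per cell. Where the
acquisition literature gives no number (endosome count per frame, radii,
amplitudes) the values are configuration choices picked once to give
realistic densities and SNR ≈ 10–20, not quantities estimated from data.

**Colocalization fixtures** rasterize smooth random-walk fibers 3 px
wide and partition fiber pixels into shared / A-only / B-only groups so
that the shared fraction of each channel's supra-threshold pixels equals
the requested ρ exactly on noiseless output.

**Degradation fields** plant Gaussian spots (σ = 2 px) with rejection
sampling at a minimum pairwise separation of 4 × PSF σ, and raise a
packing error when the requested density cannot be placed.

**Invasion stacks** scale each slice so its total intensity is exactly
proportional to the requested per-depth weight, making the planted
invasion fraction available in closed form.

## Segmentation

Nuclei: Gaussian smoothing (default 2 px), global threshold (Otsu unless
given), connected components, removal of components < 64 px, and a
watershed on the distance transform seeded at distance maxima
(min_distance 10 px) to split touching nuclei. A plane that is constant
or empty after thresholding returns an empty mask with a warning.

Puncta (endosomes, degradation spots): scale-normalized negative
Laplacian of Gaussian, σ matched to the expected spot size (default
0.4 µm ≈ PSF-broadened endosome; 0.3 µm is used inside the movie
pipeline). Regional maxima above threshold seed a watershed on the
inverted response restricted to response > half the threshold; each
basin yields one response-weighted centroid plus its
background-subtracted integrated intensity (flux). Plateaus resolve by
scan order, so detection is deterministic. Thresholds: endosomes use
max(0.2 × max response, 5 robust SDs of the response); degradation spots
default to median + 6 robust SDs of the response, which is invariant to
a global gain and yields zero detections on background-only fields.
Detections whose centroid lies within σ of the image edge are flagged
and, for endosomes, excluded by default.

**Multiplicity-aware counting.** Two puncta closer than ≈2σ produce a
single LoG maximum and cannot be split geometrically. Because a
polarized angular distribution crowds puncta at the cell front, counting
such blobs once systematically flattens the measured distribution
(≈2.5 percentage points of frontal fraction at the default densities).
The pipeline therefore estimates each detection's multiplicity as its
flux divided by the movie-wide median single-spot flux (constant-
brightness puncta make the two populations separate cleanly), and
count-based readouts (rose histogram, front fraction) weight records by
multiplicity. Spacing-based statistics (Rao's test) instead use one
angle per detection, since exactly duplicated angles would create
zero spacings and bias the statistic; with ≈10% unresolved pairs this
leaves the uniform null intact and is conservative for the polarized
alternative. On real data with variable endosome brightness the flux
ratio is a noisier multiplicity estimate; the behaviour can be disabled
with `count_by_flux=False`.

Marker regions (invadopodia): global threshold (Otsu default, manual
override supported) and removal of connected components with area
strictly below 8 px — a component of exactly 8 px is retained.

## Tracking and kinematics

Linking is greedy nearest-neighbour between consecutive frames:
candidate pairs sorted by distance (ties broken by lowest detection
index), each detection used once, links beyond `max_disp` rejected;
unmatched detections open new tracks. On separable instances (true
displacement below half the minimum pairwise nucleus distance) greedy
linking provably coincides with the optimal bipartite matching, which
the tests verify by exhaustive permutation at n ≤ 8.

Speed is per-interval displacement over elapsed time. Persistence is
defined at whole-track level as net displacement divided by path length
(1 = straight, 0 = returned to start); a per-interval alternative — the
mean cosine of successive turning angles — is exported alongside as
`turning_persistence`, since a per-pair reading of "directionality" is
also defensible. Zero-displacement intervals are allowed; their
direction is undefined and they contribute no polarity records.

## Polarity statistics

Endosomes at frame t are referenced to the displacement t−1 → t.
Intervals with displacement below 0.2 µm (configurable) yield no angles.
Spots are assigned to the nearest tracked nucleus within 15 µm;
equidistant ties go to the lowest track id. Statistics are computed on
all endosomes of a condition pooled; per-cell front fractions are also
exported as a robustness check against cell-level pooling artifacts.

The rose histogram has 12 fixed 30° bins centred on 0°, ±30°, …, 180°
(edges at −15° + 30k). The front fraction is computed on raw angles
(|θ| ≤ 60°), independent of binning. Rao's spacing statistic
U = ½ Σ|Tᵢ − λ| is exact; its p-value is Monte-Carlo — the add-one
smoothed fraction of uniform samples of the same n with larger U —
rather than interpolated from printed critical-value tables, because the
Monte-Carlo null is exact at any n and seedable. The null is cached per
(n, replicates, seed) and generated in memory-bounded chunks so pooled
samples of tens of thousands of angles remain tractable.

## Scalar assays

Control normalization is linear: values are scaled so the control
condition's mean is exactly 100, which makes the operation idempotent.
The degradation index is spots/cells per field; fields with zero cells
are excluded with a warning. Alongside the spot-count index, a mean
masked-intensity per cell metric is provided separately, since
cleaved-collagen signal is sometimes reported as mean intensity per
cell rather than as a spot count; the two are labelled distinctly.

The invasion fraction counts slice sums at depth ≥ 30 µm inclusive.
Depth 0 defaults to the first slice (the gel surface in an inverted
assay acquisition); `surface_index="auto"` instead anchors depth 0 at
the slice of maximal total signal (the non-invading monolayer) for
stacks whose acquisition did not start at the surface. Optional
per-slice background subtraction uses the median of a cell-free corner
patch.

## Validation scales and what it shows

The reference protocols use: Rao calibration with 2,000 uniform samples
of n = 30 against a 5,000-replicate null (expected rejection ≈ 5%);
power over κ ∈ {0, 0.5, 1, 2} with 500 samples each; and two end-to-end
movie conditions of 30 single-cell movies × 40 frames × 20 endosomes
(κ = 1.5 "polarized" vs κ = 0 "unpolarized"), chosen to pool roughly
2 × 10⁴ endosome records per condition while keeping a full validation
run on one CPU in minutes. Passing these protocols shows that the
implementation recovers the generating law through its own detection
and tracking machinery — it does not certify performance on real
movies, where backgrounds are structured, endosome brightness varies,
nuclei deform, and focus drifts. The synthetic generator deliberately
omits those effects; parameters exposed throughout the API are the
knobs a user would retune on real data.

## Known limitations

- No gap-closing or division handling in tracking; a lost nucleus
  starts a new track.
- Flux-based deblending assumes roughly constant puncta brightness
  within a movie.
- The linescan width-average uses bilinear interpolation at sub-pixel
  offsets; profiles across very sharp (1 px) structures are smoothed
  accordingly.
- Manders thresholds default to Otsu per channel; on sparse images a
  manual threshold is usually preferable and is accepted everywhere.
- 2D analysis throughout: z information enters only via maximal
  projection and the invasion depth profile.
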