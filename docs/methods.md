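# Methods

This note documents the models, estimators, defaults and numerical choices
behind `zygoflow`, and what the synthetic validation does and does not show
about real footage.

## Conventions and units

Pixel coordinates are (row, col), 0-based, origin top-left.  Angles are
degrees from the image vertical ("up"), increasing clockwise in the
displayed image, so a vertical diameter sits at 0°.  All algorithms work in
pixels and frames internally; conversion to µm, µm² and µm/min happens only
at the reporting layer, using the stack calibration (µm per pixel, minutes
per frame).  Intensities are normalized to [0, 1] on load by dividing
integer images by their dtype maximum, which makes 8- and 16-bit captures
of the same scene interchangeable up to quantization; the normalization is
idempotent.

## Outline detection

The frame is unwrapped into a polar lattice about a seed centre: `n_angles`
bins (default 360, i.e. 10× finer than the 36 measurement rays) × 1 px
radial bins in a user-set band [r_min, r_max], sampled bilinearly from the
Sobel gradient-magnitude map.  The edge map is normalized to a maximum of 1
before optimisation, so the detected outline is invariant to a global
intensity scaling.  The boundary is the radius function maximizing

    Σ_θ edge(θ, r(θ)) − s · Σ_θ (r(θ+1) − r(θ))² − w · Σ_θ (r(θ) − r_prev(θ))²

with circular closure r(A) = r(0) and |Δr| ≤ 2 px per angular step.  Both
penalties are quadratic.  Closure is handled by solving the DP once per
admissible start radius on a coarse grid (every 4th radius) and refining
±3 radii around the best coarse start; on small lattices where exhaustive
start enumeration is used, the DP objective equals brute-force enumeration
over all closed bounded-step paths exactly (this is tested).

Defaults: smoothing `s = 0.05`, temporal weight `w = 0.02` during tracking
(frame 0 is always detected unbiased).  With normalized edge values of
order 1, `w = 0.02` lets the outline follow boundary motion of a few px per
frame while still rejecting transient edge dropouts; much larger values
visibly attenuate genuine shape cycles by dragging each outline toward its
predecessor, which is why the default is small.  As `w → ∞` the result
reproduces the previous outline exactly (a tested limit).

Options: `edge_polarity` restricts edge evidence to radially falling or
rising intensity transitions — this selects the inner vs outer zona
pellucida edge (default for a zona run: outer, i.e. rising from the dark
ring); `pb2_angle`/`pb2_extra_px` dilate the admissible radius band within
±15° of the annotated second-polar-body direction so the 2PB bulge can be
enclosed without loosening the whole search.

Per-frame failures (no edge energy in the band) are recorded; frames
flanked by successes are filled by linear interpolation of r(θ) per angular
bin (centres interpolated likewise) and flagged `interpolated`.  If more
than half the frames fail, tracking aborts with a diagnostic.

## Radial morphometrics

The CoA is the polygon area centroid (shoelace).  Radii are exact
ray–polygon intersection distances (via shapely); when a concave outline
(cytokinesis) crosses a ray more than once, the farthest intersection is
used by default so diameters stay monotone under elongation (the first
crossing is available as an option).  Diameters are sums of opposed radii
and therefore pass through the CoA by construction.  The diameter SD uses
the sample (n−1) denominator, recorded in output metadata; the population
version differs by the constant √(17/18) ≈ 0.972.  The 2PB diameter snaps
the CoA→2PB direction to the nearest 10° ray (snap recorded); the
"+2PB-width" variant extends the near radius to the far edge of the
annotated 2PB blob (distance to its centre plus its radius).

## Shape sequences and elongation

Candidate cycles are trough–peak–trough triplets of the diameter-SD trace
after moving-average smoothing (default 3 frames), with peaks found at
minimum prominence 0.3 µm to reject pixel-level noise while keeping small
genuine cycles.  Trough frames take the widest-extent convention: the
minimum of the smoothed SD between neighbouring peaks (or the series ends).
For each triplet, each of the 18 diameters is tested for a rise of at least
1.5 µm (the detection rule) from first trough to peak followed by a fall of
at least the retraction floor (default 0.5 µm, a measurement-noise guard;
only the extension half of the rule carries a hard threshold).  One
sequence is emitted per qualifying triplet, carrying the angle with the
largest in–out–in change (min of extension and retraction); ties go to the
smaller angle.  Overlapping cycles are reported independently per triplet,
never merged.

The elongation axis is the argmax over the 18 angles of diameter(t1) −
diameter(t0); a no-growth span is flagged indeterminate, ties are flagged
and resolved to the smaller angle.  The first step is the earliest frame
where the axis diameter rises ≥ 1 µm within a 2-minute window; when the
frame interval does not divide the window the nearest whole number of
frames is used and recorded.  Indent detection (automatic staging) finds
local maxima of the depth of the boundary below its convex hull along fine
rays; depths are hull-relative and therefore smaller than the full radial
excursion of a narrow furrow.

## PIV

Multi-pass normalized cross-correlation.  Pass 1 matches `initial_window`
(default 64 px) templates within a symmetric search margin of half the
window; each later pass halves the window (to `final_window`, default
32 px; 16 px suits low-noise footage) and shifts the search region by the
coarse displacement interpolated bilinearly from the previous pass
(invalid coarse vectors are gap-filled with the mean valid displacement).
Grid spacing is `window × (1 − overlap)` with default 50 % overlap.

Correlation is computed batched in the Fourier domain with exact NCC
normalization via integral images.  The peak is refined per axis by a
three-point Gaussian fit (parabolic fallback when a lobe is non-positive).
A vector is invalidated when: the template or search region is textureless;
the peak-to-second-peak ratio (second peak outside the 3×3 around the
first) is below 1.2; the peak lies on the border of the search domain; the
search region had to be clamped at the image edge (an incomplete search
range cannot be trusted); or the displacement exceeds half the initial
window.  Invalid vectors are data, not errors.  Vectors are stored in
px/frame and reported in µm/min; summary statistics are the arithmetic mean
vector over valid vectors inside the cell outline and the mean speed inside
a cytoplasmic rectangle.

## Vorticity and sign comparisons

At each grid point a linear velocity model u(x, y), v(x, y) is fitted by
least squares to the valid vectors of the surrounding 3×3 block (centre
included, minimum 4 valid and full rank); the vorticity is ∂v/∂x − ∂u/∂y
of the fit, in min⁻¹, evaluated in y-up physical coordinates so that
positive vorticity is counter-clockwise in the displayed image (stated in
output headers).  On complete grids with linear velocity fields this
equals the central-difference curl exactly; its neighbourhood support is
what makes it usable on the incomplete vector patterns that intermittent
cytoplasmic vortices produce.

Region series average the defined vorticity values inside a (per-frame)
cell or half-cell mask.  The sign is 0 when fewer than 4 grid points
contribute or |mean| is below the noise floor (default 0.005 min⁻¹,
roughly the reading obtained from pure-noise synthetic fields; a per-video
floor of 2× the SD over a user-designated quiescent interval can be
substituted).  Half-cell masks are produced by cutting the mask with the
perpendicular bisector of its longest axis (maximal-distance chord between
convex-hull points); an annotated axis takes precedence.

Two sign series are compared per consecutive 100-minute window (the first
window start is configurable, e.g. 30–99 min after the two-indents stage):
sign-0 frames are dropped, the 2×2 table of (+, −) counts is tested with
Pearson's chi-squared (1 df), applying Yates' correction exactly when any
expected count is below 5 (Fisher's exact test is available as an option
for very small counts).  Windows where either region has fewer than 5
defined signs are reported untestable; tables with a zero margin carry no
association and report chi-square 0, p 1.  The default significance level
is 0.05.

## Kymographs

Bilinear sampling at 1 px steps along a diameter of fixed length and angle,
one column per frame.  The default anchor is the per-frame CoA so the line
tracks the cell; a fixed anchor gives zona-referenced views.  End-window
mode keeps a trailing sub-segment of the line.  A 50 µm line at 0.5 µm/px
yields exactly 100 rows.

## Synthetic data generator

The generator renders what the analysis measures: a cell drawn as a radius
function r(θ, t) (circle or oriented ellipse) containing Gaussian granules
(default 350 per scene, σ 1.6 px, contrast 0.18 about a 0.55 interior on a
0.40 background) inside a static, slightly elliptical dark zona ring (axis
ratios around 1.05–1.09).  The membrane is an intensity step centred on the
true boundary plus a faint dark rim, so the Sobel maximum sits on the
analytic boundary — the property the outline accuracy checks rely on.
Defaults (0.5 µm/px, 2-minute frames, 35 µm cell radius, Gaussian read
noise SD 0.01, chosen so PIV validity inside the cell exceeds 90 %) emulate
typical incubator time-lapse.

Shape cycles add a cosine-squared angular bump (half-width 30°) with a
half-sine time course to both opposed radii, so the stated amplitude is the
peak diameter change.  The cytokinesis script ramps an elongation along a
chosen axis with optional perpendicular slimming and deepening Gaussian
furrow indents, the second staggered after the first.  Flow models are
uniform translation, solid-body rotation, and vortex pairs; vortices can be
confined to their cell's interior (rigid cytoplasm rotation cut off at the
membrane with a 3 px soft edge), which is the two-cell configuration, or
free-standing with a linear taper outside a solid core.  Texture for frame
t is sampled from the initial granule canvas through the accumulated flow
map in a single bilinear interpolation — mathematically identical to
frame-by-frame backward advection for these flow families, but without
compounding interpolation blur, so correlation quality does not decay over
long recordings.  Ground-truth outlines, masks, flow vectors and event
lists are written from the analytic model, never re-estimated.

Presets: `interphase_cycles` (two disjoint diameter cycles, 3.5 µm at 140°
and 4.0 µm at 40°), `pnebd_burst` (a brief cytoplasmic speed spike),
`cytokinesis_vortices` (61 frames / 60 pairs of mirrored counter-rotating
two-cell flow at |ω| = 0.02 rad/min), and `two_cell_persistence` (the same
geometry spanning 555 simulated minutes at 5-minute frames).

What the synthetic scenes do **not** emulate: optics (no PSF, no defocus),
organelle-scale texture statistics, membrane ruffling, z-drift, embryo
rotation out of plane, or illumination drift.  Passing tests therefore
demonstrate the estimators' correctness against known ground truth and
their robustness to masking, noise and incomplete data — not performance on
arbitrary clinical footage, where calibration, band selection and noise
floors must be set per recording.

## Problem sizes used in validation

The test suite and the acceptance script validate on: a 512² one-frame
ellipse scene for outline accuracy; DP lattices up to 10 × 10 for
enumeration equality; 256² frames for PIV translation/null checks and one
1024² pair for throughput; a 512² sinusoidal-shear pair for the multipass
comparison; 14 × 14 analytic vector grids for vorticity; the full 61-frame
`cytokinesis_vortices` preset for the end-to-end sign test; and an 8-frame
pipeline run, twice, for byte-level determinism.  These sizes were chosen
to exercise every code path at desk scale while keeping the whole
validation run in well under a quarter of an hour.

## Known limitations

- The outline detector assumes a star-convex boundary about the seed
  centre; deeply folded shapes (late cytokinesis necks seen edge-on) are
  represented by the farthest-intersection convention rather than a true
  non-radial contour.
- PIV assumes locally rigid translation per window; strong rotation or
  deformation within a window attenuates the recovered displacement, and
  the vorticity estimate inherits that attenuation near vortex cores
  smaller than the window.
- The chi-squared sign test treats frame pairs as independent observations;
  strongly autocorrelated vorticity series overstate significance, which is
  one reason the minimum-support and noise-floor guards exist.
- Automatic indent depths are convex-hull-relative and under-read narrow
  furrows.
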