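# Methods

## Geometry model

The stage frame is right-handed: the tilt axis is +x, the beam travels along
−z and the stage canvas is the xy plane. Tilting a flat specimen by α about x
foreshortens it in projection: content at stage y appears at image
y · cos α, while x is unchanged. Conversely a beam-frame (image-plane)
displacement dy intersects the tilted specimen at stage dy / cos α, and the
circular illuminated area of radius r becomes a stage-plane ellipse with
semi-axes (r, r / cos α). These three relations drive everything else:
off-axis ROI drift and its beam-image-shift compensation
(Δy = y(cos α − 1), which nulls the projected residual identically), the
stretching of offset trajectories at tilt, and the growth of the dosed area.

Tile grids are regular m × n arrays in row-major order from the (−x, −y)
corner, with the center tile at (⌊m/2⌋, ⌊n/2⌋). Overlaps are stored in
pixels (with a fractional-overlap helper) because the exact benchmark
spacings are pixel-valued: a 5,760 × 4,092 px frame with 1,152/576 px
overlaps gives piece-coordinate spacings of 4,608 px in x and 3,516 px in y.
Piece coordinates are non-negative integers anchored at (0, 0, 0); the
image-shift vector of a tile is its piece coordinate relative to the center
tile, converted to micrometres.

Tilt schedules cover ±max in fixed increments. The dose-symmetric ordering
starts at 0° and alternates sides in blocks of `group_size` with
non-decreasing magnitude per side (the classic Hagen scheme is
`group_size=1`; the benchmark uses groups of three, which Nyquist-wise
trades a little dose symmetry for far fewer side switches). A bidirectional
ordering (0 → +max, then −inc → −max) is provided for comparison.

The fringe-impacted margin defaults to 4 % of the frame's x dimension per
side (the upper bound of the 3.5–4 % range such calibrations produce on
non-fringe-free optics); the usable field of view excludes
⌊0.04 · width⌋ pixels from each x edge and nothing in y.

The autofocus/tracking area sits on the tilt axis, 0.5 µm plus the maximum
pattern offset beyond the pattern edge, which provably clears every
illuminated tile disc at 0° even when the pattern is displaced by the full
offset clamp.

## Spiral offsets

Overlap bands between adjacent tiles are re-exposed at every tilt, so a
no-shift montage concentrates roughly double dose there for the whole
series. Displacing the entire pattern per tilt along a slowly opening spiral
spreads that burden. The literature names the control parameters — terminal
amplitude `A_final`, `period`, `turns`, `revolutions` — without a formula,
so this package fixes one semantics and documents it: exposure k uses spiral
sample s_k = ⌊k / period⌋, radius A_final · s_k / turns and angle
2π · revolutions · s_k / turns. The first sample is the origin (the 0°
reference is unshifted) and the radius is non-decreasing. With the default
A_final = 1.5, period = 3, turns = 50, revolutions = 15 and 41 tilts, the
terminal radius is 1.5 · ⌊40/3⌋ / 50 = 0.39 µm. Alternative
parameterizations can be supplied as explicit design-point arrays.

Offsets are clamped so the largest radial magnitude does not exceed 30 % of
the **long-axis** field of view — 0.30 × 2.651 µm = 0.795 µm (~0.8 µm) at
4.603 Å/px — which is what keeps the ROI inside every tile over the full
tilt range.

The "adjust shifts by tilt angle" option is directionally ambiguous in
prose; here *adjusted* means the beam-frame y offset is scaled by cos α so
the **stage-plane** trajectory is identical at every tilt to the 0° design
(verified to machine precision by property test). *Unadjusted* applies the
design point as a fixed beam-frame offset, so the stage trajectory stretches
by 1/cos α — larger physical displacements at high tilt, which pushes dose
further out of the overlap zone at the cost of a less even overall
distribution. Both modes are simulated and compared by the dose module;
the package asserts only the ordering (spiral < no-shift on overlap-band
maxima), since absolute values depend on the plan.

## Dose simulation

The canvas defaults to 150 × 150 × 1 voxels over 10 × 10 × 0.2 µm. Each
exposure's stage-plane elliptical footprint is rasterized by a
voxel-center-inside-ellipse test and every intersected voxel's dose is
incremented once per beam by the exposure dose (e⁻/Å², or unit counts if the
caller plans with dose 1). Rasterization by center test rather than literal
ray tracing is a numerical choice validated in the suite against an 8 × 8
supersampled area oracle: agreement on ≥ 99.5 % of voxels, with all
mismatches on the footprint boundary. Dose is conserved exactly
(total = Σ dose × footprint voxel count) and simulation is
order-independent, because accumulation is purely additive.

Beam-frame positions map to the stage by dividing y by cos α; at 2 e⁻/Å²
per tile per tilt over 41 tilts, interior voxels of a 3 × 3 benchmark plan
accumulate ~80–250 e⁻/Å² and overlap bands reach ≥ 130 e⁻/Å² — about twice
a typical specimen tolerance — which is the overdose-zone threshold used
downstream.

## Stitching and the two-path pipeline

Per tilt, tiles are placed from nominal piece coordinates and refined
pairwise: the nominal overlap band of one tile (contracted so the search
window can move by the full search radius in both dimensions) is matched
against its neighbour by normalized cross-correlation
(`skimage.feature.match_template`), which is unbiased by overlap area.
Pairwise offsets with peak score ≥ 0.1 enter a least-squares solve over the
tile adjacency graph anchored at tile 0; ties break toward the nominal
offset; tiles with no accepted measurement (e.g. featureless frames over a
grid bar) keep nominal coordinates and are flagged — mirroring the manual
fallback real pipelines occasionally need at high tilt. Blending is linear
feathering over the overlap band; on noise-free fixtures the blended montage
equals the ground-truth projection to machine precision because agreeing
tiles average to themselves.

Nominal piece coordinates are **per tilt**: with each tile tracking its
specimen target, projected content spacing in y contracts as cos α while the
frame stays fixed, so y overlaps grow with |α| and the stitched montage
shrinks in y. The assembled stack is center-cropped to the minimum extent
over tilts, making the high-tilt montage the limiting factor, and is
reconstructed together with every complete per-tile series: m × n + 1
volumes in total (ten for 3 × 3). Tile series missing any projection are
excluded from reconstruction, as inadequate projections would be discarded
in practice.

The drift metric stretches each tilted frame by 1/cos α along y, registers
it against the 0° frame and reports the radial peak displacement in nm. On
compensated synthetic series it stays well inside the ±200 nm retention
benchmark; an injected shift is read back to within ~1 pixel.

The reconstructor is a deterministic ramp-filtered back-projector about the
x tilt axis (linear detector interpolation, π/2N weighting), intended only
to validate pipeline plumbing on synthetic data: a point feature
reconstructs with its argmax within one voxel of truth, and an unfiltered
single 0° projection reproduces itself exactly. Real data should use an
established tomography package.

## Fringe calibration

The beam image (over vacuum, gain-normalized) is Fourier low-passed to 50 Å
with a Gaussian rolloff. The outer 20 % of x and y is treated as the
fringe "signal" band and fitted as a Poisson rate on offset-removed integer
counts (MLE λ = mean); the central 90 % (10 % overlap with the band) as a
Gaussian background (μ, σ). Edge profiles are y-means of x columns over
n ≥ 3 horizontal strips per edge; the cutoff is the outermost depth at which
a profile still leaves μ ± 2σ, averaged over strips and edges. Because the
Gaussian parameters and the excursions scale together, the cutoff is exactly
invariant to affine intensity rescaling. On synthetic beams the injected
depth is recovered to within 0.005 (the residual bias is the low-pass
kernel's real-space tail, ~3 px at 4.6 Å/px); real-instrument values in the
3.5–4 % range depend on the actual optics and are out of reach of synthetic
data, so only the round-trip and monotonicity properties are asserted.

## Particle dose filtering

Particles carry the dose of the voxel containing their stage position
(nearest-voxel lookup; particle extents are ignored, being small relative to
overlap bands). Filtering at the overdose threshold (default 130 e⁻/Å²)
partitions the table exactly, is idempotent, and is monotone in the
threshold. Doses always come from the simulator's map for the matching
plan; the fixture generator can place prescribed counts on either side of
the threshold, which is how the 13,021 → 9,332 benchmark split is exercised.

## Synthetic data: what it does and does not show

The fixture generator emulates acquisition *geometry*: a flat 10 × 10 µm
phantom (high-contrast 5 × 4 µm central region, Gaussian point features,
smooth background) is foreshortened by cos α, windowed at per-tile targets
with optional integer registration jitter, beam masking, synthetic edge
fringes and Poisson counting noise (the 10 e⁻/px/s class of detector rates
informs the default scale). Desk-scale defaults — 128 × 96 px tiles,
24 px overlaps, 3 × 3 pattern, ±30°/3° in groups of three (21 tilts),
600 px phantom — keep a full two-path run around a second; full-size
5,760 × 4,092 geometry is used wherever only geometry matters (grids,
clamps, dose maps). Desk overlaps are kept large relative to the injected
jitter because scaling the frame down 45× without scaling registration
error would make the search-to-overlap ratio far harsher than on real data.

Not modeled: contrast transfer, multislice scattering, detector MTF, beam
ellipticity, lens distortion, stage inaccuracy, sample deformation. Passing
tests therefore demonstrate geometric and algorithmic correctness — exact
bookkeeping, unbiased registration, correct dose accumulation — not imaging
realism; conclusions about real micrographs still require real data.

## Numerical choices and limitations

- Registration is integer-pixel; sub-pixel refinement was deliberately left
  out since piece coordinates are integer-valued in the metadata formats.
- Correlation tie-breaks prefer the smallest displacement from the prior;
  the acceptance threshold (0.1) is a normalized peak score.
- mdoc values round-trip as raw strings (unknown keys preserved verbatim);
  our own writers format floats to 6 significant digits, while macros use
  shortest-round-trip floats so offset tables parse back exactly.
- Macro export is descriptive: it encodes the plan faithfully in a
  SerialEM-like syntax validated by the bundled parser, and is not
  guaranteed to run unmodified on a microscope.
- The simulator treats the specimen as infinitely thin (single voxel layer
  by default); thickness-dependent dose is out of scope.
- `overdose_mask` uses ≥ (at the threshold counts as overdosed), matching
  the filter's removal rule.
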