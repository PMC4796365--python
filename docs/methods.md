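# Methods

`micropassage` quantifies single-cell migration through micro-fabricated
constrictions from two-channel fluorescence time-lapse movies (an
actin-reporter channel and a DNA-stain channel), and ships a calibrated
synthetic-movie generator so that every stage of the measurement chain can
be validated by parameter recovery without any experimental data.

## The assay and its coordinate frame

A cell migrates along a straight channel of width *d* containing one
constriction of width *W* and length *L*. All analysis is done in the 2-D
image plane; device height is carried as metadata only. Coordinates are
continuous micrometres; pixel *i* maps to coordinate (*i* + 0.5) ×
pixel size (pixel-center convention). The constriction occupies the
half-open axial interval [center − *L*/2, center + *L*/2): an edge exactly
at the entry plane counts as having entered. The geometry always comes
from configuration, never from the images.

## Measurement chain

1. **Segmentation.** Each channel is Gaussian-smoothed (σ = 1 px) and
   thresholded. The threshold starts at Otsu's value and is then refined
   to the midpoint between the background median and the median of the
   *eroded* foreground; dropping the one-pixel boundary ring from the
   foreground excludes the blur skirt that otherwise drags the threshold
   down and inflates thin objects (a squeezed cell in a 1.5-µm
   constriction is only six pixels wide at the default sampling). Holes
   are filled and the largest connected component kept (minimum 30 px).
   A contrast gate (foreground ≥ 3 background s.d. above the background
   mean) rejects frames containing only camera noise. The pipeline clips
   masks to the channel lumen — cells cannot occupy the device walls, and
   clipping removes the out-of-wall blur halos of bright structures. The
   nucleus mask is additionally restricted to the once-dilated cell mask.
   Morphology uses a 3×3 square element (8-connected; configurable).

2. **Cortex masks.** The cell cortex is dilate(cell, 1) AND NOT
   erode(cell, 6). "Around the nucleus" is an axial restriction: cortex
   pixels within the nucleus' axial span ± 1 px. In the channel geometry
   the migration axis is the natural frame, and in narrow constrictions
   the erosion consumes the whole local cross-section, so the cortex there
   is the full local cell — matching how the ring looks in projection.

3. **Tracking.** Per frame: mask centroids, leading/trailing axial edges,
   areas, mean intensities. Missing frames stay missing (no
   interpolation). Velocity is the backward difference of the cell
   centroid assigned to the later frame, unsmoothed — the simplest
   estimator at 2-minute sampling. The baseline speed v̄_pre is the mean
   velocity over frames strictly before the nucleus front first reached
   the entrance; the normalized velocity variation is
   (v_inst − v̄_pre)/v̄_pre. For the cohort slowdown statistic only
   displacements lying entirely inside the measured nuclear-transit window
   are used, so boundary frames mixing free and constricted motion do not
   dilute the ratio.

4. **Events.** Four phase times per transit (cell entry, nuclear entry,
   nuclear exit, cell exit), each the first frame the relevant edge
   crosses the relevant plane. Outcomes: *passed* (cell back crossed the
   exit), *reversed* (front retreated ≥ ε = 2 µm behind the entrance
   before any exit; sub-labelled by whether the nucleus front ever
   protruded ≥ δ = 0.5 µm past the entrance), *censored* (movie ends
   while engaged). Both margins sit above pixel/jitter scale and are
   configurable. Only the first resolved engagement is scored. The
   non-passage time runs from cell entry to the last frame of (near)
   maximal front advance — a cell dwelling with a stationary front has
   not yet changed direction. The percentage of passage is
   passed/(passed + reversed); censored cells are excluded from both
   sides.

5. **Actin quantification.** All intensity metrics are ratios against the
   whole-cell mean, hence invariant under global intensity scaling and
   exactly 1 for a uniform cell. The enrichment call is adaptive: a cell
   is scored as accumulating perinuclear actin when the peak normalized
   perinuclear signal inside the nuclear-engagement window exceeds
   max(baseline mean + 2 baseline s.d., 1.2), with the baseline taken from
   ≥ 3 pre-entry frames; cells without a valid baseline are excluded from
   enrichment denominators. The same criterion scores peribead
   accumulation, gated on the measured bead center being inside the
   constriction. Nuclear circularity is 4πA/P² with the area from the
   pixel count and the perimeter from the marching-squares contour at the
   0.5 level; on sub-pixel coverage input this recovers the disk identity
   to < 1%, while hard binary masks carry the usual staircase
   overestimate of P for curved shapes (the index is then a relative
   measure). The DNA-thickness/actin relation is an ordinary
   least-squares fit of column-wise cortex actin against column-wise
   nucleus thickness, restricted to columns thinner than *W*.

6. **Lamina morphometry** operates on fixed-cell still images. The lamina
   intensity along the nucleus boundary band (dilate 1 minus erode 1) is
   binned into a 360-bin angular profile about the nucleus centroid
   (empty bins filled by circular interpolation). A gap is a maximal
   circular run of bins below α = 0.5 × the profile median; the ring is
   ruptured when the longest gap spans ≥ θ_min = 15°. The rupture
   perimeter is (total gap span)/360 × the nucleus boundary length
   (marching-squares contour). A rupture is tip-localized when its
   largest gap centers within ± 45° of the leading pole (the boundary
   point furthest along the migration direction). α, θ_min and the cone
   half-angle are unconstrained by any printed value; the defaults
   produce zero false calls on noiseless continuous rings at any α < 1
   and recover the synthetic panels' rupture fractions exactly.

7. **Statistics.** Fisher's exact test (two-sided by the
   "probability ≤ observed" rule, stated explicitly because two-sided
   conventions differ) and the Mann–Whitney test (exact combinatorial
   U-distribution via a rank-sum dynamic program for pooled n ≤ 25
   without ties, tie- and continuity-corrected normal approximation
   beyond) are implemented from first principles; a statistics library is
   used only as an independent cross-check in the test suite. Summaries
   report mean ± s.e.m. with the n−1 sample s.d.

## The synthetic-data generator

The generator's defaults *are* the study conditions; its calibration
constants live in one place (`SynthConfig`).

**Shape model.** Cell and nucleus are incompressible 2-D columns: each
occupies an axial interval whose local transverse width is the channel
width profile clipped to the object's free width (cell 7 µm = the channel;
nucleus 5 µm), with the interval solved in closed form so the area is
conserved (cell 210 µm² ≈ 30 × 7 µm — channel dendritic cells are
elongated, and a cell much shorter than ~2× the nucleus span would pin the
perinuclear/whole-cell ratio at 1; nucleus 42.5 µm²). Squeezing therefore
elongates the object, as in the source movies. Motion is prescribed on
the center of mass, which makes mask-centroid tracking an unbiased speed
estimator; all event times are closed-form breakpoints of the piecewise
linear trajectory. The nucleus rides 3 µm ahead of the cell center, as in
amoeboid leukocytes.

**Kinetics.** Free speeds are drawn from a normal truncated below at
0.5 µm/min whose *post-truncation* mean and s.d. are moment-matched to
4.48 and 3.93 µm/min (naive truncation of a normal(4.48, 3.93) would
inflate the cohort mean to ≈ 5.6). The resulting law is near-exponential
— the honest consequence of s.d. ≈ mean with a positivity floor. Passage
outcomes are Bernoulli draws from the width-response map {1 µm: 4%,
1.5 µm: 40%, 2 µm: 60% (interpolated, not a printed value), ≥ 3 µm: 78%},
with linear interpolation at other widths. During nuclear transit
(nucleus front past the entrance until nucleus back past the exit) the
whole cell slows by a per-cell fraction drawn from
normal(width response, s.d. 0.10), clipped symmetrically so the cohort
mean stays at the width response (0.41 for widths < 3 µm, 0 at ≥ 3 µm);
without cell-to-cell variability the cohort standard error degenerates
and no sampling-error criterion is meaningful. Non-passing cells creep
their nucleus 1–3 µm into the constriction (or stall just short of it,
< δ, for the no-entry sub-population, 50/50 by default), dwell for the
matched passing-cell constriction time × (1 + Exp(0.3)) — so non-passers
spend at least as long engaged as passers — then retreat at free speed.
In a channel with no narrowing cells never draw reversals.

**Rendering.** 36 × 512 px frames at 0.25 µm/px, 60 frames at 2 min.
The pixel pitch makes every device width an integer pixel count with
edges on pixel boundaries, so binary masks rasterize the channel without
systematic area loss (at 0.325 µm/px the 1.5-µm ribbon loses ~13% of its
area and the centroid drifts with position). The actin channel paints
the body (80 photons/px) with a 1-px cortical rim (×1.15), a 2-µm
rear-pole enrichment (×1.4, kept below the threshold's halo level so it
cannot bias the centroid), and — iff the cell's enrichment flag is set
and its nucleus is engaged — a perinuclear ring band (± 2 px around the
nucleus outline, ×4). The ring amplitude is deliberately high enough
that ring *visibility* never limits detection: the calibration object is
the ring probability (0.93 for passers, 0.25 for engaged non-passers,
chosen strictly inside the printed > 90% / < 30% bounds), and the
detector recovers the flags with measured sensitivity and specificity of
1.0 on labelled cohorts. The DNA channel paints the nucleus with
per-column density ∝ (free width/local width)^0.25, renormalized each
frame so the integrated signal is exactly conserved (squeezing raises
local density without defeating single-threshold segmentation). Frames
are PSF-blurred (σ = 0.25 µm), then carry Poisson photon noise plus
Gaussian read noise (s.d. 2), clamped at zero and stored as uint16.
Movies end four frames after the outcome resolves (frames beyond carry no
information for any scored metric); censored cells keep the full length.

**Lamina panels** are still-image pairs: a filled-ellipse DNA channel and
a boundary-ring lamina channel (semi-axes ~3.2–4.2 µm, elongated ×1.25
for constriction conditions, ring 0.8 µm thick). With the condition's
probability (0.87 / 0.43 / 0.07 for long constriction, short
constriction, straight channel) one angular sector of 40–90° is zeroed;
with probability 0.97 the gap centers at the leading (+x) pole (jitter
s.d. 8°), otherwise uniformly outside the tip cone.

**Bead transits** add a bead channel with a rigid 3-µm disk riding 4 µm
behind the cell center. Width-matched beads (|W − diameter| ≤ 0.25 µm)
trigger a peribead actin ring while inside the constriction with per-cell
probability 0.85; oversized beads stall at the entrance and stall the
cell with them, and no ring is ever painted for unmatched widths.

**Determinism.** One master seed; per-cell streams are spawned from a
`SeedSequence`, so cohorts are bitwise reproducible and order-independent.

## What the generator does and does not emulate

It emulates: the printed cohort statistics as ground truth, squeezing
with area conservation and elongation, conserved DNA with compression-
dependent density, realistic camera noise, frame-rate-limited sampling of
fast transits, and censoring by finite movie length. It does not emulate:
multi-cell channels, cell shape irregularity (protrusions, blebs),
adhesion or drift, photobleaching, several constrictions in series, or
any physical force balance — passage outcomes are drawn, not computed
from mechanics. Passing tests therefore demonstrate that the measurement
chain is calibrated and unbiased on movies with known truth, not that it
would segment arbitrary real data; on real movies the thresholds and
margins exposed in the configuration are the knobs to revisit.

## Numerical choices and degenerate inputs

Sub-pixel coverage is used when painting and when rasterizing truth masks
(threshold 0.5). Velocity estimates exclude displacements touching the
axial image border (edge-clipped masks bias the centroid), and the cohort
speed statistic averages per-cell means, not frames, so slow cells are
not over-weighted. Constant images, empty masks, zero-intensity
normalization denominators, nuclei touching the image border, and rings
with no signal all raise typed errors; the cohort driver records per-cell
failures without aborting the cohort. A constriction narrower than one
pixel still yields a one-column mask. Fisher p-values are clamped to 1
when every table qualifies (float-sum guard).

## Problem sizes

The packaged validation runs the cohort sizes of the calibration targets:
300 free-running tracks for the speed law, 400 transits per constriction
width, 200-cell forced-outcome cohorts for the slowdown and enrichment
dichotomy, 400 stills per lamina condition, and 200 bead transits — about
2,500 rendered movies end to end, chosen so the full recovery suite
completes on a single CPU in well under half an hour.

## Known limitations

- The slowdown recovery carries a residual bias of ≈ −0.006 (ratio
  units) from frame-quantized window edges; it is an order of magnitude
  below the cohort sampling error at the validation sizes.
- Circularity on hard binary masks (as produced by the segmenter)
  underestimates the disk identity by ~10–15% because of staircase
  perimeter inflation; comparisons should stay within one mask source.
- The enrichment flag is undefined for cells with fewer than three
  pre-entry frames (very fast cells at 2-minute sampling); these are
  excluded from enrichment denominators and reported as such.
- One cell per movie, one constriction per channel; the first resolved
  engagement is the only one scored.
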