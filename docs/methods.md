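# Methods

This note records the models implemented in `fluotrack`, the parameter
choices that matter, what the synthetic scenes do and do not emulate, and the
numerical decisions taken where the design was genuinely open.

## Background model and silhouette detection

Each pixel's background is an exponentially weighted running mean μ of the
detection-channel intensity (levels 0–255).  Classification is a fixed
threshold on the absolute deviation, foreground ⇔ |I − μ| > T; the update
μ ← (1 − α)μ + αI is applied **selectively**, to background-classified pixels
only, so a detected animal never bleeds into the model.  Two consequences are
worth knowing:

- The classification is deliberately *not* variance-scaled.  T is a
  user-tuned constant (the `preview-threshold` command exists to pick it);
  an optional per-pixel running variance is tracked with the same selective
  rule purely as instrumentation.
- Selective updating protects only pixels classified foreground.  Sub-
  threshold *fringes* of a silhouette are classified background and are
  absorbed at rate α, so an animal that stays put for many frames on a
  low-contrast rig is slowly eaten by the background.  This is inherent to
  the selective scheme; the mitigation is a sensible α (see below) and the
  fact that real animals relocate.  The update uses the raw classified mask,
  not the morphologically opened one: the opened mask would unprotect the
  thin fragments that erosion removes.

Initial background: `max(ceil(sample_fraction · n_frames), 2)` frames at even
intervals (first and last always included), averaged per pixel.  The 1%
default is calibrated to hour-scale recordings (1,080 of 108,000 frames);
on second-scale test clips 1% means two frames and leaves half-intensity
blob ghosts in the mean, so short fixtures should sample 10–25%.

Masks are cleaned by opening with the 3×3 square element (erosion then
dilation, out-of-image treated as background, so edge-touching regions are
eroded from the border side).  Components are 8-connected by default —
thin diagonal fragments of one silhouette should not split — configurable
to 4.  The size filter keeps components with `size ≥ min_size` (a component
of exactly the threshold size survives).  Centroids are unweighted means of
member pixel coordinates: the silhouette is binary, so its center of mass is
geometric.

Defaults: `threshold 50`, `alpha 0.05` (slow drift expected over multi-hour
dark-chamber recordings), `sample_fraction 0.01`, `min_component_size 5`,
detection channel green.

## Fluorescence binning and time courses

Per component and channel, member pixels are partitioned into four intensity
bins with edges (0, 64, 128, 192, 256) — equal-width quartiles of the level
range, the only parameter-free choice; the edges are configurable.  Counts
and intensity sums per bin are exact integer partitions of the component's
pixels and total intensity (asserted as invariants).  Cross-sample
comparison uses the highest bin populated in every sample, extended downward
until all samples are represented; an empty sample is an error.

Time courses pool the selected-bin intensity sums of all components in both
views by **summation** per frame (the pooling rule when combining views was
an open choice; summation keeps the quantity extensive in the number of
animals and pixels).  Frames with no detection contribute 0 by default — an
animal still long enough to join the background is conservatively
under-counted — with a `skip` option that excludes such frames from the
minute means.  Per-minute values are plain block means over
`round(60 · frame_rate)` frames, trailing partial minute included.

LOESS is implemented in-package: at each point the `max(ceil(span·n),
degree+2)` nearest neighbors are fit by weighted least squares with tricube
weights in scaled distance, and the local polynomial is evaluated at the
point.  Defaults span 0.1, degree 2.  Degree-2 local fits are not available
in the usual Python smoothers, which fit local lines; at degree 1 the
implementation agrees with `statsmodels.lowess` to 1e-6 (cross-checked in the
suite).  The smoother reproduces polynomials up to the fitted degree exactly.

`detect_onset` is an added convenience (onset is conventionally read off the
smoothed plot): first minute exceeding baseline mean + k·SD and staying
above for ≥ 10 consecutive minutes.  Because LOESS-smoothed noise is
autocorrelated over the span window, the sustained-excursion filter is weak
and k defaults should be conservative (k = 5 in the simulated experiments).

## Camera model and triangulation

Cameras are 3×4 projection matrices up to scale; the optical center is the
dehomogenized right null vector (SVD).  Matrices whose left 3×3 block is
singular are rejected (no finite center exists).  Back-projection uses the
pseudo-inverse pre-image, oriented to positive homogeneous depth.
Triangulation solves the 2×2 normal equations of the two perpendicularity
conditions in closed form and returns the segment midpoint plus the
closest-approach distance ("gap"); the gap is kept in all outputs so users
can filter frames with poor calibration or centroid noise.  Rays with
|d₁ × d₂| ≤ 1e-9 are rejected as degenerate.  Pixel convention throughout:
u = column, v = row, origin top-left, 0-based; matrix files are three rows
of four whitespace-separated reals, `#` comments allowed.

A direct-linear-transform fit from ≥ 6 known 3D↔2D correspondences is
provided for building synthetic rigs and fixtures; it is plain homogeneous
least squares without normalization refinements and is not a calibration
tool.

## Pairing and motion statistics

Pairing is strictly by frame index (the rig is frame-synchronized); a frame
yields a 3D point only with exactly one retained component per view.
Missing and ambiguous frames are skipped and tallied by reason.  Multi-animal
3D is out of scope — cross-view correspondence of identical blobs is
undefined — but multi-animal fluorescence is fully supported.

Speeds divide Euclidean displacement by elapsed time; consecutive points
separated by more than `max_frame_gap` (default 30) frames break the series
instead of producing spurious slow segments.  A heading change is an
interior track point whose incoming/outgoing displacement angle exceeds
`angle_threshold` (default 90°); zero-length displacements are skipped.  The
angle-threshold definition of turning was an open choice and the threshold is
configurable.

## Synthetic scenes

The generator renders isotropic Gaussian-profile spots (peak level over the
background, additive, clipped to 0–255) moving along known paths inside a
cylindrical chamber, through two pinhole cameras placed at twice the chamber
height from the axis, 90° apart, focal length framing the cylinder at ~85%
of image height.  Defaults: 320×240 at 30 fps, chamber radius 10 and height
30 world units (vial proportions), blob peak 200, background 10, noise SD 2,
spot width half the projected blob radius floored at 1.5 px so the
above-threshold footprint spans ≥ 9 pixels.  Rendering is deterministic per
config (seed included); out-of-view blobs are rendered blob-free in that
view and flagged in the ground truth.  An optional per-frame peak schedule
emulates reporter induction.

What the scenes do *not* emulate: animal-shaped, anisotropic silhouettes;
occlusion by chamber walls or other animals; reflections; lens distortion;
illumination drift; autofluorescent debris.  Passing tests therefore
demonstrate the correctness of the algorithms on their stated model, not
detection robustness on real rigs — thresholds on real recordings must still
be tuned per lighting conditions.

## Simulated experiments and problem sizes

`fluotrack.experiments` packages two study designs used by the suite and the
acceptance script:

- **Helix recovery** — 600 frames, 320×240, two views: detection rate among
  frames with the blob visible in both views, mean 3D error (reported as %
  of the 20-unit chamber diameter), and mean-speed error against the analytic
  arc length.  Typical results: 100% detection, ~0.2% mean error.
- **Induction** — 240 "minutes" at 6 frames per minute (sparse 0.1 fps
  emulation keeping multi-hour designs tractable), 100×80 px, blob peak
  following a logistic from level 40 to 200 with midpoint at minute 120 and
  scale 8; motion is a bounded random walk so the animal relocates between
  sparse frames.  The per-minute G3+G4 series is smoothed (span 0.1,
  degree 2) and scanned for onset (baseline 60 min, k = 5).  The control
  variant holds the peak at level 48 with noise SD 0.5 over background 10, so
  every rendered pixel stays below level 64 and bins G2–G4 read exactly
  zero, emulating an uninduced reporter whose signal sits entirely in G1.

## Numerical choices and degenerate inputs

- Intensity levels are integers 0–255; noise is clipped, not wrapped.
- Rotation matrices must be orthonormal to 1e-9; optical-center residuals
  are checked against matrices normalized to unit Frobenius norm.
- LOESS windows where the farthest neighbor ties at distance 0 fall back to
  the local mean; all-zero tricube weights are floored at 1e-9 to keep the
  normal equations solvable.
- `aggregate_per_minute` with an empty series returns an empty series;
  onset detection on a flat series returns none.
- Batch outputs embed a provenance header (`# fluotrack <version>
  config_hash=<sha1 prefix>`); the hash covers analysis parameters but not
  paths or chunk size, so re-chunked runs of the same analysis share a hash
  (and chunking invariance is testable on the emitted files).

## Known limitations

- Single-animal 3D only; no identity maintenance or touching-animal
  separation (no watershed).
- No mixture-of-Gaussians background, shadow handling, or adaptive
  thresholds; slow low-contrast animals can be absorbed (see above).
- No lens-distortion model, bundle adjustment, or epipolar-gated matching;
  calibration quality enters only through the reported gap diagnostic.
- Absolute fluorimetry is out of scope: intensity sums are camera-level
  quantities, not calibrated fluorophore amounts.
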