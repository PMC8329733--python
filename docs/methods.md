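# Methods

This note documents the models, numerical contracts and design choices
behind `lumenmorph`, in the spirit of a methods section: what is computed,
under which assumptions, and what the synthetic validation does and does
not establish.

## Local thickness

At an interior point *p* of a binary object, local thickness is the
diameter of the largest disk (2D) / sphere (3D) that contains *p* and fits
entirely inside the object; local lumen radius is half of it.  The
continuous definition is discretised as follows:

- candidate disk centres are foreground **pixel centres** *q*;
- the disk radius at *q* is *r(q)*, the Euclidean distance (in µm, using
  the per-axis pixel spacing) from *q* to the nearest **background pixel
  centre** — exactly the Euclidean distance transform of the mask;
- a pixel *p* is covered by the disk at *q* when ‖p − q‖ ≤ r(q)
  (physical distance, boundary inclusive), and

  thickness(p) = 2 · max{ r(q) : foreground q with ‖p − q‖ ≤ r(q) }.

The inclusive boundary makes single-pixel objects well defined (thickness
2 px).  Image borders are treated as background by default — an inscribed
disk may not extend past the image; a flag exposes the alternative
convention because real analyses differ on this point.

Two implementations coexist deliberately. `brute_force_thickness` is a
literal O(N²) evaluation of the formula and is the *normative* semantics;
`local_thickness` computes identical values efficiently (exact EDT →
disk sweep painting each candidate disk, keeping the per-pixel max of r²,
with a per-radius offset-stencil cache, O(N·k) for mean disk area k).
Exact equality — not approximate agreement — is the contract, and it is
engineered, not hoped for: both paths evaluate every distance through one
shared squared-physical-distance helper and compare in squared form;
the fast path derives r² from the EDT's nearest-background *indices*
re-evaluated through that same helper.  The test suite checks bitwise
equality on all 512 3×3 masks in a 7×7 background, on random 16×16 and
8×8×8 masks (with frozen golden values from the oracle's first verified
run) and on anisotropic spacings.  Redundant-centre pruning was considered
and rejected: the plain sweep already meets every runtime target at this
package's problem sizes, and pruning would reintroduce a floating-point
tie-safety question for zero benefit.

With a radius cap (used for in vivo 3D reconstructions; 10 µm in the
default configuration), r is clipped before the sweep — provably the same
as clipping the final map at 2·max_radius, which the tests also verify.

Anisotropic spacing is handled by computing all distances in physical
units; no resampling.

## Phantom generator

The study conditions the package targets are: branched, ~1 µm-radius
tubular lumina whose actin walls carry quasi-periodic transverse bulkhead
stripes with spacing on the order of the lumen diameter, versus several-µm
spherical cysts without stripes; replicate structure of 3 independent
experiments × 4 images per condition; fluorescence images with
Poisson–Gaussian camera noise.  Defaults encode exactly these conditions:
`tube_radius` 1 µm, `bulkhead_spacing` 2 µm (≈ one diameter),
`cyst_radius` drawn from 7–9 µm, `n_experiments` 3, `images_per_condition`
4, wall-contrast SNR 10 for the segmentation-grade datasets.

Geometry. Tubes are **capsules**: a centerline segment dilated by the tube
radius, with hemispherical caps; branched tubes are unions of capsules.
The capsule choice is load-bearing: every interior point lies within one
tube radius of the centerline, so the largest inscribed circle through any
interior point has exactly the tube radius — the ground-truth radius field
is uniform and exact rather than approximate (a flat-ended tube would
violate this near its corners).  Cysts are spheres, radius field equal to
the cyst radius.  2D images are mid-plane sections of this 3D geometry;
the in vitro analysis stage is per-2D-image.

Rendering. The actin channel is background intensity everywhere, interior
intensity inside the mask, wall intensity on the mask's inner boundary
shell (`wall_thickness`, default 0.2 µm — cortical-actin scale), and
stripe intensity on transverse bulkhead planes (`bulkhead_thickness`,
default 0.3 µm — a ridge-like membrane plate, not an infinitely thin
line), restricted to the outer `bulkhead_depth` (default 0.7) of the
cross-section and alternating the side they project from.  Bulkheads are
intensity-only: they never remove pixels from the mask, mirroring the
biology — bulkheads cross the lumen but never seal it into chambers
(`bulkhead_depth < 1` is enforced).  Bulkhead positions are multiples of
the spacing jittered by a Gaussian of sd `bulkhead_jitter · spacing`; the
spacing distribution of real bulkheads is not quantified anywhere, so the
jitter default (0.1 in dataset designs) is an acknowledged free parameter.

Noise. Shot noise as Poisson resampling at `noise_poisson_scale` photons
per intensity unit, then additive Gaussian read noise — the standard
fluorescence camera model.  Dataset SNR is defined as wall-to-background
contrast over the Gaussian sd.

Determinism. The whole dataset is a pure function of (design, master
seed); per-image seeds derive from (master seed, condition, experiment,
image) via `numpy` SeedSequence, and bit-identical reproduction is tested.

What the phantoms do *not* emulate: optics (no PSF beyond Gaussian blur),
cell bodies and off-target actin structures, curved or entangled
canaliculi, depth-dependent shading, time dynamics.  Passing tests on
phantoms therefore demonstrate the *correctness of the computation* under
known geometry and noise — not segmentation robustness on real tissue.

## Segmentation

Preprocessing is Gaussian smoothing (`smooth_sigma`, default 0.2 µm,
converted per axis through the spacing) followed by rolling-ball
background subtraction (`ball_radius`, default 10 µm) with clipping at 0.
These are documented stand-ins for the wavelet denoising and shading
correction used in interactive workflows; the smoothing is the denoiser
(it provably raises wall-to-background SNR on phantoms), the rolling ball
removes additive backgrounds and makes Otsu-after-preprocessing invariant
to constant offsets.

Thresholding is Otsu by default (the original workflow does not state its
rule — a free parameter, exposed along with a fixed-threshold mode), then
morphological closing (0.2 µm), hole filling, connected-component
labelling with the permissive convention (8-connected in 2D, 26 in 3D,
favouring lumen continuity) and removal of objects under `min_size`
(default 1 µm² / 1 µm³ — excludes single-pixel noise while keeping
sub-canalicular fragments).  A constant image yields an empty label map,
not an error.

The interactive "pause for verification" of macro-based workflows is
replaced by `apply_mask_correction`, which restricts labels to an external
binary mask, splitting and relabelling as needed — same effect,
scriptable and testable.

The rescue filter keeps objects whose fractional overlap with a binary
GFP channel is **at least** 0.70 — the boundary is inclusive by reading
"minimum 70 %" literally, and the comparison carries an absolute 1e-9
slack so that a 7-of-10-pixel object is never lost to float rounding.

## Histogram statistics

Per-object radius histograms (uniform bins, default 0.25 µm over
[0, 10 µm]; the bin width is a free parameter, the 10 µm range matches the
radius cap) are normalized to unit mass; values at or above the top edge
fold into the top bin (they arise only under the cap).  Image level:
weighted sum with wᵢ = Aᵢ^(3/2), renormalized — this discards differences
in the total amount of apical membrane between images.  Experiment level:
unweighted mean over that experiment's images.  Study level: unweighted
mean over experiments, per-bin SEM = sample SD across experiments / √n.
The two-level averaging makes experiments the unit of replication: an
experiment with one image weighs the same as one with four.  Images with
zero objects are excluded from the experiment mean (a zero histogram would
violate unit mass) and logged.

"Percentage of lumina above t µm" defaults to **mass mode**: 100 × the
histogram mass in bins whose lower edge is ≥ t (bins are half-open, so an
edge-aligned threshold is unambiguous; misaligned thresholds are realigned
to the nearest edge with a logged warning).  Whether the original
statistic was mass- or object-based is not stated anywhere, so an
**object mode** (fraction of objects whose maximum local radius exceeds t)
is computed as well, and result tables label the mode explicitly.

## Bulkhead periodicity

Per object: skeletonize (2D only — the stripe pattern is an in vitro,
per-image observable), take the longest path through the skeleton
(double-Dijkstra; exact on trees), resample at one-pixel arclength steps,
and average the actin intensity over the transverse cross-section
(perpendicular to the local tangent, restricted to the object) at each
step.  Objects with elongation < 2 or degenerate skeletons return a
not-tubular sentinel — cysts are excluded by construction.

Detection: subtract a running median (window ~ n/4, odd), autocorrelate,
smooth the autocorrelation lightly (Gaussian, 1.5 lags) and take the first
positive-lag peak, refined to sub-sample precision by a parabola through
the peak and its neighbours.  An object `has_stripes` iff

1. that peak's prominence ≥ `min_prominence` (default 0.2), **and**
2. the periodic component's amplitude, √(2·ac[lag]) · sd, modulates the
   profile by at least `min_modulation` (default 0.05) of its baseline
   (the median of the trend).

The modulation gate exists because the normalized autocorrelation is
scale-blind: on stripe-free noisy tubes the detrended residual is tiny in
absolute terms (≈1 % of baseline) yet its autocorrelation wiggles can be
prominent, which made a prominence-only rule flag ~30 % of stripe-free
tubes at SNR 5.  True stripes modulate the transverse-mean intensity by
14–21 % on phantoms; the 0.05 default sits well between the two
populations, and both thresholds are dimensionless, so the result is
invariant to intensity offset and scale.  Measured on phantom tubes
(radius 1 µm, spacing 2 µm): spacing recovered within one sample step at
jitter 0–0.1, 0/100 false positives on stripe-free tubes at SNR 5;
accuracy degrades with jitter (≈3 steps median error at jitter 0.2) —
quasi-periodicity genuinely blurs the autocorrelation peak.  The
autocorrelation (not a spectral argmax) is used because the profiles are
short and only quasi-periodic.

## Pipeline and problem sizes

The orchestration layer chains preprocess → segment → (GFP filter) →
thickness → radius → histograms → two-level averaging → threshold stats →
(periodicity), writing TIFF rasters and tidy CSVs with fixed float
formatting so that re-runs are byte-identical; an effective-config YAML
records every parameter actually used.  Physical units (µm) appear in all
user-facing numbers; pixels exist only inside rasters.

The validation suite runs the full study at 0.2 µm/pixel on 384² canvases
(5 objects per image, 3 experiments × 4 images × 2 conditions, SNR 10)
and the periodicity studies at 0.1 µm/pixel on single-tube images — sizes
chosen so the whole suite and the acceptance script each complete in a few
minutes on one CPU while keeping ≥10 pixels across every tube radius.

## Known limitations

- The brute-force oracle is O(N²) and intended for ≤ ~64² / ~24³ grids.
- Exact oracle/fast-path equality is guaranteed bit-for-bit; with strongly
  anisotropic spacing, equidistant-background ties could in principle
  resolve differently at the last ulp (never observed in testing).
- Centerline extraction assumes a mostly tree-like skeleton; small cycles
  are traversed by the double-Dijkstra approximation.
- The modulation gate presumes stripes are localized intensity structures
  on a roughly uniform baseline; a dense sinusoidal pattern at a few
  percent modulation would be rejected.
- Periodicity is 2D-only; 3D skeletons are out of scope.
- Segmentation defaults (Otsu, min_size, connectivity) are documented free
  parameters, not values inherited from the original interactive workflow,
  which never recorded them.
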