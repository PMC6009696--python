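# Methods

## The %radial distance statistic

A chromosome territory's position is summarized as the fraction of the
nuclear radius — along its own direction — at which its centre sits.  With
nucleus centre *N*, territory centre *C*, and *B* the intersection of the
ray *N→C* with the nuclear boundary, %RD = 100·|NC|/|NB|.  The statistic is
scale-free (uniform rescaling of the voxel size cancels exactly) and uses
the boundary distance *along the territory's own ray*, so elongated nuclei
do not bias territories lying along the long axis.  It is a centre-based
statistic: territory shape and volume enter only through the centroid.  An
alternative family of methods (normalized erosion shells) is deliberately
out of scope.

Both centres are **unweighted (binary-mask) centroids** — the geometric
centre of the thresholded object, not an intensity-weighted centre.  All
coordinates are physical micrometres with voxel centres at
(i + 0.5)·voxel_size, array axis order (z, y, x); anisotropy is handled
entirely by this scaling.

## Segmentation

Per-channel thresholding with Otsu's method by default; fixed and
fraction-of-max thresholds are available for reproducibility studies.  The
nucleus is the largest 26-connected component of the blue channel after 3D
hole filling (holes are filled for the nucleus only, never for
territories); a mask touching the frame border is flagged truncated.  Two
refinements matter in practice:

* **Territory thresholds are computed within the nucleus mask.**  A paint
  territory occupies a small fraction of the frame; Otsu over the whole
  stack degenerates into splitting the background mode.  Restricting the
  histogram to nucleus voxels keeps the threshold on the signal/background
  boundary.
* **No-signal guard.**  If the resulting foreground covers more than 25 %
  of the nucleus volume the channel is treated as signal-free and yields no
  objects — a real territory (two homologs ≈ 7 µm³ of a ≈ 160 µm³ nucleus)
  never approaches this, whereas a threshold placed inside pure noise
  does immediately.

Territory objects are connected components above `min_volume`
(default 0.5 µm³, suppressing noise speckles), clipped to the nucleus mask
by default (whether boundary-straddling voxels should count is genuinely
open; a flag disables clipping), sorted by volume and truncated to
`max_objects` (default 2 — one per homolog in a diploid nucleus; each
homolog contributes an independent measurement, so *n* counts territories,
not nuclei).

## Boundary intersection

B is found by marching from *N* along (C−N)/|C−N| in steps of half the
smallest voxel dimension, sampling the nucleus mask by **trilinear
interpolation** and linearly interpolating the 0.5-level crossing between
the straddling samples.  Treating whole voxels as in/out instead would make
the ray exit at the voxel staircase and bias |NB| low by up to a voxel —
with 0.34 µm axial voxels that alone is worth ~2 %RD.  The residual
boundary error is bounded by roughly half the coarsest voxel along the ray
direction (measured: ≤ 0.04 µm isotropic in-plane, ≤ 0.14 µm along the
axial direction).  Blur can push a measured centroid marginally past the
interpolated boundary; %RD is then clamped to 100 and the event logged.

Medians are ordinary sample medians (mean of the middle pair for even n).
Bin edges are left-closed, [0,20), …, [80,100], so 20 counts in the second
bin and 100 in the last.  The Mann–Whitney U test uses exact enumeration
when both samples have ≤ 8 untied observations and the tie-corrected
normal approximation (midranks, continuity correction) otherwise; U is
reported for the first sample.  Values are pooled across replicates before
medians and tests.  Shift tables report Δ = median − median(reference),
'+' toward the periphery; CSV output rounds %RD to 2 decimals alongside a
full-precision column.

## Synthetic scenes

Nuclei are axis-aligned ellipsoids (default semiaxes 3.2 × 4.0 × 4.0 µm in
a 28 × 96 × 96 frame at the 0.105/0.34 µm voxel): real nuclei are
irregular, but an ellipsoid makes the boundary intersection analytic and
hence the whole recovery loop exactly checkable.  Territories are filled
ellipsoidal blobs (default semiaxes 0.8 × 1.0 × 1.0 µm, ≈ 3.4 µm³).  The
**ground-truth fractional position is defined by the same ray construction
the measurement uses**: a blob requested at fraction f is centred at
N + f·|NB|·d, so recovering 100·f is a closed loop rather than a
comparison of two different definitions.  Blobs that would cross the
boundary at high f are shrunk to fit by default (the applied size is
recorded in the truth; a strict mode raises instead).

Rendering applies, in order: anisotropic Gaussian blur specified in µm and
converted to per-axis voxel sigmas (default σ = 0.4/0.2/0.2 µm — a
moderate confocal-like PSF, not an optics model), a constant background
(default 5 % of dynamic range), Gaussian or Poisson noise (default
Gaussian σ = 2 % of range), and quantization clipped to [0, 2^depth − 1]
(default 8-bit).  Identical parameters and seed give bit-identical stacks.
No intensity statistics of real acquisitions were available, so noise
defaults were chosen for testability: strong enough that thresholds and
centroids are exercised under perturbation, weak enough that the
measurement's own error dominates.  Measured on this generator, %RD
recovery at the default settings has mean absolute error ≈ 0.6 points and
|bias| < 0.1 points over f ∈ {0.2 … 0.8}; error grows monotonically with
blur and noise and degrades sharply once blur smears territories into the
background (σ ≈ 1 µm) or noise approaches the signal scale.

What the generator does **not** emulate: irregular nuclear shapes,
chromatin texture, spectral bleed-through, multi-nucleus fields, or
optics-accurate PSFs.  Passing recovery tests therefore validates the
measurement machinery, not robustness to every property of real
micrographs.

## Expression simulation and summaries

The simulator plants, per chromosome, a silent fraction (FPKM ≤ 1 in all
conditions; default 0.4) and per-condition up/down deregulation fractions
among the transcribing genes — defaults emulate a strongly deregulated
chromosome-1-like target (8 % up + 8 % down) against a ~9 % background on
others, 500 genes per chromosome.  Transcribing FPKMs are log-normal
(offset above 1); deregulated genes receive |log₂FC| = 2 + |N(1, 0.5)| so
every planted call clears the threshold, background genes N(0, 0.3).

Summary conventions: "transcribing" is FPKM **strictly** > 1, evaluated in
the reference condition by default (`any_condition` widens it — the
anchoring condition is not dictated by the problem).  Deregulation is
|log₂FC| ≥ 2, boundary inclusive; the threshold is exposed because "2-fold
(log₂)" phrasing is ambiguous between |log₂FC| ≥ 2 and ≥ 1.  Percent
deregulation divides deregulated by transcribing counts **without
intersecting the two sets** (a strict mode exists); chromosomes with zero
transcribing genes report missing, not 0.  Enrichment normalizes
per-chromosome deregulated counts by the direction's total and sums to
100 % by construction.  Pooling over several conditions counts a gene once
if deregulated in any of them; per-condition mode is the default.
Fold-change bin edges are configurable with no canonical default.

## Envelope profiles

One scan line per nucleus through the mask centroid, by default along the
mask's major axis (orientation is not dictated; `angle="random"` with a
seed supports robustness runs).  Boundary crossings are located on the
bilinear mask occupancy (0.5 level) and the endpoints inset half a pixel
inside, so the end samples read nuclear intensity rather than the
edge's background mixture.  Intensities are sampled by bilinear
interpolation at n (default 101) evenly spaced points and positions
rescaled to [0, 1]; nuclei of different diameters are thereby resampled to
a common axis before averaging.  "Peripheral intensity" is the mean of the
two profile endpoints; dividing both conditions by the reference
condition's value maps the reference periphery to exactly 1.0.  The
peripheral/interior ratio compares the outer `rim_fraction` (default 0.1)
of positions at both ends against the central band; it reaches the
simulator's rim contrast only when the rim spans the whole band.  No
background subtraction is applied by default.  Intensity comparisons use
the pooled-variance Student's t test (Welch behind a flag); two identical
zero-variance samples report (0, 1).

The 2D simulator draws circular nuclei with a rim of controlled
rim/interior contrast plus Gaussian noise — it emulates envelope vs
nucleoplasmic staining patterns, not real chromatin texture or irregular
outlines.

## Pipeline and reproducibility

A run is one validated config (unknown keys rejected; a missing reference
condition fails before any computation).  The global seed expands into
per-scene seeds via `SeedSequence([seed, condition_index, scene_index])`,
so serial and parallel execution agree and a rerun is bit-identical.  The
manifest records the config snapshot, package version, and per-scene
thresholds, object counts and clamp events, so every CSV row traces back
to a scene entry.  Demo problem size is 12 nuclei per condition —
deliberately small; medians at this n carry several points of sampling
noise, which the Mann–Whitney p-values make visible.

## Known limitations

* Single nucleus per stack; no multi-nucleus field segmentation,
  deconvolution or chromatic-shift correction.
* Centre-based %RD says nothing about territory shape or volume changes.
* The boundary is as good as the nucleus mask: heavy blur or noise moves
  the Otsu surface and with it |NB|.
* Synthetic validation bounds errors under the generator's assumptions
  (ellipsoidal nuclei, symmetric blobs); real, irregular nuclei can add
  segmentation error that no test here measures.
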