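# Methods

`pvmra` is a desk-scale synthetic re-creation of a paired pulmonary-vein (PV)
MR angiography experiment: a non-gated, motion-corrupted "conventional"
protocol is compared against a cardiac-gated, 5x-undersampled protocol with
compressed-sensing (CS) reconstruction, using a quantitative vessel edge
sharpness metric and paired statistics. Clinical data are out of reach, so
every input is generated by the phantom module; the package's claims are
therefore about *mechanisms and orderings* (which protocol yields sharper
edges, how the metric relates to a known edge), never about reproducing
clinical sharpness magnitudes, which depend on scanner, anatomy and reader
contours.

## Phantom

A subject is a 3D intensity grid (default 1.5 mm isotropic) containing:

- **Vessels**: straight tubes along the readout axis. The radial intensity
  profile is plateau `I` (default 100) inside `r - w/2`, background `b`
  (default 10) outside `r + w/2`, and a *linear ramp* across the edge width
  `w` (default 2 mm). Linear edges are chosen because their 20–80% transition
  length has the closed form `L = 0.6 w`, giving an analytic oracle for the
  sharpness metric.
- **Atrial blood pool**: an ellipsoid at intermediate intensity (60) with a
  ramped edge, so the background is not empty.
- Structures blend as `b + max_s((I_s - b) * ramp_s)`, which keeps every
  isolated edge an exact background-to-plateau ramp (an additive blend would
  distort the ramp foot and bias the oracle).

Rendering is done on a 3x supersampled grid and box-averaged down, so
fractional edge widths are represented. Note the box average itself widens an
edge: the 20–80% length of a ramp of width `w` convolved with a voxel box of
width `v` stays exactly `0.6 w` only while `v <= 0.4 w`. Oracle tests
therefore render at 0.3 mm; on the 1.5 mm study grid a `w = 2` mm edge
measures ~0.75 /mm rather than the asymptotic 0.833 /mm, which is irrelevant
for the paired comparisons (both arms share the grid).

The default phantom has four vessels ("left/right superior/inferior", radii
4.5–5 mm) on a 128x128x48 grid; a thin-slab variant (8x128x48) is the default
for the pipeline and tests. Per-subject anatomical variation is a seeded
jitter of vessel centers (±1.5 mm) and radii (±5%).

## Acquisition model

Per coil: `k_c = F(blur(x) * S_c) + n`, with `F` the centered unitary 3D FFT
(DC at `floor(N/2)`; Parseval holds exactly), `S_c` smooth complex coil
sensitivities normalized to root-sum-of-squares 1 (default 6 coils), and `n`
complex Gaussian noise with std `sigma` (default 1.0, i.e. 1% of the vessel
plateau) in image-intensity units. The undersampling mask applies to the two
phase/slice-encode axes; the readout axis is always fully sampled.

Motion artifacts of the non-gated first-pass protocol are collapsed into a
single surrogate: a directional Gaussian blur (default FWHM 6 mm along the
phase-encode direction, i.e. 4 voxels), applied exactly in the Fourier domain
(`exp(-2 pi^2 sigma^2 (k.d)^2)`). A spatially-truncated kernel would differ
only below 1e-3 of the signal. This surrogate reproduces the *kind* of
degradation (anisotropic edge blurring) but none of the ghosting, timing or
contrast-dynamics failure modes of real first-pass imaging — passing tests
show the pipeline ranks blurred vs gated imaging correctly, not that it
models respiration.

## Undersampling design

The pattern over the `(n_y, n_z)` plane keeps a fully sampled `32 x 19`
center block, never samples outside the elliptical window inscribed in the
grid (closed boundary, semi-axes `n_y/2`, `n_z/2`, centered on DC), and keeps
a uniform random subset of the remaining window lines so that the sampled
count is `round(N_ell / R)` with `R = 5`. No variable-density taper is used.
At the on-scanner geometry (`214 x 60`), `N_ell = 10065`, 2013 lines are
sampled, and the acceleration is 5.0 w.r.t. the window and 6.3 (truncated to
one decimal) w.r.t. the whole k-space. One fixed seed defines the single
pattern reused for all subjects. Acquisition ordering sorts sampled lines by
angle about DC (atan2 on the offsets), then radius, then raw index — a
deterministic total order whose within-segment k-space jumps are roughly half
those of a random order.

The matrix size after FOV/voxel rounding is not uniquely defined (320/1.5 is
not an integer); fixtures use 214x60 but the dimensions are plain parameters.

## Reconstruction

- **Zero-filled baseline**: per-coil centered inverse FFT of the masked data.
- **Coil combination**: B1-weighted `sum(conj(S_c) x_c) / max(sum |S_c|^2,
  1e-8)` (complex), or root-sum-of-squares (magnitude).
- **Patch thresholding**: reference patches (4x4, or 4x4x4 in 3D mode) on a
  stride-2 grid (the last corner is always included so every voxel is
  covered); for each reference, the 8 most-similar patches within a 16-voxel
  search window (L2 distance, candidate stride 2, the reference itself always
  in its own group) are stacked; an orthonormal DCT within patches plus a DCT
  across the group is applied; coefficients below `tau * max|image|` are
  hard-thresholded; overlapping estimates are averaged uniformly. Distances
  are computed for all window offsets at once via box-filtered squared
  difference maps, so the step is fully vectorized.
- **Iteration**: starting from the combined zero-filled image, alternate
  thresholding and data consistency (project through coils to k-space,
  restore measured values at sampled lines, invert, recombine). The
  per-coil replacement makes the projection idempotent and exactly consistent
  at sampled lines. `tau` decays geometrically from 0.1 to 0.01 over 10
  iterations; in the `tau -> 0`, fully-sampled limit the loop reproduces the
  zero-filled image to numerical precision.

The block size, search geometry, transform and schedule are this package's
own defaults (chosen once for desk-scale runtimes and stable convergence on
piecewise-smooth phantoms); no attempt is made to replicate any proprietary
implementation. On the default slab fixture at R = 5 the CS reconstruction
roughly halves the RMSE of the zero-filled image and raises measured vessel
sharpness on every vessel.

## Sharpness metric

Inner and outer contours bracket each vessel edge (ground truth in fixtures:
concentric circles at `r - w/2 - m` and `r + w/2 + m`, margin `m = 1.5` mm,
72 vertices). Each outer vertex pairs with its nearest inner vertex;
zero-length segments are discarded. Profiles are sampled at 10 points/mm by
bilinear interpolation in the contour plane (voxel centers at
`(index + 0.5) * spacing`, 0-based), with both endpoints extended by 1 mm so
the plateau/background extremes are captured. With `T_min/T_max` at 20%/80%
of the profile's range, `L` is the distance from the *last* falling crossing
of `T_max` to the *first subsequent* falling crossing of `T_min` walking
outward (bright lumen to dark background), sub-sample positions by linear
interpolation; sharpness is `1/L` and the vessel value is the mean over
retained segments.

Decisions where the procedure is underdetermined: profiles walk outward; the
last-80/first-20 rule makes the measurement robust to plateau ripples;
segments are rejected (not fatal) when flat — range below 5% of the image's
1–99 percentile range — or without a monotone transition, and a vessel
reports a value only if at least half its segments are retained. Because the
thresholds are relative, the metric is exactly invariant under affine
intensity rescaling.

## Statistics

Paired t-test on per-subject differences (`t = mean(d)/(sd(d)/sqrt(n))`,
sample sd, two-sided p, df `n-1`). Wilcoxon signed rank with the drop-zeros
convention and mid-ranks for ties; `W = min(W+, W-)`; the two-sided p is
exact by enumeration over all sign assignments (a subset-sum convolution over
doubled ranks) for effective `n <= 12`, else the tie-corrected normal
approximation without continuity correction — the study-sized case (n = 19,
ordinal scores with many ties) lands in the approximation regime while unit
fixtures stay exact. Quality scores use the 4-point ordinal scale; summaries
report mean, sample sd, the percentage of scores >= 3, and per-score counts.
Significance is read at p < 0.05 throughout.

## Problem sizes and determinism

The shipped experiment uses 5 synthetic subjects on the thin-slab phantom
with 6 coils and 10 CS iterations (about 4 s per subject per arm); a
19-subject configuration reproduces the clinical cohort's report shape when
wanted. All randomness (pattern, coils, jitter, noise) derives from one base
seed, so reports are byte-identical across reruns.

## Known limitations

- Straight tubes only for ground-truth contours; curved centerlines render
  but require user-supplied contours.
- The blur surrogate is stationary and directional; no through-plane motion,
  ghosting, or contrast-timing failures.
- The sharpness metric is evaluated on one mid-slab plane per vessel.
- `kspace` files use NumPy `.npz` containers rather than a bespoke binary
  format.
- No SENSE/GRAPPA solver: the conventional arm is emulated by full elliptical
  sampling plus blur, which isolates the image-quality mechanism being
  measured rather than replicating the clinical sequence.
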