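# Methods

This note records the models, parameter choices, and numerical details
behind each pipeline stage, and what the synthetic-data experiments do
and do not establish about real data.

## Doppler hemodynamics

**Model.** A transvalvular jet is represented by its velocity envelope
v(t) ≥ 0 (mm/s), uniformly sampled, with ECG R-peak times annotating
cycle starts. Cycles are half-open intervals [Rᵢ, Rᵢ₊₁) so the partition
of the recording is disjoint and exhaustive. When a recording extends at
least one median R-R interval past the last annotated peak, a terminal
cycle of median length is appended; this makes a clip whose R-peaks mark
cycle *starts* yield exactly one cycle per peak.

**Peak velocity.** The per-cycle peak is the maximum envelope sample.
The trace-analysis path first applies a short median filter (default
2 ms) to the envelope: the raw maximum of a noisy envelope is biased
upward by the extreme-value statistics of the noise (about +8% at noise
of 5% of the peak and 8 kHz sampling), while the 2 ms median filter
reduces the bias to under 2% and shifts a clean sin²-shaped peak by less
than 0.2%. The bare `peak_systolic_velocity` operation defaults to no
smoothing so that noise-free recovery is exact to sample resolution.

**Mean pressure gradient.** The simplified Bernoulli relation
ΔP [mmHg] = 4·v² (v in m/s) — the standard clinical-echo convention —
is time-averaged over the ejection phase. Ejection is detected as the
longest contiguous run of samples above 10% of the cycle maximum
(`detect_ejection_window`), which excludes diastolic near-zeros; for the
average, the detected run is then extended outward along monotonically
decreasing velocity shoulders so the whole flow lobe contributes. The
extension matters: for a sin² lobe, averaging only over the
above-threshold core would overstate the mean gradient by ~26% relative
to the full-lobe value (the conditional mean of sin⁴ given sin² > 0.1 is
0.471 versus 3/8 overall). On noise-free traces the extension reaches
the true lobe boundaries, so the average matches the closed form
1.5·Vpeak² (in m/s) to discretisation error. Under noise, the extension
stops near the threshold crossing and the gradient acquires an upward
noise bias; the gradient is therefore best interpreted on smoothed
envelopes (the trace-analysis default).

**Aggregation and severity.** Cycle metrics average (unweighted) into
image summaries; image summaries average (unweighted) into mouse
summaries — counts are reported but not used as weights, since the
source protocol states counts ("three images", "~100 cycles") without a
weighting rule. A mouse is hemodynamically severe when its peak velocity
strictly exceeds 1320 mm/s; the threshold is the 95th percentile of peak
velocity in an established hyperlipidemic reference model, so a value
exactly at the boundary is not called severe.

## Trichrome colorimetry and morphometrics

**Color model.** Classification runs in bi-hexcone HSL (H in [0,360)
degrees, S, L in [0,1]), implemented directly (scikit-image ships HSV,
not HSL). Stain classes are closed boxes in HSL; hue intervals with
lo > hi wrap through 0°, which the red cytoplasm window (250°–25°)
requires. Window interiors may not overlap, but shared boundaries are
allowed — the two default windows meet at H = 250° — and a boundary
pixel goes to the first matching window in configuration order.
Background is any ROI pixel matching no window (in practice near-white
or desaturated pixels); area fractions divide by non-background ROI
pixels only. ROI membership uses pixel centers (scan-line polygon
rasterisation).

**Thickness.** Mean leaflet thickness = mask area / length along the
cusp. The cusp length is the longest geodesic path through the skeleton
of the leaflet mask, measured as a polyline subsampled every 5 px (which
suppresses the length inflation of rasterised zigzag paths, ~20% on a
rotated bar otherwise) and extended at both ends by the local
half-width from the distance transform, since skeletons stop about half
a thickness short of the tips. On a 200×20 px bar the estimate is
19.9 px and changes by ~3% under a 30° rotation. A user-supplied
centerline polyline can replace the skeleton path. Output is in pixels;
physical units are the caller's scaling.

## Immunofluorescence quantification

**Foreground.** Two-cluster fuzzy c-means on the ROI intensity
histogram, fuzziness m = 2, tolerance 1e-5, ≤ 300 iterations, centers
initialised deterministically at the 25th/75th intensity percentiles.
For m = 2 and two clusters, membership > 0.5 is equivalent to being
nearer the bright center, so the pixel rule reduces to a midpoint
threshold between the converged centers. A constant ROI is rejected as
degenerate.

**Nucleus splitting.** Watershed on the inverted Euclidean distance
transform, restricted to the foreground, with markers from h-maxima
suppression (h = 2 px) after Gaussian smoothing of the distance
transform (σ = 1 px; unsmoothed, ragged foreground boundaries seed
spurious maxima and oversplit elongated nuclei). Objects under 25 px are
discarded. Remaining clumps are handled by concave-point separation:
contour points whose interior angle exceeds 210° over a 7-point contour
window are concavities (one representative per contiguous stretch); an
object with at least two is cut along the shortest chord between
concavities that stays inside the object and leaves two parts ≥ 25 px,
for at most two passes (the operation is then a fixed point). All of
h, σ, the minimum area, the angle and the window are config-exposed;
the defaults suit ~10–16 px nuclei at 20× magnification.

**Marker rules.** The positive threshold is the median marker intensity
within the leaflet ROI, with strictly-greater positivity; the positive
mask is therefore exactly invariant under any strictly increasing
intensity transform. Area-fraction markers (αSMA, phospho-ERK) report
positives over all leaflet pixels. Nuclear markers (Runx2) report the
fraction of segmented nuclei whose within-nucleus positive fraction
strictly exceeds 0.5. Note that on a continuous intensity distribution
the median rule pins the positive area fraction at exactly 0.5
regardless of signal; the rule is informative only when a tissue
background level dominates the ROI (ties at and below the median), which
is the regime real stained sections and the generator both occupy.

## qPCR ΔCt

Technical replicates are averaged arithmetically per sample/target;
undetermined (non-amplifying) wells are dropped with a warning. ΔCt
subtracts the geometric mean of the two housekeeping Cq values — the
geometric mean is taken of the Cq values themselves, a literal reading
of the normalisation described for the assay. Amplification efficiency
is assumed 2.0 (no standard curves), so relative expression is
2^(−ΔΔCt) against the reference-group mean; group statistics always run
on untransformed ΔCt.

## Test-selection engine

A comparison is parametric only if **every** participating group has
n ≥ 7 and passes the D'Agostino–Pearson omnibus K² test (scipy's
`normaltest`) at α = 0.05; the n < 7 rule is applied per comparison
because the source protocol does not distinguish per-group application.
Groups of n < 8 cannot be K²-tested at all (the skewness z-score needs
n ≥ 8) and short-circuit to non-parametric via the size rule. Branches:
t / Mann–Whitney for two groups, one-way ANOVA + Tukey HSD /
Kruskal–Wallis + Dunn for three or more, one-sample t / Wilcoxon
signed-rank for paired change scores against zero. Dunn's post-hoc uses
the standard rank-sum z with tie correction and Bonferroni adjustment
over all pairs (no suitable implementation ships with the installed
stack). Degenerate variance in a parametric branch falls back to the
rank-based branch with a logged warning. All tests are two-sided;
summaries report mean ± SEM. Null simulations (2000 replicates per
branch at n = 10) put each branch's type-I error — family-wise over
pairs for the post-hoc branches — within 0.05 ± 0.02.

## Synthetic data: what it does and does not show

The generator is the package's test bed, not a physics simulation:

- **Doppler** traces are sin² ejection lobes (chosen so the mean
  gradient has the closed form 1.5·Vpeak², from mean sin⁴ = 3/8) with
  zero diastolic flow, exact R-peaks, and additive Gaussian noise
  truncated at 0. Defaults: heart rate 465 bpm (the study's reported
  anaesthetised average), ejection 32% of the cycle, 8 kHz sampling.
  Real envelopes have variable waveshape, R-R variability, and
  spectral-broadening noise that is not additive white.
- **Trichrome** leaflets are painted by sampling HSL uniformly inside
  each class window shrunk by a margin (10°, 0.08, 0.03) large enough
  that 8-bit RGB quantisation cannot push a pixel across a boundary, so
  pixel classification is exactly invertible; class pixel counts are
  exact by largest-remainder rounding. Real sections have stain
  gradients, out-of-window hues and spatially correlated texture.
- **Fluorescence** fields place elliptical nuclei (semi-axes 5–8 ×
  3.5–5.5 px) without contact except for the requested number of
  touching pairs, built as overlapping ellipse pairs (center distance
  0.8 of the combined major axes) whose union exhibits the two concave
  junction points the splitter targets. Marker coverage per nucleus is
  exact (a half-plane cut through the pixel set); diffuse stain is laid
  down as contiguous patches (thresholded smooth random field) so its
  painted area survives blur. The DAPI channel gets the optical blur
  (σ = 1 px); the marker channel is rendered sharp by default so planted
  area fractions stay exact. A uniform tissue autofluorescence level
  inside the leaflet, with marker-excluding (dimmer) nucleus interiors,
  reproduces the regime in which the median threshold is meaningful.
- **Cq tables** are i.i.d. normal per sample/target.

Passing recovery tests therefore demonstrates correctness of the
*computations* under controlled conditions (count recovery within ±5%
at 100 nuclei / 10 touching pairs, positivity within ±0.05, stain
fractions within ±0.02, peak velocity within 3% under 5% noise), not
robustness to the full variability of real histology or ultrasound.

## Problem sizes and reproducibility

Recovery experiments use 100-cycle traces (≈13 s at 465 bpm), 192×256
trichrome images, 384×384 fluorescence fields with 100 nuclei, and
cohorts of 8 mice/group; null calibrations use 2000 test replicates and
50 replicate studies. All randomness flows from explicit integer seeds:
generators take a seed per call, and a study derives per-mouse,
per-modality seeds deterministically from one root seed
(`numpy.random.SeedSequence` spawn keys), so repeated runs are
byte-identical.

## Known limitations

- The ejection-window rule (10% of cycle max, monotone extension) is a
  declared convention; the original envelope-analysis script is not
  described in enough detail to reproduce its windowing exactly.
- Severity classification depends on a threshold imported from a
  different mouse model; the package treats it as a fixed constant.
- The concave splitter cuts along straight chords and at most twice per
  object; triple clumps or heavily overlapping nuclei can remain merged.
- Leaflet thickness assumes an elongated, roughly tubular mask; on
  compact blobs the skeleton path is short and the estimate is closer to
  a diameter than a thickness.
- No efficiency correction, inter-plate calibration, or outlier-well
  handling beyond dropping undetermined Cq values.
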