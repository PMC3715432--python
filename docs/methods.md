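# Methods

## The measurement problem

Dual-colour 3D DNA-FISH marks two fosmid probes flanking a gene locus in
fixed tissue sections; super-resolution (SIM-class) stacks of DAPI-stained
nuclei then allow two per-nucleus readouts:

* **Chromatin compaction.** In interphase nuclei the mean squared physical
  distance between two genomic points grows linearly with their genomic
  separation, so the squared 3D inter-probe distance d² (µm²) at a fixed
  probe separation g (kb) is a direct compaction statistic: larger d² at the
  same g means decompacted chromatin.
* **Nuclear radial position.** The fractional radius f of a locus is the
  shortest distance from the probe signal to the nuclear periphery in the
  image plane where both are in focus, divided by the nuclear radius (half
  the broadest distance across the nuclear cross-section). f = 0 at the
  periphery; f = 1 is attainable only at the centre of a circular section.

Tissue-section nuclei are not spherical, which rules out volumetric nuclear
segmentation; the radial measurement is therefore deliberately 2D, made in
the single z-slice containing the position probe's centroid (automating the
manual "sharp focus" criterion), while d is fully 3D.

## Generative model (synthetic cohorts)

No public raw data accompany this kind of measurement, so the package ships
a ground-truthed generator whose defaults mirror the study design: two or
more tissue regions/conditions, **3 embryos per region and 50 nuclei per
embryo** (one rendered field per embryo × region), with all randomness a pure
function of (configuration, seed).

**Chain model.** The inter-probe displacement is isotropic Gaussian with
per-axis variance c·g/3, the minimal model consistent with the linear
d²–genomic-distance law: E[d²] = c·g exactly, with c the compaction
coefficient (µm²/kb) and g the genomic separation (kb). Defaults: c =
0.0015 µm²/kb (compact) vs 0.0030 (two-fold decompacted), g = 65 kb — at
g = 65 kb this gives mean d² ≈ 0.1–0.2 µm², i.e. d of a few hundred nm,
the scale at which such probe pairs separate in embryonic nuclei. The
fosmid-separation range exercised in recovery tests is g ∈ {60, 80, 100,
120} kb.

**Radial model.** Fractional radius is drawn from a Beta(a, b) family
(flexible peripheral/central biases) or from the `uniform_volume` reference
— a point uniform in a sphere, for which P(f ≤ x) = 1 − (1 − x)³ in closed
form; the latter is the analytic oracle for recovery tests.

**Placement.** Nuclei are ellipsoids (default semi-axes (1.4, 2.2, 1.8) µm
with ±12 % jitter and random in-plane rotation — flattened, non-spherical,
as in neuroepithelium) laid out on a jittered grid with ≥2.2 µm clearance.
The pair midpoint is placed so that the *in-slice* fractional radius at the
midpoint's z equals the radial draw — the same definition the measurement
uses — with the exact point-to-ellipse distance inverted along a random ray.
The midpoint's z-offset from the equator is scaled by (1 − f) so that f = 1
is the 3D nucleus centre (a locus measured as central should not sit at a
z-pole). The displacement is then drawn from the chain model and resampled
(up to 100 times) if a probe would leave the nucleus; a midpoint so close
to the boundary that nothing fits (radial draws near 0) is redrawn.
Residual edge truncation biases mean d² by ≲1–2 % at the default
separation-to-radius ratio and leaves a small deficit of measured f in the
lowest few percent of the range; recovery tolerances account for both. For
strongly elliptical cross-sections the sampled f may exceed the attainable
in-slice maximum (minor/major axis ratio); the midpoint is then placed at
the slice centre and the attained value recorded as ground truth.

**Imaging.** Voxels default to SIM-like (z, y, x) = (0.125, 0.04, 0.04) µm
(the acquisition system's voxel size is not public; these are plausible
stand-ins, configurable). Probe spots are Gaussians with PSF sigma (0.15,
0.05, 0.05) µm; the DAPI channel is the smoothed ellipsoid interior at 60 %
of spot amplitude. Detection is additive: constant background (100 counts)
plus Gaussian noise (sd 100), spot amplitude 1100, i.e. SNR =
(amplitude − background)/noise_sd = 10 by default. Probe channels can be
offset by per-channel (y, x) shifts to emulate chromatic misregistration;
the analysis undoes them with predetermined shifts, as in acquisition
practice. No photon-statistics or SIM-reconstruction artefacts are
modelled — the generator calibrates recovery of geometry and statistics,
not photorealism, so passing tests certify the measurement and inference
chain, not robustness to reconstruction artefacts in real SIM data.

## Image analysis

**Spot segmentation.** Per ROI and channel: Gaussian pre-filter (sigma
1 voxel — a symmetric kernel leaves the spot's intensity centroid unchanged
while suppressing single-voxel noise), then Otsu thresholding of the 256-bin
subvolume histogram. On large ROIs the single Otsu cut lands between the
two halves of the background noise distribution (they dominate the
between-class variance), so the threshold is recomputed on the
above-threshold intensities until the foreground occupies ≤2 % of the ROI
(≤6 passes). Foreground voxels are 26-connected; the component with the
greatest integrated intensity is kept (robust when a second allele clips
the ROI edge), and the centroid is its intensity-weighted mean voxel
position in calibrated µm (a binary-centroid mode exists for sensitivity
analysis). Components touching the ROI border are flagged. The Otsu
objective is evaluated in exact integer arithmetic; plateaus are broken at
the floored midpoint.

**Nuclear cross-section.** The DAPI slice at the position probe's centroid
z is thresholded (same Otsu) inside the ROI expanded laterally by 4.5 µm,
enough to contain the whole cross-section; the 4-connected component
containing the probe position is kept (falling back to the largest when no
probe hint is given), holes filled, and the boundary extracted at sub-voxel
precision by marching squares.

**Measurements.** d and d² from the two 3D centroids; e = exact Euclidean
distance from the position probe's (y, x) centroid to the boundary polygon;
R = half the maximum Feret diameter (max pairwise distance over the convex
hull of the boundary); f = e/R. The position probe is the biotin-labelled
probe (`probeB`) by convention. Values of f > 1 are flagged, never clamped.
Genomic separation is the inner-end gap between the two fosmid intervals
(0-based half-open BED), matching how separations of probes *flanking* a
gene are quoted; a midpoint-to-midpoint mode is available.

## Statistics

Group contrasts use the two-sided Mann-Whitney U test (the measurement
distributions are skewed); explant-pair designs use the paired Wilcoxon
signed-rank test on per-pair medians, with per-pair Mann-Whitney tests
reported alongside. Exact p-values are computed by integer counting of the
null distribution (all rank arrangements / sign patterns) for tie-free
samples with n1+n2 ≤ 20 (U) or n ≤ 15 non-zero pairs (W); otherwise the
normal approximation with tie and continuity corrections is used, and every
report row states which. Two-sided exact p is 2·min(P(≤obs), P(≥obs))
capped at 1; the reported U is the folded min(U, n1·n2 − U). No multiplicity
correction is applied by default (contrasts are reported raw, as is usual
for per-figure tests of this kind); an optional Holm adjustment is
available. Box summaries put whiskers at the data extremes (no outlier
trimming) and use linear interpolation between order statistics for
quartiles.

Because the Mann-Whitney test depends on ranks only and squaring is
strictly monotone on non-negative distances, the p-value on d equals the
p-value on d² exactly — a property the suite checks bit-for-bit.

## Calibration choices and problem sizes

* d²-vs-g recovery regresses per-level mean d² on g **through the origin**
  (the chain law has no intercept); slope and R² are reported. Rendered
  recovery uses 150 nuclei per g level (3 embryos × 50); geometry-level
  recovery uses 2×10⁴ draws per level.
* Radial-law recovery renders 500 spherical nuclei (radius 2.5 µm, g =
  60 kb so the probe offset from the pair midpoint stays small against the
  radius) and compares measured f to 1 − (1 − x)³ by Kolmogorov distance;
  the geometry-level check uses 5×10⁴ draws.
* Type-I error (2000 replicate cohorts) and power (500 replicates,
  two-fold compaction difference plus a no-effect control locus) are
  simulated at n = 50 nuclei per group on generator-level d² samples; the
  sub-voxel centroid noise that full rendering would add (~0.01 µm against
  d ≈ 0.3 µm) is negligible for these rank-test properties, and the rank
  tests exercised are exactly the pipeline's.
* End-to-end determinism is checked by running the demo cohort (2 regions ×
  3 embryos × 50 nuclei, rendered and measured) twice and comparing
  measurement tables byte for byte.

## Numerical notes and degenerate inputs

* Point-to-ellipse distance uses the standard Lagrange-parameter root find
  (bisection, closed forms on the axes and for circles); placement inverts
  it along a ray by bisection to ~1e-6 relative accuracy.
* Otsu rejects histograms with mass in fewer than two bins ("no
  foreground"); flat DAPI slices raise "no nucleus"; a missing probe signal
  raises "no spot" with the nucleus id, and the pipeline logs the rejection
  and continues. Manifest counts always reconcile: ROIs in = measurements
  out + rejections.
* For any closed region the inscribed-disc radius cannot exceed half the
  boundary diameter, so f ≤ 1 holds for non-convex masks too up to
  numerical slop; the f > 1 flag is retained as a guard rather than an
  expected path.
* Integer channel shifts are undone exactly; fractional shifts use linear
  interpolation with the channel median as fill.

## Known limitations

* The fractional-radius orientation (f = edge distance / radius, 0 =
  periphery) follows the distribution-level usage of the original
  measurement description, whose verbal definition is ambiguous; the
  orientation matters because nuclear radii vary between nuclei.
* The nuclear "broadest distance" is measured in the same slice as the
  probe, one of two defensible readings.
* The generator emulates the *statistical* structure of tissue FISH, not
  optics: no reconstruction artefacts, no photobleaching, no overlapping or
  mitotic nuclei, no segmentation of touching nuclei. Real-data performance
  on those axes is untested by design.
* Whether one or both alleles are measured per nucleus is delegated to the
  ROI table the user supplies; the generator produces one pair per nucleus.
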