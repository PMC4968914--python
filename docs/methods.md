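# Methods

`omagflux` implements an optical-microangiography (OMAG) quantification
pipeline for peripapillary retinal-nerve-fiber-layer (RNFL) microcirculation,
from repeated complex OCT B-scans to two scalar perfusion metrics — the blood
flux index and the vessel area density — measured in an annulus around the
optic nerve head (ONH), together with the cohort statistics used to compare
normal, glaucoma-suspect and glaucoma eyes, and a synthetic phantom that
gives every stage a ground-truth oracle.

## Flow extraction

The acquisition model is a spectral-domain OCT instrument (68 kHz A-line
rate, 840 nm) recording R = 4 consecutive complex B-scans at each of 245
transverse locations; each B-scan holds 245 A-scans of 1024 axial samples
over 2.4 mm × 2.0 mm. Flow contrast is the averaged magnitude of
consecutive inter-repeat complex differences,

    flow(x, z) = 1/(R-1) * Σ_{i=1..R-1} |C_{i+1}(x, z) - C_i(x, z)|,

computed after bulk-phase compensation. Static tissue is identical across
repeats up to noise and cancels; moving red blood cells decorrelate over the
~3.6 ms inter-B-scan interval and survive. The structural channel is the
repeat-averaged `log(1 + |C|)`; the log stabilizes the dynamic range (the
scale of the structure axis is a free choice — nothing downstream depends on
it beyond monotonicity).

**Bulk-phase compensation.** Axial bulk motion between repeats adds a
near-global phase to each B-scan. We estimate one phase per adjacent repeat
pair per B-scan as the argument of the depth-summed lag-one autocorrelation
(Kasai estimator) and rotate it away, accumulating in double precision.
Estimated phases with magnitude below 1e-12 rad are treated as zero so that
already-compensated input passes through bitwise unchanged. A per-B-scan
(rather than per-A-scan) phase is the minimal estimator consistent with
removing residual axial motion; in scenes containing flow the estimate
acquires a small bias from the decorrelating voxels, which is physically
faithful — the residual static signal it leaves is exactly what the
feature-space classifier (below) removes.

**Static/flow separation.** Each voxel's (structure, flow) pair is
classified against a linear decision boundary; static-side voxels have their
flow zeroed, and zero-flow voxels are always static. The default boundary is
obtained by logistic regression (balanced classes) on a deterministic
labeled phantom generated with a fixed internal seed at first use, then
cached; boundaries can also be supplied as a `{w_structure, w_flow, bias}`
mapping from JSON/YAML. On labeled phantoms the default boundary zeroes
> 99% of static voxels while retaining > 99% of capillary-flow voxels.

## Layer segmentation

Three surfaces are found per A-scan from the structural volume, using a
derivative of Gaussian (σ = 2 samples) along depth:

* **ILM** — the first positive-gradient peak from the vitreous side whose
  height reaches half the A-scan's peak gradient ("first", not "largest":
  the RPE edge is often stronger).
* **RPE** — the most posterior local maximum of the smoothed intensity
  within 90% of the A-scan's peak brightness (the RPE band outshines inner
  layers; "deepest strong peak" makes the rule robust to a bright RNFL).
* **Posterior RNFL** — the most negative gradient between ILM and RPE.

Peak positions are refined by parabolic interpolation through the three
samples around the discrete extremum, so boundaries are reported at
half-sample interface positions: a noiseless step whose first tissue sample
is k is reported at k − 0.5 exactly. A-scans whose peak gradient falls below
25% of the volume's median peak gradient (e.g. inside the disc cup) are
flagged and filled from their nearest valid neighbor; each surface is then
5 × 5 median-filtered laterally, which also repairs the A-scans whose RPE
estimate is corrupted by big-vessel shadows (vessel stripes are narrower
than the filter's majority). Ordering ILM ≤ posterior RNFL ≤ RPE is enforced
by clipping and re-validated on every output.

The procedure is semiautomatic: sparse manual edit points can be imposed;
each edit anchors the surface exactly at its A-scan and decays as a Gaussian
(scale 3 px, compact support 3σ) so edits stay local. Edits violating the
ordering invariant are rejected.

## En face projections and montage

The RNFL angiogram is the maximum of the flow signal over the ILM-to-
posterior-RNFL slab per A-scan, after 3-D Gaussian smoothing (σ = 0.5 px
lateral and axial by default) that suppresses single-voxel noise spikes
before the maximum is taken. Pixels inside the manually drawn (or phantom-
provided) disc margin are zeroed and excluded from all metrics. The sub-RPE
structural image S_RPE is the mean of the structural signal over the 10
axial samples immediately anterior to the RPE; large retinal vessels absorb
and scatter strongly, so they appear as dark shadows there.

3 × 3 montages of tiles with 10% linear overlap are stitched by
complementary linear feathering ramps (a partition of unity, so constant
tiles stitch losslessly); three 2.4 mm tiles span 6.72 mm. The disc center
is the area centroid (shoelace) of the margin polygon; without a polygon, an
automatic fallback takes the centroid of the largest connected low-intensity
region near the image center and flags the result as automatic.

Orientation convention: x increases temporal→nasal for a right eye, y
(B-scan index) increases inferior→superior; left eyes are mirrored into this
layout before any quadrant computation.

## Vessel detection

**Big vessels** are segmented on the max-normalized S_RPE by the Phansalkar
adaptive local threshold, T = m·(1 + p·e^{−q·m} + k·(s/r − 1)) with window
mean m and SD s over a 61 × 61 neighborhood (reflected padding) and
p = 2.0, q = 12.0, k = 0.135, r = 0.5. The original formulation targets
bright nuclei; vessel shadows are dark, so the polarity is inverted — a
pixel is vessel iff its value is *below* T.

**RNFL capillaries** are bright curvilinear ridges on the flow en face,
detected by a multiscale Frangi vesselness filter: per scale σ the image is
Gaussian-smoothed and its Hessian computed by central finite differences
(the truncated derivative-of-Gaussian kernel has a DC bias; finite
differences of the smoothed image respond to constants with exactly zero,
making vesselness exactly invariant under additive offsets), eigenvalues
|λ1| ≤ |λ2| scale-normalized by σ². Bright-ridge pixels (λ2 < 0) score
exp(−R_B²/2β²)·(1 − exp(−S²/2c²)) with R_B = λ1/λ2, S = √(λ1²+λ2²),
β = 0.5 and c defaulting to half the maximum Hessian norm per scale; the
output is the maximum over scales. The pipeline default scales {1, 1.5, 2}
px bracket the ~2 px apparent capillary caliber at the default pixel pitch
(larger vessels are the shadow detector's job); the standalone filter
defaults to the generic {1, 2, 3, 4}. Binarization is Otsu's threshold on
the nonzero vesselness values, one step of binary closing (ridge junctions
and merged-vessel interiors score low on the blobness term and would
otherwise leave pinholes), and removal of connected components below 5 px.
Whether the vesselness is binarized or used as a weight is configurable;
binarization is the default.

## Annulus metrics

The measurement region is an annulus centered at the ONH with inner diameter
2.5 mm and outer diameter 3.7 mm (a 0.6 mm-wide ring, matching where
commercial devices measure RNFL thickness). With V = detected RNFL vessel
pixels ∩ annulus, minus big-vessel pixels:

* **blood flux index** = mean over V of flow / F_max, where F_max is the
  instrument's full flow-signal dynamic range (2× the maximum complex
  amplitude; fixed per configuration rather than per image, so indices are
  comparable across eyes). Unitless, in [0, 1].
* **vessel area density** = |V| / Area_Annulus, where Area_Annulus excludes
  big-vessel pixels by default (configurable), consistent with measuring
  capillary microcirculation only.

Both are reported globally and per quadrant — temporal [315°, 45°),
superior [45°, 135°), nasal [135°, 225°), inferior [225°, 315°), continuous
half-open versions of the instrument's integer-degree spans, with 0° at the
temporal horizontal meridian and angles increasing counterclockwise in the
right-eye layout. An empty vessel set yields flux 0 with an explicit
empty-region flag rather than NaN.

## Cohort statistics

Eyes with signal strength below 6 are removed before analysis (SS = 6 is
retained). Group differences use one-way ANOVA followed by pairwise
independent two-sample t-tests (pooled-variance Student by default, Welch by
flag) judged at the Bonferroni level α = 0.05/3 ≈ 0.0167 for three
comparisons. Associations with clinical covariates use ordinary least
squares with a two-sided t-test on the slope. Diagnostic accuracy is the
area under the ROC curve computed by the Mann–Whitney construction (ties
count ½), oriented so that lower flow in disease still yields AROC ≥ 0.5;
standard errors and paired AROC comparisons use the DeLong covariance
method. Two-visit reproducibility is the per-subject coefficient of
variation with the n = 2 identity SD = |x1 − x2|/√2, summarized as mean and
min–max. Mean ocular perfusion pressure uses MAP = DBP + (SBP − DBP)/3 and,
in the default mode, MOPP = ⅔·(MAP − IOP); the alternative parenthesization
⅔·MAP − IOP is selectable because the two conventions coexist in the
clinical literature.

## The phantom

The phantom renders a layered retina — vitreous (relative reflectivity
0.05), RNFL (1.0), inner retina (0.45), a 5-sample RPE band (2.0), sub-RPE
(0.45) — an optic disc (structural dimming ×0.35), big vessels (polylines
with physical radius, lumen reflectivity 1.2, multiplicative shadow below),
and an RNFL capillary bed drawn as smooth random walks painted 2 px wide
(a capillary broadened by the lateral point spread; a 1 px curve would be
narrower than any OCT PSF). The inner-retina and sub-RPE reflectivities are
equal so the RPE band is locally symmetric and its center is recoverable to
machine precision in the noiseless case.

Static voxels keep one complex value across repeats. A voxel with flux
parameter φ ∈ [0, 1] is re-drawn each repeat with phase ψ + φ·U(−π/2, π/2)
and amplitude jitter (1 + 0.3·φ·U(−1, 1)); the phase half-spread keeps the
pairwise phase difference within ±π, where |sin| is strictly increasing, so
the expected difference magnitude is strictly monotone in φ. Speckle and
system noise are additive complex circular Gaussians of scale σ_n (default
0.05 = 5% of the RNFL reflectivity in noisy scenes, a high-but-realistic
SNR regime); per-B-scan bulk phases are free parameters. Everything derives
from one integer seed; identical seeds give byte-identical cubes.

`annulus_capillary_scene` places the capillary bed so that the number of
capillary pixels inside the 2.5/3.7 mm annulus equals round(d·N) exactly for
a requested density d, by trimming the last random walk — so perfect-mask
density recovery can be asserted to machine precision. `generate_cohort`
draws per-subject layouts (density uniform in [0.08, 0.12]) and scales
capillary φ by a per-group multiplier, emulating reduced capillary flux in
disease. Cohort simulations for the power analysis use 32 × 32 × 48 cubes
over 4.8 mm with ground-truth vessel masks in the metric stage, which
isolates the flow measurement from detection error and keeps 100-replicate
studies tractable on one CPU; detection-enabled recovery is exercised
separately at 128 × 128 × 64.

**What the phantom does not emulate:** physical speckle statistics and the
axial PSF, transverse eye motion (only per-B-scan bulk phase), pulsatile or
velocity-dependent flow, vessel-wall contrast, and pathology-specific
structure (focal wedge defects, peripapillary atrophy). Passing tests
therefore demonstrate the correctness and internal consistency of the
algorithms under the stated flow model, not clinical performance on real
eyes.

## Numerical choices

* Bulk-phase correlation sums accumulate in complex128 even for complex64
  cubes; products of a value with its own conjugate then have exactly zero
  imaginary part, so identical repeats yield exactly zero flow.
* Gradient-peak ties break toward the anterior (more vitreal) index.
* Frangi Hessians via central differences of the smoothed image (see above);
  degenerate λ2 = 0 pixels score zero.
* Phansalkar local moments via separable uniform filters; the variance is
  clamped at zero before the square root; input must be pre-normalized to
  [0, 1] (the pipeline normalizes S_RPE by its maximum over valid pixels).
* Feathering ramps use weights (i+1)/(o+1) so opposing ramps sum to one at
  every overlap pixel.
* The annulus-fit check requires the full outer circle inside the image and
  raises otherwise (a single 2.4 mm cube cannot host a 3.7 mm annulus — a
  montage is required, as in the intended acquisition).
* An all-zero B-scan has undefined bulk phase: treated as zero with a
  warning. An empty vessel set in a region reports metric 0 plus a flag.

## Known limitations

* The exact algebra of the flux index is reconstructed from the surrounding
  text of the source method (mean normalized flow over vessel pixels;
  density as vessel-pixel fraction); the original printed formula is not
  machine-readable. The reconstruction is the module's contract.
* Whether the original system compensated phase per A-scan or per B-scan is
  unknown; per-B-scan is implemented.
* The feature-space classifier stands in for a proprietary predetermined
  classification map; it reproduces the stated behavior (static suppression
  with flow preservation) but not the original's exact boundary.
* The Gaussian filter in the maximum projection may have been 2-D or 3-D in
  the original; a separable 3-D kernel is used here.
* No vendor raw-format reader: cubes are imported via the documented HDF5
  layout only.
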