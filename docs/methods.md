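# Methods

This note documents the quantitative procedures implemented in `capsulezone`,
the conventions chosen where the field's practice is unstated, and what the
synthetic-data validation does and does not establish.

## Growth-pattern scoring

The tumor–liver interface of each whole-slide image is annotated as labeled
polylines (encapsulated / replacement / pushing; replacement subtypes 1 and 2
are merged on load, following consensus scoring guidelines). A slide's
percentage for pattern *p* is

    pct_p = 100 · Σ length(segments with label p) / Σ length(all segments),

with polyline length the sum of per-segment Euclidean lengths in µm.
Tumor- and patient-level percentages pool **raw lengths** across slides;
averaging slide percentages would weight a short interface as much as a long
one and is deliberately not offered. Patients whose every slide shows 0%
viable tumor (complete pathological regression) are excluded from scoring;
patient-level viability is the length-weighted mean of slide viabilities
(a pooling rule of this package — the underlying protocol does not state
one).

Conventions:

* **Predominant pattern** — argmax of the three percentages. Exact ties are
  resolved toward the prognostically worse pattern
  (replacement > pushing > encapsulated) so misclassification errs
  conservatively; the order is configurable.
* **Strata** — encapsulation: low (<33%), medium (33–<100%), high (exactly
  100%); the 33% boundary belongs to medium. Replacement: none (0%), mid
  (>0–<66%), high (66–100%).
* **Agreement** — unweighted Cohen's κ (patterns are nominal categories);
  κ ≡ 1 when both raters are constant and identical.

## Capsule zonation

Three regions are quantified per case: the desmoplastic rim (DR, annotated),
the perimetastatic liver parenchyma (PLP: the DR buffered outward by a fixed
expansion — 1500 µm for IHC/IF, 1000 µm for ISH — minus DR and tumor) and
the tumor center (TC: tumor minus DR). Portal-tract and necrosis polygons
are subtracted from DR and PLP; a case whose TC is more than 50%
necrotic (configurable) is dropped from TC quantification — the exclusion
rule is qualitative in the source protocol, the threshold is this package's.

Regions are tiled on a 25 µm axis-aligned grid anchored at the coordinate
origin. A tile belongs to a region iff its centroid lies inside the polygon
(boundary inclusive); the area-majority alternative was rejected as slower
and no better defined. Tile distance is the minimal centroid distance to the
liver–tumor interface (PLP, DR) or to the DR's inner border (TC). Because
rim and tumor dimensions vary across cases, distances are normalized per
case and zone by the **maximum raw tile distance** of that zone (for PLP
this converges to the expansion distance), giving the standardized distance

    s = 100 · d / d_max,   PLP → +s,   DR → −s,   TC → −100 − s,

so the liver–tumor interface is 0%, the full PLP width +100%, the full DR
width −100% and the full TC depth −200%. Tiles landing exactly on a
reference border are nudged inward by 1 nm so the half-open zone ranges
(PLP (0,100], DR [−100,0), TC [−200,−100)) hold strictly.

Profiles: per case, mean tile intensity in 5%-wide bins over [−200, 100];
per cohort, the mean of case means with a 95% CI computed from the t
distribution across cases (normal-based CIs are available; the choice is a
package convention), then a centered rolling mean over 5 bins that shrinks
at the edges (a trailing window is available). Empty bins propagate as
missing values and never enter smoothing denominators.

Chromogenic intensities can be unmixed by color deconvolution given
externally determined unit stain OD vectors (OD = −log₁₀ transmittance;
amounts solve the linear system; negative amounts are clamped to zero);
fluorescence channels can be corrected by subtracting the autofluorescence
channel with clamping at zero. Stain-vector estimation and raster processing
are out of scope — vectors and per-tile mean intensities are inputs.

## Portal-tract remnants

Remnant pins are compared against the two rim interfaces. The relative
distance of a pin is d_liver/(d_liver + d_tumor) ∈ [0,1] — the source
analysis names the quantity but not the formula; normalizing by the sum
makes positions comparable across rims of varying thickness. Density is
pins inside the rim polygon per mm². The A vs A+BD positional comparison is
a two-sided Wilcoxon rank-sum on relative distances: exact (full null
distribution, or complete permutation enumeration when ties are present)
for combined n ≤ 12, otherwise the normal approximation with tie and
continuity corrections; the threshold is configurable.

## Survival analysis

Endpoints are overall survival and hepatic relapse-free survival in months.
Kaplan–Meier, log-rank and Efron-ties Cox fits delegate to lifelines; a
Breslow-ties Newton solver is provided for comparison and the two agree on
tie-free data. Encapsulation enters either as stratum indicators (low as
reference) or continuously coded as pct/10, so the hazard ratio reads "per
0.1-fraction increment". Confidence intervals are Wald-type on the
log-hazard scale. No imputation is performed; records with missing model
covariates are dropped per model with a logged count. Sex is screened by
log-rank only.

## Power calculation

The two-sample normal-approximation sample size for comparing means μ_a, μ_b
with SDs σ_a, σ_b at allocation ratio r:

    n = ⌈ (z_{1−α} + z_{power})² (σ_a² + σ_b²/r) / (μ_a − μ_b)² ⌉  per group.

α is one-sided by default: the printed reference design (95/5 vs 80/15,
power 0.8, α 0.05, r = 1) yields n = 7 under the one-sided reading and n = 9
two-sided, and the reference derivation's sidedness is not stated, so the
formulation that reproduces its printed result is the default and
`sided="two"` is exposed. The returned n is minimal: the analytic power
function (the formula's inverse) verifies power(n) ≥ target > power(n−1).

## Synthetic-data generator

The generator emulates the study's structure, not its images:

* **Geometry** — the tumor is a disc (default radius 2000 µm, a scaled-down
  slide kept small so tile-level analyses stay fast; real lesions are
  cm-scale) whose boundary circle is partitioned into contiguous arcs with
  arc-length shares equal to the target pattern fractions; vertices are
  placed every 0.5° so chord-sum ratios match angle ratios to ~1e−6. The
  rim is an annulus (or annular sector) of thickness U(100, 600) µm over the
  encapsulated arcs, with both border polylines emitted.
* **Intensities** — piecewise-linear mean profiles over standardized
  distance plus Gaussian noise (SD ≈ 20% of each profile's range), NGFR/ASMA
  increasing toward the liver border and FAP peaking in the inner rim.
* **Pins** — homogeneous Poisson in the rim (default 2/mm²); subtype A+BD
  with probability expit(slope·(0.5 − relative distance)), slope 6.0 — set
  a priori so the subtype gradient is unambiguous at realistic pin counts,
  mirroring the clearly separated subtype distributions reported for human
  rims.
* **Cohort** — encapsulation ~ 100·Beta(1.2, 1.0) with point masses 0.10 at
  0% and 0.15 at 100% (capturing fully replaced and fully encapsulated
  lesions); neoadjuvant treatment (p = 0.5) shifts encapsulation by +15
  points. Survival is exponential with log-hazard β·(pct/10), default
  β = log 0.91 for OS (log 0.92 for hRFS) on a base hazard of 0.03/month
  (0.05 for hRFS), with independent exponential censoring at 0.011/month
  (≈40% censored) capped at 180 months. Viability couples to encapsulation
  through a Gaussian copula at target Spearman −0.5 (treated) / −0.25
  (naive). Clinical covariates are drawn independently of the hazard.

All draws descend from one seed through named substreams (geometry,
intensity, pins, cohort), making outputs byte-reproducible and insensitive
to adding markers.

**What passing tests show** — that the implementation inverts its own
generative model at the stated sizes: fractions round-trip to <0.5 pp,
zonal gradients are recovered from 6 noisy cases, the Cox estimator
recovers HR 0.91 per 0.1 fraction from 200 cohorts of n = 250 with correct
CI coverage, and the subtype comparison has the expected power and null
calibration. **What they do not show** — performance on real slides, where
interfaces are not arcs, rims have variable thickness and gaps, intensity
noise is spatially correlated, annotations carry human error, and hazards
are neither exponential nor exactly proportional.

## Problem sizes and numerical choices

Validation suites run at deliberately modest sizes chosen as the smallest
that make the statistical assertions stable: 50–100 slides for scoring
round-trips, 6 cases for gradient recovery, 200 seeds for Cox and Wilcoxon
calibration, n = 250–500 patients per simulated cohort. Geometry predicates
use shapely with tolerances stated inline (zone overlap < 1e−6 of the
smallest zone; polygon-vs-analytic areas to 0.5%, the discretization error
of 256-segment circle approximations). The Cox Newton solver stops at step
norm 1e−10 and raises on ill-conditioned information matrices (monotone
likelihood). Exact Wilcoxon enumeration is capped at combined n = 12.

## Known limitations

* Zone geometry assumes valid, non-self-intersecting input polygons; no
  repair is attempted.
* The PLP expansion uses a Euclidean buffer; anatomical barriers (capsule
  gaps, large vessels) are not modeled.
* The relative-distance formula for portal tracts is an interpretation (see
  above); analyses depending on its absolute scale, rather than the A vs
  A+BD contrast, should treat it as such.
* Proportional-hazards diagnostics are limited to a logged note; competing
  risks and time-varying covariates are out of scope.
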