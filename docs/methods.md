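# Methods

This note documents the models and estimators implemented in `glioshape`,
the choices made where the clinical protocol leaves the numerics open, and
what the synthetic-data experiments do and do not demonstrate.

## Boundary model

The tumor–basal-ganglia interface is treated as an open planar curve on one
axial slice. Pixel indices are (row, col), 0-based; physical coordinates
are `x = col·spacing_col`, `y = row·spacing_row` in mm; curves are
polylines in mm. The medial direction is supplied by the user as a unit
vector in the (x, y) frame — typically pointing from the tumor centroid
toward the basal ganglia; the package does not attempt anatomical
landmark recognition, slice selection, or segmentation.

**Arc extraction.** The full contour of the largest 4-connected component
is traced with marching squares on the zero-padded mask, oriented
counterclockwise, and outward vertex normals are computed from tangents of
a circularly Gaussian-smoothed copy of the contour (σ = 3 vertices) — the
smoothing stabilizes normal directions on the pixel staircase without
displacing the returned points. Vertices whose outward normal lies within
half the angular window (default 90°) of the medial hint are kept, and the
longest contiguous run by arc length becomes the medial arc. Staircase
vertices inflate polyline lengths of oblique or curved interfaces by a few
percent; descriptors quoted on extracted arcs inherit that bias, while
descriptors on analytic curves do not.

## Fractal dimension and the L/C rule

FD is the OLS slope of `log N(ε)` on `log(1/ε)` over dyadic box sizes,
after resampling the arc to 501 equally spaced points and rasterizing it at
the native pixel resolution. Protocol choices, each checked against curves
of known dimension (straight segment, circle, Koch-4 polyline with
similarity dimension log 4 / log 3 ≈ 1.2619):

* **Scales**: 2 px up to extent/8 px. Coarser grids cover the whole curve
  with so few boxes that the ±1 boundary box flattens the slope: with a cap
  of extent/4 a 512-px straight segment measures ≈ 0.952, at the edge of
  the acceptable band, and Koch-4 loses ~0.07 of its dimension. If fewer
  than 4 dyadic scales fit under the cap (small arcs), the cap is relaxed
  upward.
* **Grid phase**: 4 repeated counts per scale with the grid anchored at the
  curve's bounding box and a random phase of at most 4 px, seeded. A phase
  uniform over the full box size systematically inflates counts at coarse
  scales (each per-offset slope drops by 0.05–0.08 on Koch-4); the bounded
  phase keeps the coarse grids near the minimal cover that the box-counting
  definition intends, while still probing placement sensitivity. The four
  per-offset slopes are the replicates; their arithmetic mean, reported to
  4 decimals, is the estimate — mirroring a protocol of repeated
  semi-automatic measurements averaged together.
* The estimate of a *finite* fractal depends on the scale window: refining
  the digitization (same curve, smaller pixels) legitimately moves a smooth
  curve's estimate toward 1 and a Koch polyline's estimate toward the
  locally straight regime of its finest segments. The invariance tests therefore rescale
  curve and box sizes together.

The linear/curved rule is applied verbatim to the mean estimate:
**L iff FD ≤ 1**, no tolerance band. A digitized straight edge measures
FD ≈ 0.97 < 1 and a pixelated circular arc ≈ 1.11 > 1 under this protocol,
so the two canonical shapes land on the intended sides of the boundary.
Curvature descriptors are computed only when the label is C; for L
boundaries they are reported as absent, matching the clinical workflow.

## Curvature suite

x(s) and y(s) are fit as cubic smoothing splines of the polyline arc-length
parameter; the `smoothing` parameter (mm) is the tolerated RMS residual
(`UnivariateSpline` with `s = n·smoothing²`), default **0.25 mm**, chosen
so that a unit-spacing circle with 0.2 mm point jitter recovers |κ| = 1/r
within 10%. Signed curvature `κ = (x′y″ − y′x″)/(x′²+y′²)^{3/2}` is
evaluated at 401 uniform parameter positions and paired with the arc length
of the smoothed curve. Closed contours are wrap-padded by a quarter turn on
each side before fitting so the spline sees periodic context.

Summary conventions (the source protocol delegates these to a tracing
plugin without stating them):

* **Total / maximum / average curvature** use |κ|: a convex arc then yields
  its subtended angle as total curvature, and a full convex contour yields
  one turn (2π; verified within 2% on smooth convex masks — sharp polygon
  corners overshoot under light smoothing and need stronger smoothing than
  the default).
* **Average curvature** is the arc-length-weighted mean of |κ|. The
  half-sum-of-principal-curvatures notation this replaces is a surface
  quantity with no direct planar analogue; the arc-length mean is the
  natural planar reading and is always ≤ the maximum.
* **Curvature variation** is the RMS of the finite-difference dκ/ds using
  the *signed* κ — a clothoid with constant dκ/ds = c measures c within
  numerical error.
* **Tortuosity** is L/D with D the endpoint chord; undefined for closed
  curves, exactly 1 for collinear points.

## Association analysis

Markers are called from raw assay fractions with inclusive thresholds
(IDH1 ≥ 30% immunoreactive cells; ATRX and TP53 ≥ 10% stained nuclei;
1p/19q co-deletion ≥ 25% of probe signals; MGMT ≥ 10% mean CpG
methylation). Continuous covariates are dichotomized at the published
cut-points (age 38 y, volume 20.17 cm³, Ki-67 index 10%), stored in an
overridable dictionary. Each variable forms a 2×2 table against the shape
label with complete-case handling per variable (dropped counts logged).

The odds ratio is the cross-product of the oriented table with a 95% Woolf
log-interval; zero cells trigger the Haldane–Anscombe +0.5 correction,
flagged. **Orientation is an explicit parameter and never inferred**: the
published table is not consistent with a single reference coding (the age,
ATRX and TP53 rows reproduce with the rows swapped; the others as printed),
so the reproduction suite declares the orientation per variable. The
epilepsy row's printed OR (1.21) follows from its printed counts under
neither orientation (cross-products 1.12 / 0.89) and is excluded from the
reproduction suite. The chi-square test defaults to no continuity
correction (the published p-values do not identify the convention); Yates
is available as a flag. The collinearity screen excludes a covariate only
when all three published conditions hold — pairwise |Spearman ρ| > 0.7 with
p < 0.05 *and* VIF > 10 — dropping the member of the pair with the larger
VIF.

## Risk scores and survival

Both published models are linear predictors over binary adverse
indicators. The indicator codings are not printed in full; the package
codes **adverse level = 1** using the only dichotomizations named anywhere
in the protocol: Ki-67 > 10%, epilepsy present, TP53 mutant, 1p/19q
co-deleted, volume > 20.17 cm³, IDH1 mutant, age > 38 y, and tortuosity
above the in-cohort median. The coding map is explicit on the model object
and overridable, so alternative reference levels can be tested.

Cox fits use the partial likelihood with Efron tie handling (lifelines);
monotone likelihood triggers a light ridge fallback, flagged. Stepwise-Wald
selection is forward entry of the smallest Wald p (< 0.05 by default, ties
by declared order) with backward removal at p > 0.10 after each entry, the
path logged. Note a structural property of forward selection at these
defaults: with k independent noise candidates the probability that none
enters is 0.95^k (≈ 0.81 at k = 4), so "exactly the true covariate" is
selected in about 81% of replicates — an inherent multiplicity property of
the procedure, not an implementation artifact.

The points scale defaults to the nomogram-100 scheme
(`points_j = round(100·|β_j| / max|β|)` carrying the sign), which is
invariant under rescaling of all coefficients. The published thresholds
(23 points for Risk_L, 41 for Risk_C) cannot be reconstructed without the
original patients — the publication does not state its points construction,
and under nomogram-100 the Risk_L points range makes 23 atypical — so they
are carried as recorded metadata, never asserted. The score threshold
search scans unique score values and maximizes the Mantel–Cox statistic
subject to each side holding ≥ 10% of patients (ties → lower threshold);
the tests demonstrate, on pure-noise scores, that the log-rank p at a
searched threshold is anticonservative and must not be read at face value.

**Internal validation.** Bootstrap optimism correction refits the model on
each resample and subtracts the mean optimism `C(boot on boot) − C(boot on
original)` from the apparent C. Cross-validation is event-stratified
k-fold (default 5); held-out linear predictors give the per-fold C, and
held-out event probabilities at the horizon (from each fold model's
baseline hazard) are pooled for calibration. The observed curve is a
Gaussian-kernel weighted local-linear smooth of inverse-censoring-weighted
event indicators over predicted probability (censoring distribution from a
reversed Kaplan–Meier; subjects censored before the horizon are excluded;
bandwidth by Silverman's rule, floored at 0.01). ICI is the mean and E50
the median absolute difference between predicted and smoothed observed
probability. The calibration horizon defaults to 36 months (the
publication states none).

## Synthetic data

Shape fixtures are region indicators sampled at pixel centers without
anti-aliasing (matching binary segmentation masks), with the analytic
medial curve and closed-form descriptor values returned alongside.
Optional Gaussian jitter perturbs the returned curve (emulating tracing
error), never the mask.

Cohorts draw the shape label with P(curved) = 169/330, then each covariate
independently given shape with the published conditional frequencies (e.g.
P(age ≤ 38 | L) = 91/161); pathology columns are masked to missing at the
published subtotal rates. Continuous values are drawn uniformly on either
side of their cut-point within clinically plausible ranges (age 18–75 y,
volume 3–110 cm³, Ki-67 1–60%). PFS is exponential with hazard
`0.012·exp(β'x) /month` — a baseline chosen to put the uncoded median near
5 years — under uniform censoring over (0, 180] months, giving ≈ 60%
events at the Risk_L truth; `make_reference_cohort` instead deals exact
published marginal counts for the association suite. Two idealizations
matter for interpretation: covariates are **conditionally independent given
shape** (the real joint distribution is unknown), and the baseline hazard
is exponential. Recovery and calibration results on these cohorts
demonstrate correctness of the estimators under the generating model, not
the clinical accuracy of the published models on real patients — the
original cohort is not public, and its patient-level metrics (median PFS
difference 20.67 months, C-indices 0.67/0.84/0.63/0.81, ICI/E50, points
thresholds 23/41) are carried as metadata on the model objects.

Simulation scales used by the test-suite guarantees: coefficient recovery
at n = 2000 over 100 seeds (mean per-covariate estimate within ±0.1 of
truth; pooled 95% Wald CI coverage across the 500 covariate-by-seed
intervals within [90%, 99%]); stepwise selection at n = 1000 over 100
seeds; power and null checks at 20–30 replicates with proportionally
adjusted pass bounds.

## Known limitations

* Staircase bias: mask-derived arc lengths and curvatures carry a few
  percent of rasterization bias; sub-pixel contour refinement is not
  implemented.
* Box-counting estimates of strongly fractal curves depend on the scale
  window; the defaults are tuned for boundary arcs spanning 50–500 px.
* The calibration smoother is unweighted toward the tails of the predicted
  probability distribution and needs ≥ ~10 usable subjects.
* No 3D geometry, no OS modeling beyond KM/log-rank, no multivariable
  modeling of the shape label itself.
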