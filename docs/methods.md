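# Methods

`ecocrit` derives nutrient concentration criteria — the total phosphorus
(TP, μg/l) and total nitrogen (TN, mg/l) levels compatible with a given
ecological status class — from paired nutrient–biology observations. The
unit of analysis is a lake-year: annual mean TP and TN together with a
harmonized macrophyte Ecological Quality Ratio (EQR, ≈0 worst to ≈1
near-natural; common-metric values slightly above 1 are retained, never
capped). Status classes come from two intercalibrated EQR cut-offs, the
high/good (HG) and good/moderate (GM) boundaries; a value exactly on a
boundary belongs to the upper class. All nutrient concentrations are
log10-transformed before modelling.

## The four derivation methods

**1. Univariate type II inversion.** Because both the EQR and the annual
mean concentrations carry substantial error, the EQR ~ log10(concentration)
line is fitted by Ranged Major Axis (RMA) regression: centre both
variables, divide each by its observed range, take the major-axis slope
(leading principal direction of the 2×2 covariance) of the
range-standardized pairs, and back-scale by the range ratio. The slope sign
follows the covariance sign, the line passes through the centroid, and the
fit is exactly equivariant under axis scaling and reciprocal under axis
exchange. The criterion at a boundary EQR `E` is `10**((E − b)/m)`. The
25th/75th percentiles of the EQR-direction residuals define two lines
parallel to the fit; inverting them gives a range that brackets 50% of the
observations. Residuals are deliberately measured in the EQR direction —
RMA minimizes neither vertical nor horizontal offsets, but criteria ranges
are drawn as EQR-offset lines parallel to the fit. Before trusting a linear
fit, `check_linearity` runs a segmented (two-piece continuous) regression
over a 50-point breakpoint grid spanning the 10th–90th percentile of the
abscissa; if the two-segment model improves the Gaussian AIC by less than 4
(the conventional "substantial support" cut-off) the whole range is treated
as linear, otherwise the steeper segment is recommended.

**2. Bivariate contour intersection.** An OLS plane
`EQR = a0 + a1·log10 TP + a2·log10 TN` has, at a boundary EQR, a whole
contour line of compatible (TP, TN) pairs. The reported pair is the
intersection of that contour with the RMA regression of log10 TP on
log10 TN, i.e. the point on the contour consistent with how TP and TN
actually covary in the population of lakes. Shifting the contour by the
plane's residual quartiles gives the range pair. When one plane coefficient
is zero the construction reduces exactly to the univariate inversion.

**3. Logistic inversion.** Records are binarized at a boundary (GM: good or
better vs moderate or worse; HG: high vs good or worse) and a binomial
logistic regression of the impaired label on log10 concentration is fitted
by maximum likelihood (statsmodels Newton/IRLS, observed-information
covariance; complete or quasi-complete separation is detected — disjoint
class supports or |β| > 50 — and reported as an error since no finite MLE
exists). The criterion at probability `p` (default 0.5; 0.25 and 0.75
express more or less precaution) is `10**((logit(p) − β0)/β1)`. Bounds are
the crossings of the pointwise Wald band on the linear predictor (delta
method, 95% by default) with the horizontal line at `p`; a band that never
crosses inside the data range yields an open bound flagged in the
diagnostics and reported at the data-range end.

**4. Classification-mismatch minimisation.** For every candidate criterion
c (grid: sorted unique concentrations plus geometric midpoints) two
percentages of *all* records are computed: biology good-or-better but
concentration > c, and biology moderate-or-worse but concentration ≤ c.
The whole-dataset denominator is a deliberate choice: the two curves are
then directly comparable shares of water bodies, and their crossing is the
threshold at which regulation is "fair" (a water body is no more likely to
pass on biology and fail on nutrients than the reverse). Both step curves
are smoothed by loess on log10 concentration (span 0.75, degree 2, tricube
weights — implemented in-package since the degree-2 variant is not
available in the installed libraries); the difference of the smoothed
curves is sampled on 500 log-spaced points and every sign change refined by
bisection to 1e-4 relative. All crossings are kept: the criterion is their
mean, the range ends are the extreme crossings. A run of exact zeros
flanked by opposite signs (a tie interval of step curves) counts as one
crossing at the start of the run, matching brute-force candidate
enumeration on toy data; an everywhere-tie raises a no-intersection error
with diagnostics.

## Compilation and reporting

Per type, nutrient and boundary the driver reports the criterion of the
best regression model (highest r²/R², ties broken toward the simpler
univariate model), that model's residual-quartile range, and the
cross-method range spanning the central values of all methods that ran.
Any single method's failure (e.g. no class contrast for the categorical
methods when all EQRs sit above the boundary) is logged and the method
omitted; different boundaries legitimately support different method
subsets. HG inversions often extrapolate into sparsely populated regions
of the gradient; they are flagged `extrapolated` rather than suppressed.
Presentation rounding is 2 significant figures at ≥10 and 2 decimals below;
full precision is kept in the JSON output.

## Synthetic data and what passing tests show

The generator draws (log10 TP, log10 TN) from a bivariate normal and sets
`EQR = a0 + a1·log10 TP + a2·log10 TN + ε`, ε Gaussian, truncated below at
0 only. Defaults: n = 1000 lake-years (the order of the per-type counts in
the motivating datasets), μ = (2.5, 0.8), σ = (0.35, 0.30), ρ = 0.6, plane
(1.8, −0.35, −0.25), boundaries gm = 0.6 and hg = 0.8 (the common-metric
boundary positions are not published, so typical intercalibrated values are
adopted), and ε sd 0.18, calibrated so the population bivariate R² is ≈0.49
— the observed strength of macrophyte–nutrient relationships at this scale
(univariate r² ≈ 0.43 TP / 0.37 TN on a default draw). μ is placed so the
mean EQR (0.725) sits between the boundaries and both classes are
populated.

The analytic "true" criterion is the intersection of the noiseless boundary
contour with the *population* major axis of the log-nutrient distribution,
mirroring the bivariate estimator's construction so recovery error isolates
estimation noise. Recovery tests use ε sd 0.1 over 200 seeded replicates;
all four methods return the GM TP criterion within 15% of truth in well
over 90% of replicates. Caveats on what this does and does not show: noise
is homoscedastic (real EQRs are likely noisier near the scale ends), the
response is exactly planar (no saturation or regime shift), lake-years are
independent (no within-lake correlation or down-weighting of repeated
years), and the univariate RMA inversion is only unbiased when the
error-in-both-variables assumption roughly holds — with error purely in the
EQR and a boundary far from the centroid, a type II slope over-steepens and
the inversion drifts; under the default conditions this effect stays below
a few percent because the boundary lies close to the mean response.

## Numerical choices

- Quantiles use the linear-interpolation definition throughout.
- Collinearity guard for the plane fit: |r(log TP, log TN)| < 0.999.
- Inversion refuses non-negative slopes (direction error) and |slope| <
  1e-6 (unstable inversion); contour/line intersections require the 2×2
  determinant to exceed 1e-9.
- Segmented regression treats the breakpoint as an estimated parameter
  (k = 4 vs 2 in the AIC); exactly-linear input (SSE ≈ 0, where a Gaussian
  AIC is undefined) short-circuits to "linear over the full range".
- Loess bandwidth is the distance to the ⌈span·n⌉-th nearest neighbour;
  evaluation outside the fitted range raises rather than extrapolates.
- Logistic confidence limits use the Wald band rather than a bootstrap;
  the pointwise band reproduces the standard ±95%-limit crossing
  construction at negligible cost.
- EQR exactly on a class boundary is assigned to the upper class; binarize
  requires ≥5 records on each side by default.

## Known limitations

- The mismatch criterion is a point where smoothed empirical curves cross;
  with weak gradients curves may touch without crossing (reported as an
  error with the closest approach) or cross several times (all reported).
- Only homoscedastic Gaussian EQR noise is generated; heteroscedastic or
  bounded-scale error structures are untested.
- No mixed-model handling of repeated lake-years; each lake-year counts
  once.
- GAM-based visual exploration is out of scope; the loess smoother and the
  segmented linearity check stand in for it.
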