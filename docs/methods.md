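# Methods

## Scope and model

`fcfwer` performs familywise-error-rate (FWER) control for pixel-wise and
cluster-extent inference on 2D statistic images arising from two-group
comparisons of seed-based functional-connectivity maps. Two inferential
engines are implemented against one shared data model (per-subject map
stacks, a boolean analysis mask, pooled-variance t fields with per-pixel
degrees of freedom):

1. **Random field theory (RFT).** The null statistic image is modeled as a
   stationary smooth random field. The expected suprathreshold cluster
   count is `mu(T) = s * sum_d R_d(V) f_d(T)` with resel counts `R_d` of
   the search region `V`, Euler characteristic (EC) densities `f_d`, and a
   sidedness factor `s` (2 for a two-sided group comparison of a symmetric
   null). Cluster extents are modeled as exponential: a cluster of `k`
   pixels has tail probability `beta = exp(-lambda k)` and familywise
   p-value `1 - exp(-mu beta)`.
2. **Maximum-statistic permutation.** Balanced relabelings of the subjects
   generate the empirical distribution of the image-wide maximum (peak |t|
   or largest cluster extent at a fixed forming threshold); the critical
   value is the `c`'th largest of `M` maxima with `c = floor(alpha M) + 1`,
   and rejection requires strictly exceeding it.

All inference is applied two-tailed to the t-map regardless of the `s` used
in the threshold calculation: `s` is a modeling choice whose consequences
the audit harness measures, not a switch on the detection rule.

### EC densities

Gaussian: `f0 = 1 - Phi(T)`, `f1 = sqrt(ln 2)/pi * exp(-T^2/2)`,
`f2 = 4 ln 2 / (2 pi)^{3/2} * T exp(-T^2/2)`. Student t with `nu` dof:
`f0` is the exact upper-tail probability (regularized incomplete beta, not
quadrature), `f1` replaces the Gaussian kernel by `(1 + T^2/nu)^{-(nu-1)/2}`,
and `f2` additionally carries the factor
`Gamma((nu+1)/2) / (sqrt(nu/2) Gamma(nu/2))`, which tends to 1 as
`nu -> inf`; all three converge to the Gaussian densities in that limit
(tested to 1e-4 at nu = 1e6). The t-field cluster-*size* law retains the
Gaussian exponential form; the exact t-field size distribution is out of
scope, matching common practice.

### Cluster-extent algebra and deliberate faults

`lambda` has two forms: the full definition `mu / (s V f0(T))` and the
historical simplified form `2 ln 2 T^2 / (pi FWHM^2)`, which substitutes the
large-T tail approximation `1 - Phi(T) ~ exp(-T^2/2)/(T sqrt(2 pi))` (about
9% high at T = 3.09, the dominant source of the full/simplified gap). The
extent threshold is `k = ln(-mu / ln(1-alpha)) / lambda`, reported rounded
to the nearest integer; significance means extent >= k. Two documented
faults of an earlier toolbox are replicable by flags, so the audit can
quantify their cost: `replicate_threshold_bug` forms clusters at the
p = 0.05 threshold while computing `mu`, `lambda`, `k` at the nominal
cluster-defining p (this alone drives the FWER toward 1), and the
autocorrelation FWHM estimator's `replicate_origin_bug` adds exactly one
pixel to the estimated width.

### Smoothness and resels

The primary FWHM estimator uses forward spatial differences of the
standardized image. Their covariance matrix `Lambda` (with the small-sample
factor `(eta-2)/(eta-1)/N`, `eta` the Bartlett effective temporal dof,
`eta -> inf` giving plain moments) yields `FWHM = sqrt(4 ln 2)
|Lambda|^{-1/4}`. For white noise convolved with a Gaussian kernel this
recovers the *kernel* FWHM — exactly the parameter resel formulas assume —
verified by simulation to within 10% at 128². The moments are taken over
the common support of both derivative fields so `Lambda` is a genuine
sample covariance (`Vxy^2 <= Vxx Vyy` by construction); derivative pairs
straddling the mask boundary are dropped, not imputed. The secondary
estimator measures the width of the pooled 1-D spatial autocorrelation at
1/2; for Gaussian-smoothed fields this is `sqrt(2)` times the kernel FWHM,
so the two estimators deliberately disagree — reproducing the discrepancy
between processing pipelines that motivates treating FWHM as an assumption
to be audited rather than a known constant.

Resel counts follow the Worsley lattice approximation: in-mask pixels `P`,
orthogonal adjacencies `E`, complete 2×2 blocks `F`; `R0 = P - E + F` (the
Euler characteristic, cross-checked against a flood-fill components-minus-
holes oracle with 4-connected foreground / 8-connected background),
`R1 = (E - 2F)/FWHM`, `R2 = F/FWHM²`. These are accurate for convex
regions; no concavity correction is attempted (two-hemisphere masks with a
midline gap are exactly the regime where this is an acknowledged
approximation). Note that for a full a×b rectangle `R2 = (a-1)(b-1)/FWHM²`,
about 1.6% below the continuous `ab/FWHM²`; at FWHM 12 on 128² both
conventions give the same 79-pixel extent threshold.

Bartlett's effective dof for the correlation of two autocorrelated series is
`eta = n / sum_{|k|<=K} rho_a(k) rho_b(k)`, rectangular lag window
`K = n/4` by default (configurable; the closed-form AR(1) check
`eta/n -> (1-phi^2)/(1+phi^2)` holds within 10%), capped at `n`. Fisher z
maps are standardized as `z = atanh(r) sqrt(eta - 3)` (the alternative —
carrying the variance separately — is a notational choice; the standardized
form makes z-maps directly comparable to unit-variance fields), with `r`
clipped at `1 - 1e-7` before `atanh`.

## Numerical choices

- Pixel-threshold solving: Brent's method on `T in [1, 50]` to 1e-10; the
  lower bracket is 1 because the 2D EC density `~ T exp(-T^2/2)` peaks at
  T = 1 and `mu(T) = alpha` is only guaranteed a unique root above it.
- Cluster labeling: 8-connectivity (configurable to 4); positive and
  negative excursions are labeled separately and never merged.
- Degenerate pixels (zero pooled variance) get t = 0 with a warning;
  per-pixel subject exclusion recomputes `n_A`, `n_B`, dof per pixel rather
  than imputing.
- Ties at a permutation critical value are non-rejections (strict
  inequality). Because a subset and its complement give identical |t|
  maxima, the sorted maxima tie in pairs and the self-calibration identity
  `FWER = floor(alpha M)/M` is exact only at an odd critical rank `c`;
  at even `c` the procedure is conservative, never anticonservative.
- `mu <= -ln(1-alpha)` makes every cluster significant; `k = 1` is returned
  with a warning rather than an error.
- Global RFT quantities for t fields use the minimum dof over the analysis
  mask (conservative) when dof varies by pixel.

## The synthetic null generator

The generator emulates the statistical structure of widefield hemodynamic
cohorts under a true null: a two-hemisphere elliptical mask with a midline
gap (one 8-connected component at gap 0, exactly two for any gap >= 1,
optional rectangular holes emulating quality censoring); per-subject unit-
variance fields built as white Gaussian noise convolved with a Gaussian
kernel of known FWHM (reflective padding so edge variance stays
approximately stationary, then standardization within the mask); and AR(1)
time series with spatially smoothed innovations, started at stationarity
and standardized per pixel. One `SeedSequence` per cohort spawns
independent per-subject streams, so output is reproducible and independent
of iteration order. Defaults are chosen to represent the emulated study:
16 subjects (a typical cohort, split 8/8), 64×64 grids with ~2500-pixel
masks, field FWHM 10 px (the smoothness at which t-field RFT is
approximately calibrated), AR(1) coefficient 0.5 (strong hemodynamic
autocorrelation), frame rate 1 Hz with 300-frame scans, and
0.078 mm/pixel (implied by a 5-pixel ≈ 0.4 mm seed radius; the true pixel
pitch is not pinned down, so this stays configurable).

What the generator does **not** emulate: optical physics (spectroscopy,
vascular artifacts), nonstationary smoothness across cortex, per-subject
segmentation differences, or any true group effect. Consequently, passing
audits here demonstrate calibration under stationary Gaussian-field nulls
with t-distributed statistics — the regime where the parametric methods'
failures are *provably* due to their assumptions (dof, sidedness, bugs,
FWHM misspecification) — but say nothing about power, and real data can
only be less favorable to RFT (nonstationarity, non-Gaussian noise).

## The audit harness

`run_mass_fwer` reduces every method to a per-split yes/no test and counts
a split once no matter how many positives it contains. Method sweeps are
declarative (`MethodSpec.from_dict`), covering distribution, sidedness,
`mu` dimensionality, `lambda` form, FWHM, search region (masked vs full
frame), the threshold bug, and both permutation kinds. Results are reported
per map channel ("seed"), summarized as median and range across channels.
Permutation methods are calibrated on a split plan disjoint from evaluation
by default; evaluating on the calibration plan itself is possible and gives
the exact-self-calibration behavior described above.

Problem sizes used by the shipped studies: the cluster-count agreement
check uses 400 fields at 128²; direction checks (FWER inflation, FWHM
opposite effects, bug cost) use 300–400 splits of a 16-subject cohort at
64², where a two-fold FWER inflation is detectable at many Monte-Carlo
standard errors; the permutation generalization study uses 1000 calibration
+ 2000 evaluation splits per channel and 14 channels, reporting the median
across channels — the channel count mirrors the 14 seed locations of the
emulated study design, and the median matches its reporting convention.

## Known limitations

- Resel counts (hence all RFT quantities) are convex-region approximations;
  masks with midline gaps and holes are used anyway, as in practice.
- The exponential cluster-size law and the EC cluster-count approximation
  are high-threshold results; observed counts exceed predictions at low T
  by construction, and tests only enforce agreement at T >= 3.
- Per-pixel dof variation is collapsed to the minimum for global RFT
  thresholds (conservative); modal dof is available but not default.
- Sampled split plans draw subsets without replacement; for cohorts where
  `C(n, k)` is astronomically larger than `M`, rejection sampling is used
  and plan construction cost is O(M log M).
- The permutation engine covers subject-relabeling nulls only (no
  sign-flipping, no covariate-adjusted schemes).
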