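# Methods

This note records the model, the numerical choices, the synthetic-data
design and the known limitations of `larvahsi`, at the level of detail a
user needs to judge what the package's tests do and do not demonstrate.

## Data model and preprocessing

A survey record is one net tow: position (lon/lat), year, calendar
month, larval count N (individuals) and filtered water volume V in
(10 m)³. Density is always recomputed as C = N / V (ind (10 m)⁻³) and
never read from files. Records are binned to 0.25° × 0.25° half-open
grid cells (lower-left origin; a point on a cell boundary belongs to the
upper cell), pooling years within calendar month; the cell statistic is
the arithmetic mean of member station densities, which is stable when
station counts differ between cells.

Environmental fields (SST °C, SSS practical salinity, Chl-a mg/m³) are
2-D lat/lon arrays with a validity mask. Non-finite values, sentinel
fills (≤ −9000 by default) and negative Chl-a are masked before
compositing. Monthly composites average the valid observations per cell;
a cell valid in no input stays masked. Fields are matched to the
analysis grid by nearest-cell lookup — no interpolation, so masked
source cells never bleed into valid analysis cells. A cell missing any
of the three covariates is kept in the density table but flagged
incomplete and excluded from curve fitting.

## Suitability curves

Within a month, SI = Y / Y_max maps densities to [0, 1]; a month whose
densities are all zero has no defined SI and is rejected. The
single-factor response is the two-parameter Gaussian

    SI(x) = exp(A (x − B)²),  A < 0,

whose peak is pinned at 1 (the month's densest site is by definition
fully suitable). The optimum of a factor is the stationary point of the
curve, which is B exactly; its uncertainty is reported as the asymptotic
standard error of B from the least-squares covariance. Optima are
rounded to one decimal in formatted tables.

Fitting is nonlinear least squares **on the SI scale** — zero-SI
observations are legitimate there, whereas a log-scale fit would have to
discard them. Three starting points are tried and the lowest-SSE
solution kept: (i) a quadratic regression of ln SI on x restricted to
SI > 0.05 (the threshold is configurable; near-zero SI makes ln SI
unstable and carries almost no shape information), (ii) a narrow bump at
the best observation with width from the half-maximum spread, and
(iii) a broad curve at the SI-weighted mean of x. The multi-start
matters for sharply peaked curves, where most observations sit on the
noise floor and a single bad start can strand the optimizer in a local
minimum. The curvature is constrained negative and the center is bounded
within one data-span of the observed x range. Preconditions: at least 4
samples, at least 3 distinct x values, at least one positive SI.

### Significance test

Each fit is scored against the intercept-only null with an
F(2, n − 3) residual-sum-of-squares ratio (2 model degrees of freedom).
The model residual is the better of two single-peaked descriptions: the
fitted Gaussian itself and its quadratic linearization
SI ~ 1 + x + x². The quadratic branch keeps the test calibrated under
the null — the Gaussian family contains no free intercept, so its RSS
alone can exceed the null's and would pin p at 1 — while the Gaussian
branch makes a perfect nonlinear fit register as such (RSS 0, p 0).
Empirically, on shuffled (null) data the p-values are close to uniform
(median ≈ 0.44 over 200 seeded shuffles, ~6% below 0.05), and noiseless
Gaussian samples give p below 1e−200. n ≤ 3 raises an error.

## Combiners and surfaces

The four combiners (MAXM, MINM, AMM, GMM) act per cell on the three
single-factor SI values. The printed formulation of the arithmetic and
geometric means divides a 3-term sum by 4 and takes the 4th root of a
3-term product — apparently vestiges of a four-factor model. Because an
`as_printed` AMM can never exceed 0.75 (so "HSI > 0.8" zones are
unreachable under it), both variants are exposed: `as_printed` (default,
fidelity to the published formulas) and `renormalized` (3-term mean and
cube root). They obey exact identities — AMM_printed = 0.75 ·
AMM_renorm and GMM_printed = GMM_renorm^(3/4) — and the order chain
MINM ≤ GMM_renorm ≤ AMM_renorm ≤ MAXM, which the tests verify on random
triples. Predicted surfaces evaluate each fitted curve on its monthly
composite field and combine; a cell masked in any covariate is masked in
the surface. Zone maps use strict thresholds (high: HSI > 0.8, low:
HSI < 0.2, mid otherwise).

## Validation

Cells are split 80/20 per month (round(0.8 n) training cells per
stratum, seeded permutation, at least 5 cells per stratum); stratifying
by month prevents a global split from emptying one monthly model. A test
cell's observed SI is its density divided by the **training** maximum of
its month — normalizing by the full-data maximum would leak test
information — and is clipped to 1 since hold-out densities can exceed
the training maximum. A forecast is accurate when
|predicted HSI − observed SI| < threshold, strictly; the default
threshold is 0.4. Accuracy is reported per month × combiner together
with per-pair diagnostics. Accuracy is invariant to pair order and
non-decreasing in the threshold.

## Synthetic data

The generator produces one reproducible "study" per seed: monthly
environmental fields and a tow survey whose expected density follows a
known HSI surface built from known true curves (the package's reference
coefficient table by default).

Design. All three covariates of a month derive from a single latent
habitat coordinate w — a smooth random Fourier surface blended (weight
0.35) with a plume-like trend increasing eastward/offshore, rescaled to
[0, 1]. Each covariate is an affine transect in w, centered on its true
optimum at w₀ = 1/2 and sloped as steeply as its realistic range allows
(SST 22–25 °C in April and 28–30 °C in June–September; SSS 22–34;
Chl-a 0–10 mg/m³), with signs making SSS increase and Chl-a decrease
offshore. Along such a transect every single-factor relation is exactly
Gaussian with the true center (the other factors contribute a curvature
rescaling only), so all fifteen optima are simultaneously identifiable
from one survey, and the symmetric placement prevents noise in the
normalizing maximum from biasing fitted centers. The expected density at
a station is d_max(month) × HSI_true of its cell (true combiner:
renormalized GMM by default), times multiplicative log-normal noise
(sd 0.1 on the log scale); the filtered volume is uniform on
0.1–0.5 (10 m)³ and the count is Poisson with mean density × volume —
the minimal error structure producing the zeros and overdispersion of
real tow data. Peak densities default to 100 ind (10 m)⁻³ in April and
700 in June–September; 300 stations per month; 10% of cells are masked
per variable/month to emulate cloud gaps. All randomness flows from one
seed through fixed per-stage streams.

What the generator does **not** emulate — and what passing tests
therefore do not show: real SST/SSS/Chl-a fields are correlated through
shared physics but are *not* functionally linked along one coordinate,
so real single-factor fits face cross-factor confounding these synthetic
studies deliberately avoid; there is no temporal autocorrelation between
months, no plume dynamics, no species-specific behavior, and cloud gaps
are spatially independent rather than contiguous. Recovery results on
synthetic data are statements about the pipeline's correctness and
estimator efficiency, not about the identifiability of real-world
response curves.

Under the default study (300 stations/month, noise sd 0.1) the full
pipeline recovers fitted centers to within about ±0.1 of truth; at the
one-decimal rounding used in formatted tables, a few broad-curve optima
whose true centers sit within ~0.01 of a rounding boundary can land one
step off at this survey size (the worked example in the README shows one
such case).

## Pipeline and reproducibility

Stages (simulate, ingest, fit, predict, validate, report) communicate
through files in the run directory, so each is independently
re-runnable; tables are written atomically (temp file + rename). A rerun
with the same configuration and seed is bit-identical. Problem sizes
were chosen so a full synthetic run completes in well under a second on
one core: an 8 × 8 grid of 0.25° cells over 113–115° E, 21–23° N and
five survey months (April, June–September).

## Known limitations

* The Gaussian response cannot represent skewed or bimodal suitability;
  optima of genuinely asymmetric responses will be biased.
* The peak-pinned-at-1 normalization makes the fitted amplitude absorb
  no noise; when the observed monthly maximum is itself noisy, fitted
  widths (A) are biased slightly wide, though centers are unaffected in
  symmetric designs.
* Accuracy under the 0.4-error rule is lenient by construction; it
  separates poorly between combiners when predictions track observations
  well (as on synthetic data) and should be read comparatively, not as
  an absolute quality score.
* The `as_printed` AMM is bounded above by 0.75, so its "high
  suitability" zones (HSI > 0.8) are empty by construction; use the
  renormalized variant when zone maps matter.
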