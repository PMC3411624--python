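# Methods

## The JED statistic

For one gene and arrays i, j with post-reset summaries `y_i, y_j > 0` and
leave-one-out summaries `y_{i(-j)}, y_{j(-i)}` (array j removed from every
preprocessing step, including normalization),

    JED_ij = 1/2 ( |y_i - y_{i(-j)}| / y_i + |y_j - y_{j(-i)}| / y_j ).

Properties enforced by construction and verified by tests: symmetry in
(i, j); non-negativity; `JED_ij = 0` iff both jackknife summaries equal the
full-data summaries; the convention `y_{i(-i)} = 0` makes the diagonal
exactly 1; and the statistic is invariant to rescaling either array's pair
of summaries by a positive constant, so it reads as an average *percent*
change. JED is not capped at 1 — a relative change above 100% is reported
as is, not truncated. The associated distance is `d_ij = JED_ij` off the
diagonal and `d_ii = 0`; no triangle inequality is claimed.

The reset rule: any raw summary ≤ 0 is replaced by the smallest positive
raw summary observed for any gene on the same array ("the array floor"),
separately within each preprocessing run (full data and each leave-one-out
run uses its own floors). Zero is treated like a negative. An array with no
positive summary is a fatal error naming the array. If excluding array j
flips the sign of array i's raw summary, the reset maps it to the floor
`eps_i`, and that half of the JED becomes `|y_i - eps_i| / y_i -> 1` as the
floor vanishes — hence the characteristic banding of JED near 1/2 for pairs
with one sign change and near 1 for pairs with two. The sign-change count
per pair (0, 1 or 2) is reported alongside the JED.

## Preprocessing methods and the subset contract

Every method maps `(probe-level data, subset of arrays)` to an expression
matrix, so the jackknife driver can run any of them on the full set and on
each leave-one-out subset (A+1 runs for A arrays). Built-ins:

- **perarray** — per-gene, per-array mean of log2 PM intensities. Shares
  nothing across arrays, hence exactly JED ≡ 0; it stands in for the class
  of strictly per-array methods (e.g. MAS5), which are *not* reimplemented
  here. Summaries from any real external method can be analyzed through
  the external-summary mode instead.
- **rmalike** — quantile normalization over the chosen subset, then
  per-gene median polish; the summary is overall + array effect. It stands
  in for the class of methods that share information at both the
  normalization and summarization steps, and shows strictly positive JED
  on generic data.
- **mindep** — see below.

Conventions (fixed, declared):

- *Quantile normalization*: each column's k-th order statistic is mapped to
  the mean of the k-th order statistics across columns; ties receive the
  average of the reference values at their tied ranks. On tie-free columns
  the defining property (all sorted columns identical) and idempotence hold
  exactly; tied values get averaged reference values instead, so those two
  properties are asserted on tie-free inputs only. A single-column input
  is returned unchanged with a warning.
- *Median polish*: row-first alternating median sweeps, at most 10
  iterations, stopping when the sum of absolute residual changes falls
  below 0.01 × the mean absolute deviation of the input. The decomposition
  overall + row + column + residual reproduces the input exactly at every
  stage.
- *Log scale*: base 2 throughout; inputs are taken as already log2.

## MINDEP and its closed-form covariance

For each gene with P probes on A included arrays, a balanced two-way model
is fit by OLS:

    x_pi = mu_i + beta_p + e_pi,   e_pi ~ iid N(0, sigma^2)

The LSMEAN for array i is the array effect plus the mean probe effect —
in the balanced layout, the column mean of the gene's probe matrix — and is
invariant to the identifiability constraint (sum-to-zero probe effects by
default; reference coding available and tested to agree). The summary is

    y_i = LSMEAN_i - lambda * min_k LSMEAN_k,   lambda in [0, 1],

a pseudo-background-correction that couples the arrays through whichever
array m attains the minimum. Writing `y_i = c_i' theta` with
`c_i = coef(LSMEAN_i) - lambda * coef(LSMEAN_m)`, least-squares theory
gives

    Cov(y_i, y_j) = c_i' Cov(theta_hat) c_j,
    Cov(theta_hat) = MSE * (X'X)^{-1},  df = N - (A + P - 1).

The covariance is computed *conditional on the observed argmin array m*:
the closed form cannot account for the argmin switching between arrays
under resampling. This is a documented limitation; the simulation check
therefore uses well-separated array effects so the argmin is stable. The
closed form refers to the raw (pre-reset) summaries; the reset is a JED
convention. At lambda = 0 the summaries are pure LSMEANs — independent
across arrays (off-diagonal covariance exactly 0, diagonal MSE/P). At
lambda = 1 the argmin array's summary is identically 0; its correlations
are undefined and reported as 0 by convention, which is why the "mean
absolute correlation is nondecreasing in lambda" property is stated on
[0, 1) — the non-degenerate pairs' correlation still rises to 1/2 and the
argmin pairs' to ~0.707 as lambda -> 1. When the residual variance is 0
(an exact fit), the covariance matrix is 0 with a warning and correlations
are reported as 0. Residual sums of squares below 1e-24 of the total sum
of squares are snapped to zero so exactly additive inputs are recognized
as exact fits.

MINDEP is a reference model for relating numerical dependence (JED) to
statistical dependence (correlation), not a recommended preprocessing
method. No per-pair translation between the two exists; only the joint
trend across the weight is meaningful.

## Power under compound symmetry

Two groups of n replicates; the 2n responses are multivariate normal with
mean `X beta` and covariance `sigma^2 * Sigma(rho)` where Sigma is compound
symmetric (unit diagonal, off-diagonal rho; positive definite for
`-1/(2n-1) < rho < 1`, restricted to [0, 1) unless explicitly overridden).
The design X holds an intercept and a group column (±1 by default, -1's
followed by +1's; 0/1 optional — with ±1 coding the group means differ by
2·beta1). Both analyses are z-tests of beta1 = 0 at level alpha with known
sigma^2:

- OLS: `beta1_hat = [(X'X)^{-1} X' y]_1`, standard error
  `sigma * sqrt([(X'X)^{-1}]_11)` — the independence-assuming one — while
  the estimator's true variance is the sandwich
  `sigma^2 [(X'X)^{-1} X' Sigma X (X'X)^{-1}]_11`.
- WLS/GLS: variance `sigma^2 [(X' Sigma^{-1} X)^{-1}]_11`, which is also
  the true sampling variance, so the test is exactly sized for every rho.

Power is `P(|beta1_hat| > z_{alpha/2} * se_assumed)` under the true normal
sampling distribution. All quantities are computed from the generic matrix
formulas at run time — no hand-transcribed variance constants — and are
validated against a Monte-Carlo rejection-rate oracle (Cholesky sampling of
the compound-symmetric normal, both z-statistics per draw, binomial
standard errors). The z-statistic is invariant to affine recoding of the
group column, so the power is invariant to the analysis coding when the
data-generating means are held fixed (tested numerically). For rho ≥ 0 the
WLS power dominates the OLS power with equality at rho = 0; for large
effects both powers saturate near 1 and the gap closes again.

## Synthetic data generator

`gen_probe_data` simulates balanced probe-level log2 intensities from the
additive structure the MINDEP model assumes:

    x = baseline_g + array_i + probe_pg + delta_g * treated_i + noise,

with gene baselines uniform on (6, 10) log2 units, array effects N(0,
0.5^2), probe effects N(0, 1^2), iid noise sd 0.25, and a group effect of 1
log2 unit on the second half of the arrays for 10% of genes. Defaults
emulate a modest Affymetrix-like study (200 probesets × 11 probes × 6
arrays, HGU95-like probeset size); all randomness flows from a single seed
and outputs are bit-reproducible. The generator does not emulate scanner
artifacts, spatial effects, probe-sequence effects, non-additive probe
behaviour or spike-in designs — so passing tests establish the numerical
properties of the methods on well-specified input, not their behaviour on
real arrays (the independence contrast and sign-change banding are
structural and carry over; absolute JED magnitudes do not).

`gen_sign_change_fixture` builds two-array jackknife sets realizing exact
0/1/2 sign-change patterns, using a constant positive "floor-carrier" gene
to pin each run's array floor at a chosen value; `gen_jackknife_fixture`
wraps explicit full and leave-one-out matrices for worked examples and for
external summaries.

## Problem sizes and numerical choices

The test-suite and reproduction-script runs use desk-scale problems chosen
once: 200 genes × 8 probes × 6 arrays for the weight-0 identity (3000
gene-pair JED values; identity asserted at |·| < 1e-8, reflecting only
least-squares float noise), 5000 simulated refits for the covariance check
(agreement within 3 Monte-Carlo standard errors, normal-theory SE
`sqrt((s_ii s_jj + s_ij^2)/(R-1))`), and 200,000 draws per scenario for
the power oracle (agreement within 3 binomial standard errors at 9 grid
points). Sign-change limits use floor 1e-6 against summaries of 8, giving
JED within 1e-3 of the 1/2 and 1 limits. Ties in ranks, degenerate
layouts (single probe or array), zero-variance fits and empty subsets all
have declared behaviours (see above) with tests.

## Known limitations

- The MINDEP covariance conditions on the observed argmin array; near-tied
  LSMEANs make the closed form optimistic about stability.
- JED carries no inferential calibration: no thresholds, p-values or array
  QC use are supported, by design.
- The power scenario is an illustration of the cost of ignoring dependence,
  not a model of any real differential-expression test.
- Built-in methods are stand-ins for method *classes*; real MAS5 / RMA /
  PLIER / GCRMA / PUMA summaries should be analyzed via the external
  summary-matrix mode.
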