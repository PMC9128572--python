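# Methods

`erocio` implements and evaluates numerical observers for *joint signal
detection-estimation tasks*: given a measured image `g`, an observer must
decide whether a signal is present (by thresholding a scalar test statistic
`T(g)`) and, when it decides "present", report an estimate `theta_hat(g)` of
the signal's parameters.  Performance is summarized by the estimation ROC
(EROC) curve and its area (AEROC).  This note records the models, the
estimators, the numerical choices, and what the shipped simulations do and do
not demonstrate.

## Imaging model

All images are 64x64 (configurable) vectors produced by a linear
continuous-to-discrete operator with isotropic Gaussian point-response
functions of height `h` and width `w_m`.  Pixel centres sit at integer
coordinates 1..n per axis; images are flattened row-major.  For a Gaussian
object of amplitude `A`, width `w` and centre `r0`, the measured image is
closed-form:

    [s]_m = A h w^2/(w_m^2+w^2) exp(-||r_m-r0||^2 / (2(w_m^2+w^2))).

Measurement noise is i.i.d. zero-mean Gaussian with standard deviation
`sigma_n`.  Noise is drawn from a counter-based stream (seed, counter) so
that "semi-online" training — fresh noise on stored noiseless images each
iteration — is exactly reproducible.  The Gaussian log-likelihood is used
unnormalized (additive constant fixed at 0); only likelihood ratios enter
any computation.

## Tasks

Three studies are shipped as `TaskConfig` defaults (see
`tests/data/study_parameters.json` for the independent manifest):

1. **bke_amplitude** — amplitude estimation, zero background (SKS/BKE):
   signal width 1 at the image centre, `A_s ~ N(9, 4^2)`, `h = 16`,
   `w_m = 3.87`, `sigma_n = 40`; Gaussian utility with `sigma_u = 3`.
2. **lumpy_location** — localization on a lumpy background (SKS/BKS):
   `A_s = 6`, `w_s = 3`, location uniform on `(16, 48)^2`; lumpy model
   `Nbar = 5`, `a = 10`, `w_b = 7`; `h = 40`, `w_m = 0.5`, `sigma_n = 320`;
   quadratic (`eps1 = 100` or `200`) or l1 (`eps2 = 20`) utility.
3. **clb_width** — width estimation on a clustered lumpy background:
   signal peak amplitude 0.05 at the centre, width uniform on `(1, 6)`;
   CLB parameters `Kbar = 70`, `Nbar = 20`, `L_x = 5`, `L_y = 2`,
   `alpha = 2.1`, `beta = 0.5`, `sigma = 12`; `sigma_n = 0.33`; Gaussian
   utility `sigma_u = 3`.

Interpretation notes.  The CLB background is formed directly in image space
(no PRF) and min-max normalized to [0, 1] **per image**; per-dataset scaling
would leak information across cases.  Since no imaging system is specified
for the CLB study, the signal there is the grid-sampled Gaussian with peak
0.05 (the `w_m = 0` limit of the general signal formula).  Lump and cluster
centres are uniform over the physical pixel extent `[0.5, n+0.5]^2`; blobs
whose centres fall outside the image still contribute their in-image tails.
Signals are evaluated on the full grid without boundary truncation.

### CLB blob geometry and the fast renderer

The blob is `l(r|R) = exp(-alpha ||R r||^beta / L(R r))` where `L(v)` is the
radius of the ellipse with half-axes `(L_x, L_y)` in the direction of `v`:
`L(v) = L_x L_y ||v|| / sqrt(L_y^2 v_x^2 + L_x^2 v_y^2)` (the printed form of
the blob function is typographically ambiguous about the division by `L`;
the division is the standard CLB form and is adopted).  With `beta = 0.5`
the blob tails are so heavy that any truncation window tight enough to save
work would violate a 1e-4 per-pixel error budget, so every blob is evaluated
on the full grid.  The production renderer is a numba kernel using an
`exp(-t)` lookup table (131072 bins, linear interpolation, `t` capped at 40
where `exp(-40) ~ 4e-18`); its measured per-pixel error against the exact
numpy evaluation is ~1e-6, and the exact path is kept as the test oracle.

## EROC analysis

Utilities: Gaussian `exp(-||e||^2/2 sigma_u^2)`, quadratic `1 - ||e||_2^2 /
eps1`, l1 `1 - ||e||_1 / eps2`; the last two can be negative, so EROC curves
need not be increasing.  The curve sweeps the pooled empirical test
statistics (plus infinite sentinels) with a strict `T > tau` rule; AEROC is
estimated by the utility-weighted two-sample U-statistic with half weight on
ties (the Wilcoxon convention; tie handling is a package choice).  The
U-statistic equals the trapezoidal area under the empirical polyline to
machine precision, which the tests assert on random tied samples.
Uncertainty: a seeded nonparametric bootstrap over cases (H0 and H1
resampled independently, 2000 replicates by default, percentile 90%
interval).  The bootstrap is a package choice for the interval; the point
estimate does not depend on it.  "Statistically equivalent" in comparison
tables means overlapping 90% CIs.

## Observers

**Analytic BKE ideal observer** (amplitude task): conjugate Gaussian algebra
gives the posterior-mean amplitude and a test statistic depending on `g`
only through `s_ref' g`, with `s_ref` the unit-amplitude signal template.

**RWMH posterior samplers.**  `rwmh_bke` targets `p(theta | g, H1)` with a
Gaussian random walk (proposal std 3 for the amplitude task).  `rwmh_bks`
targets the joint posterior over `(theta, lumpy background)` using
Metropolis-within-Gibbs sweeps: one theta move, then one move of a single
lump centre (proposal std 4), with the background image updated
incrementally.  Joint all-coordinate proposals are not used: their
acceptance probability factorizes into a product over components and the
chain freezes.  The lump count is held at the realization's generative value
(no transdimensional moves); lump amplitude and width are model constants.
Chain defaults are 1000 burn-in plus 5000 kept samples — package choices;
the proposal scales are study settings.  For location tasks, chains start
from a coarse matched-filter argmax (grid spacing 2) of the mean-subtracted
image; without this approximate-MAP start a fraction of desk-scale chains
spend their whole budget searching a 32x32 support for a ~3-pixel
likelihood basin.  Initialization does not alter the target distribution.
The posterior over location is genuinely multimodal for some realizations
(a background lump can mimic the signal); posterior means then fall between
modes.  This is a property of the task, not a sampler defect.

**Utility-weighted posterior mean.**  `U(g)` is the Monte-Carlo average of
`u(theta_hat, theta_j)` over posterior samples; the hybrid observer's test
statistic is `Lambda(g) * U(g)`.

**Scanning linear observer.**  Templates are the mean background plus the
*exact* signal template per grid point (the signal model is known in closed
form; binned empirical templates were evaluated and are substantially
noisier at 4000 fit images).  The plug-in covariance is the sample
covariance of noiseless residuals — absent images about the mean background,
present images about mean background plus the true-theta template — plus
`sigma_n^2 I` added analytically (covariance decomposition).  Scores are
computed on mean-centred data: `d' K^-1 (g - b_bar) - d' K^-1 d / 2 +
ln p(theta)` with `d = g_bar(theta) - b_bar`.  The uncentred variant adds a
`b_bar' K^-1 g` term that is identical under both hypotheses and carries no
signal information; with clustered-lumpy backgrounds (mean background ~10x
the signal) it demonstrably swamps the detection statistic while leaving
the estimate unchanged, so the centred form — standard in the
scanning-linear literature — is used.  Scalar parameters scan 101 uniform
grid points over the prior support (mean +/- 3 sigma for the Gaussian
amplitude prior, with the Gaussian log-density as the prior term); locations
scan the integer-pixel lattice inside the prior box.  A 1e-6 ridge is added
only if the Cholesky factorization fails; with the `sigma_n^2 I` term it
never does in the shipped studies.

**MCMC ideal-observer approximation (quadratic utility).**  Under the
quadratic utility the ideal estimate is the posterior mean and
`U(g) = 1 - tr(posterior covariance)/eps1` exactly, so one H1 chain yields
both.  The likelihood ratio is the background-marginalized estimate
`Lambda(g) = mean_j Lambda_BKE(g | b_j)` with `b_j` sampled from
`p(b | g, H0)` by single-lump RWMH sweeps and `Lambda_BKE` computed by inner
Monte Carlo over the theta prior (shared prior draws across backgrounds;
log-sum-exp throughout).  This construction is a reconstruction of the
standard background-marginalization estimator from the MCMC-observer
literature and is validated against the BKE closed form in the tests.  It
raises an explicit unsupported-utility error for non-quadratic utilities
(for the l1 utility no such shortcut exists — the reason the hybrid method
is needed).

**Multi-task CNN (hybrid and sub-ideal observers).**  A shared block of 5x5
convolutions (leaky rectifier, slope 0.2) feeds a detection head (2x2
max-pool, dense, sigmoid) trained with binary cross entropy and an
estimation branch (further convolutions, pool, linear dense head) trained
with the negative utility; l1-utility training uses the subgradient.  The
network is implemented directly in numpy (im2col convolutions, manual
backpropagation, Adam); gradients are verified against finite differences
in the tests.  Training alternates one estimation step then one detection
step per iteration; both steps update the shared block (the plain reading
of shared weights).  Balanced minibatches justify `Lambda = p/(1-p)` from
the sigmoid output; prevalence only rescales `Lambda`, leaving rankings and
AEROC unchanged.  Architecture growth uses the 1% rule: add layers while
the validation loss (averaged over the final 10% of recorded evaluations,
to damp minibatch noise) improves by at least 1% of the shallower model's
loss — detection cross entropy for the shared block first, then the
estimation loss for the estimation block.  A `MultiTaskNetSpec.input_scale`
factor (e.g. `1/sigma_n`) is available as part of the architecture; the
reduced-scale profiles use it so that larger learning rates remain stable.

With a constant utility the hybrid statistic reduces exactly to the
sub-ideal one (`U_hat = 1`), which the tests assert case by case.

## Problem sizes and reduced-scale profiles

Full-scale training (150k-200k cases per class, 200k minibatches, 64
filters) is supported by the code but the shipped tests exercise a reduced
profile chosen as the smallest configuration on which the learnability of
the conjugate amplitude task is demonstrable: 16x16 images, one conv layer
per block, 8 filters, input scale 1/40, Adam at 3e-4, 2000 iterations of
32+32 minibatches on 2000+2000 noiseless training images.  On that profile
the trained detection head's AEROC comes within 0.05 of the analytic ideal
observer on a shared 400+400 test set.  Reduced profiles shrink sizes and
iterations only; task parameters and model equations are never changed.

The reference-observer studies run at full scale: the analytic-IO amplitude
study on 1000+1000 test cases, and both SLO studies fit on 4000+4000
noiseless images and evaluated on 1000+1000 test cases.

## What the simulations do and do not show

The synthetic generators *are* the study conditions: statistical structure
(Poisson counts, uniform/Gaussian scatter, stationary Gaussian noise) is
exact by construction, so passing tests demonstrate correctness of the
observers and estimators under the stated models — not robustness to real
detector physics (Poisson noise, blur beyond a Gaussian PRF, anatomical
backgrounds richer than lumpy/CLB textures), none of which are modelled.
AEROC values on finite test sets carry seed-to-seed spread of roughly
+-0.01 to +-0.03 (visible in the bootstrap CIs); study-level checks use
three times the published half-widths.  Known limitations: no
transdimensional background moves; the MCMC-IO is restricted to quadratic
utilities by construction; location posteriors can be multimodal and
posterior-mean estimates then degrade; the SLO covariance at 4096
dimensions from 8000 samples is noisy, and its inverse is regularized only
through the additive noise term.
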