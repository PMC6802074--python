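# Methods

## The estimation problem

Seedling-emergence experiments (and many other monitoring designs) record
only how many individuals emerged between consecutive inspections, indexed
by an accumulated covariate such as cumulative hydrothermal time (CHTT).
The observable is therefore a grid of k+1 grouping points
`e_0 < e_1 < ... < e_k` and counts `n_1, ..., n_k` per interval; the
underlying per-individual values are never seen.  Writing `t_i` for the
interval midpoints and `w_i = n_i / n` for the sample proportions, the
package estimates the density and distribution of the underlying variable
with

    fhat_h(x) = (1/h) sum_i w_i K((x - t_i)/h)
    Fhat_h(x) = sum_i w_i KK((x - t_i)/h),      KK(u) = int_-inf^u K,

with a Gaussian kernel throughout (kernel choice is second-order for
efficiency; bandwidth choice is not).  When `n` exceeds the summed counts
(not every individual emerges), weights are renormalized so all estimators
condition on the observed events; `n` still enters the bandwidth formulas
as the resampling size.

## The binning term

Collapsing an interval of width `d_i` to its midpoint removes the
within-bin spread.  Two consequences run through every formula here:

* the continuous-scale estimate used by normal-reference rules is
  `sigma_c^2 = sum_i w_i (t_i - mu)^2 + Delta` with
  `Delta = sum_i w_i d_i^2 / 12` (midpoint variance plus within-bin uniform
  variance);
* the mean of `fhat_h` is approximately `f * U * K_h`, where `U` is the
  within-bin offset, so the squared smoothing scale in density-level bias
  expansions is `h^2 mu2(K) + Delta`, not `h^2 mu2(K)`.

Every bandwidth equation that targets a density-level object therefore
solves its classical first-order condition with `h^2 mu2` replaced by
`h^2 mu2 + Delta`.  CDF-level objectives carry no such term: the midpoint
discretization error of the grouped CDF is a mean-zero sawtooth within each
bin, and smoothing averages its leading contribution away.

## Bandwidth selectors

**Density plug-in.**  `h` solves

    h^3 mu2 (h^2 mu2 + Delta) psihat_4 = R(K) / n,

which reduces to the textbook `h = [R(K) / (mu2^2 psi_4 n)]^{1/5}` when
`Delta = 0`.  The curvature functional `psihat_4 = R(fhat'')` is the
closed-form Gaussian double sum over midpoint pairs, evaluated at a pilot
`g_4` solving the analogous corrected pilot equation
`g^5 (g^2 mu2 + Delta) = -2 K''''(0) / (mu2 psi_6 n)` with `psi_6` at its
normal reference in `sigma_c` (the classical direct-plug-in ladder, one
estimated rung by default; `stages` exposes deeper ladders).

**Distribution plug-in.**  `h = [rho(K) / (mu2^2 R(fhat') n)]^{1/3}` with
`rho(K) = 2 int u K KK = 1/sqrt(pi)` for the Gaussian kernel and `R(fhat')`
estimated at the corrected pilot `g_2`.

**Bootstrap selectors.**  The grouped structure makes the bootstrap exact:
resamples are multinomial over the bins with probabilities given by the
integrals of a pilot density `fhat_g`, so the bootstrap MISE has a closed
form in Gaussian convolutions (density case) or a low-dimensional quadrature
(CDF case, integrated against `dFhat_g` over the edge range padded by three
pilot bandwidths).  No random numbers are drawn on the default path; a
seeded Monte-Carlo implementation exists purely as a cross-check and is
tested against the closed form.  Pilots: the density bootstrap rescales the
density plug-in bandwidth to the `n^{-1/9}` rate optimal for curvature
estimation (`g = h_PI n^{1/5 - 1/9}`); the distribution bootstrap rescales
it to the `n^{-1/7}` rate optimal for `f'` (`g = h_PI n^{1/5 - 1/7}`).  A
normal-scale pilot and a manual override are also available.  Minimization
runs on a log grid ((edge range)/200 to the edge range; `hn` points,
default 100) with local refinement; the distribution selector instead does
`nit` rounds of grid shrinkage (factor 0.3 per round) as its objective is
quadrature-based.

On the bundled wild-oat example these four selectors give 14.48, 19.90,
10.03 and 13.94 CHTT units (see the README's worked example); the package's
acceptance script recomputes exactly these numbers.

## Confidence bands

Sup-norm bootstrap bands: B multinomial resamples of the counts from the
empirical weights, `q` the (1-alpha) quantile of `sup_x |fhat* - fhat|`,
band = estimate +/- q, truncated to the natural range.  These bands quantify
resampling variability around the *smoothed* estimate; they do not correct
smoothing bias.  At moderate n with coarse bins the density band can
therefore undercover the true density near sharp peaks (in our simulations
at n = 300 with 12 bins, joint coverage of nominal 95% bands was about
two-thirds for the density and above 90% for the distribution function,
whose bias is second-order).  Bias-corrected and undersmoothed variants
were evaluated and did not robustly close the gap, so the simple
construction is shipped and the caveat documented here.

## Parametric overlays

Weibull and logistic families are fitted by grouped (multinomial) maximum
likelihood, `l(theta) = sum_i n_i log(F_theta(e_{i+1}) - F_theta(e_i))`,
conditioned on the grouping range, multi-start Nelder-Mead from
moment-matched seeds.  They serve as comparison curves beside the kernel
estimates, not as the primary model.

## Emergence indices

`I1 = sigma/mu` (coefficient of variation, larger better) and
`I2 = m4/sigma^4` (kurtosis, smaller better) come from the midpoint-mass
moments.  `J1 = sigma^3 int f'^2` and `J2 = sigma^5 int f''^2` (both
smaller better) use the closed-form integrated squared derivatives of the
grouped kernel density.  Because the raw double sum estimates the roughness
of `f * K_h * U`, the reported J values divide out the normal-reference
attenuation `(sigma^2 / (sigma^2 + h^2 + Delta))^{(2r+1)/2}` and use
`sigma_c` as the scale prefactor; without this the J2 of a normal sample
binned at ~0.4 sigma is underestimated by ~30%, with it both J indices
recover Gaussian truth within a few percent at n = 5000 (and within 1% on
fine grids).  Functional bandwidths come from the corrected normal-start
rule (`method="plugin"`), from minimizing a bootstrap MSE under multinomial
resampling (`"np"`), or under resampling from a normal mixture fitted to
the binned counts by EM (`"mix"`, quantile-initialized, truncated-normal
M-steps, falling back to `"np"` if EM fails).  Percentile bootstrap
intervals hold the selected bandwidths fixed across resamples by default
(`reselect` enables re-selection); degenerate resamples are dropped and
counted, erroring above 10%.

A caution on cross-grid comparisons: I1 and I2 depend only on the grouped
data, but J1 and J2 are estimated through grids of different resolution
when depths are compared, and coarser grids genuinely carry less shape
information.  The `rank_depths` helper reports the per-index winners and a
majority winner rather than forcing a single index to decide.

## Factor test

For k groups sharing a grid, `D = sum_j n_j int (Fhat_j - Fhat_0)^2 dFhat_0`
with `Fhat_0` from the pooled sample and one shared bandwidth (default: the
pooled bootstrap distribution bandwidth).  The integral is a Simpson rule
against the pooled smoothed density on a 513-point grid over the padded
edge range (Lebesgue measure available behind a flag).  Calibration: B
multinomial resamples of every group from the pooled weights, bandwidth
frozen at the observed selection (re-selection behind `reselect`);
`p = (#{D* >= D} + 1)/(B + 1)`, with the raw Monte-Carlo proportion also
reported.  Under the null the test holds its size (empirical type-I error
0.03-0.08 at alpha = 0.05 in the suite's 400-replication check) and has
high power against one-sigma location shifts at n = 100 per group.

The weights-level entry point (`bootstrap_test_weights`) accepts a
proportion matrix exactly as supplied, without renormalizing columns.  This
mirrors the standard field interface and lets published proportion tables
be replayed verbatim.

## Synthetic data

`simulate_grouped` draws from normal, Weibull, logistic or normal-mixture
truths and bins by the same left-closed convention as the data model;
draws outside the grid are clipped into the end bins (an error if more
than 1% of them, so the grid must essentially cover the support — as in
real emergence grids).  Truth handles expose exact density, CDF, moments
and index values (closed forms for normal and mixtures, quadrature
otherwise), powering the recovery, calibration and coverage tests.  The
generator reproduces multinomial sampling of a smooth truth; it does not
emulate inspection-time irregularity, overdispersion between replicates,
or non-emergence censoring, so green simulation tests speak to estimator
correctness under the stated model, not to robustness against those
features of field data.

Test problem sizes were chosen to exercise the asymptotics the claims rest
on while keeping the default suite quick: rate checks use n up to 1e5 on
fine grids, calibration checks 400 replications at B = 199, coverage
checks 500 runs at B = 500.

## Numerical conventions

* Interval convention is left-closed right-open; counts recorded at an
  inspection value are assigned to the interval whose left edge is that
  value (verified against the bundled per-cylinder vectors).  Trailing
  zero-count inspections are dropped with a warning; nonzero trailing
  counts are an error.
* All Gaussian convolution identities are exact (Hermite-polynomial
  derivatives up to order 8); quadrature appears only in test oracles and
  in the CDF bootstrap objective.
* Bandwidth equations are solved by bracketed root-finding to 1e-12;
  search-grid minimizations refine locally and widen with a warning if the
  minimizer lands on an endpoint.
* Degenerate inputs (single occupied bin, zero variance, all mass in one
  pilot bin) raise ValueError rather than returning NaN.
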