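# Methods

## Model

All estimators operate on the triplets `(x_j, u_j, nu_j)` of the `n`
results flagged for inclusion in the KCRV; results excluded for
substantive reasons stay in the study and receive degrees of equivalence,
but never influence the statistics. The common structure is the
random-effects model `x_j = mu + lambda_j + eps_j` with Gaussian errors
`eps_j ~ N(0, sigma_j)`. A finite `nu_j` declares `u_j` an *estimate* of
the unknown error scale: `sigma_j` then enters the model as a parameter
with the data term `nu_j u_j^2 / sigma_j^2 ~ chi2(nu_j)`; an infinite
`nu_j` pins `sigma_j = u_j`. In every leaf `tau` denotes the standard
deviation of the effects `lambda_j`, so dark uncertainty means the same
thing whichever distribution the effects follow (Laplace scale
`b = tau/sqrt(2)`; skew-t scale `omega = tau / sqrt(nu/(nu-2) -
delta^2 b(nu)^2)` with `delta = alpha/sqrt(1+alpha^2)` and `b(nu) =
sqrt(nu/pi) Gamma((nu-1)/2)/Gamma(nu/2)`, and location offset `xi =
-omega delta b(nu)` so the effects have mean zero; this requires
`nu > 2`, enforced by truncating the `nu` prior at 3).

## Gating tests and the tree

* **Cochran's Q** (size 0.10 by default — failing to detect dark
  uncertainty is costlier than falsely declaring it). The Q-profile
  interval for `tau` inverts the generalized statistic
  `Q(tau) = sum (x_j - xbar_w(tau))^2/(u_j^2+tau^2)`, which is strictly
  decreasing in `tau`; roots are found by bisection (bracket
  `[0, 100 max u_j]`, expanded tenfold if needed, relative tolerance
  1e-8). The interval is reported with its own matching point (the `tau`
  solving `Q(tau) = n-1`), because the DerSimonian–Laird estimate keeps
  fixed-effects weights and can fall outside the profile interval on
  strongly heterogeneous data. A traversal warning is raised when Q is
  not significant yet the interval's upper end exceeds twice the median
  reported uncertainty.
* **Symmetry** (size 0.05) uses the Miao–Gel–Gastwirth statistic on the
  raw measured values. The null distribution is a *reflection bootstrap*:
  each replicate flips independent fair-coin signs on the fixed deviation
  magnitudes `|x_j - mean(x)|` and recomputes `T` in full; the p-value is
  two-sided via `|T|`. This scheme reproduces the published p-values of
  the reference implementation on all four historical datasets where they
  are reported (0.13, 0.22, 0.007, 0.02 to within Monte Carlo error) and
  is correctly sized (empirical size 0.047 at n = 10 under a Gaussian
  null, 2000 replicates). Default 10 000 replicates; p-values are
  bit-reproducible given the seed.
* **Gaussian shape** (size 0.05) on `z_j = (x_j - median x)/u_j`.
  Shapiro–Wilk runs from n = 3; the Anderson–Darling implementation
  refuses n < 8 (an explicit error). `auto` mode uses Shapiro–Wilk alone
  below n = 8 and otherwise runs both and lets the smaller p-value
  decide, recording each — whichever test can sound the alarm does.

Tree topology: consistent results go to a shape node (Gaussian → adaptive
weighted average, else weighted median); inconsistent results go to the
symmetry node (asymmetric → skew-t effects; else Gaussian shape chooses
Gauss or Laplace effects). Ties at `p == size` retain the hypothesis.
With the Bonferroni option the three nominal sizes are all replaced by
`alpha/3` regardless of which nodes are visited — conservative, since the
tests are applied sequentially. The traversal is advisory and fully
audited; `--force-leaf` overrides it.

## Estimators

**Adaptive weighted average.** Weights `1/(u_j^2 + tau_DL^2)` with the
DerSimonian–Laird moment estimate (truncated at zero, so the plain
weighted mean is the `tau = 0` special case). Uncertainty by parametric
bootstrap (default 5000 replicates): each replicate draws
`lambda* ~ N(0, tau_DL)`, redraws error scales
`sigma*_j = u_j sqrt(nu_j/chi2_{nu_j})` for finite-dof labs (equivalently
`u_j`-scaled Student-t errors), rebuilds `x*_j`, and re-estimates both
`tau` and the mean; the reported `u(KCRV)` is the larger of the bootstrap
sd and the internal `(sum 1/u_j^2)^(-1/2)`. This recipe makes the
bootstrap sd converge to the internal value when `tau_DL = 0` and all
`nu_j` are infinite. It does not propagate the sampling uncertainty of
`tau_DL` itself; two-stage schemes that do were examined and produce
values 5–20 % larger, at the price of breaking the `tau = 0` convergence
property, and were not adopted.

**Weighted median.** Weights `1/u_j^2`. The exact point estimator is the
minimizer of `sum w_j |x_j - m|` (first cumulative-weight crossing of
1/2, midpoint on an exact tie); the consensus path uses the centered
weighted-ECDF interpolation (mass points `(cum_k - w_k/2)/W`), which is
unbiased on symmetric samples, and reports the bootstrap-smoothed
(bagged) estimate — the mean of the replicate medians — which removes the
order-statistic bias visible in sparse regions of the sample.
Bootstrap mode `auto` resamples `(x_j, u_j)` pairs nonparametrically for
n ≥ 15 and draws parametric replicates (Gaussian, or Student-t under
finite dof) below that; 15 separates the historical use cases.

**Hierarchical models.** Priors are weakly informative and configurable:
`mu ~ N(median x, 1e5 mad x)` (effectively flat), `tau ~
half-Cauchy(mad x)`, `sigma_j ~ half-Cauchy(median u)` for finite-dof
labs, and for the skew-t leaf `alpha ~ N(0, 4)` and `nu ~ Gamma(2, 0.2)`
truncated at 3. The skewness and tail-dof priors are reconstructed
defaults: with only ~10 laboratories those parameters are weakly
identified and prior-sensitive, and these scales reproduce the posterior
summaries published for the historical lead-in-wine dataset
(`alpha ~ -4 +- 3`, `nu` mean ~11, median ~9); broader choices (e.g.
`N(0,10)`, `Gamma(2, 0.1)`) drift to `alpha ~ -9`, `nu ~ 17` on the same
data.

The sampler marginalizes the per-lab effects out of the likelihood —
exactly for Gaussian effects (`x_j ~ N(mu, sqrt(sigma_j^2+tau^2))`) and
Laplace effects (the Laplace×Gauss convolution written with scaled
complementary error functions, computed in log space for stability), and
by 48-node Gauss–Hermite quadrature against the Gaussian error kernel for
skew-t effects (the density is smooth, so quadrature error is far below
Monte Carlo error). The remaining 2–4(+) dimensional posterior is
explored with an affine-invariant ensemble sampler (differential-
evolution moves, 32+ walkers, default 1000 warmup steps and 10 000
retained draws, at least 200 retained steps per walker). Split-Rhat and
bulk ESS are computed per parameter treating walkers as chains; the fit
warns above Rhat 1.05 or below ESS 400 and raises above Rhat 1.2.
Degenerate corners of the skew-t posterior (`tau -> 0`, `nu -> inf`)
carry negligible mass and are excluded by hard bounds rather than
special-cased quadrature. Per-lab effect summaries are conditional
means/sds computed post hoc (closed form for Gaussian effects, quadrature
reweighting otherwise), combined across a thinned set of hyperparameter
draws by the law of total variance.

## Degrees of equivalence

`D_j = x_j - KCRV` exactly; `U95(D_j)` is the symmetric half-width of the
equal-tailed 95 % interval of simulated deviations `d*_j` built from the
retained draws (default 10 000 predictive replicates) with a *fresh*
effect `lambda*` from the fitted effects distribution and fresh error at
the lab's (possibly redrawn) scale — the predictive construction that
answers whether a result lies beyond the range the model allows, rather
than a plug-in one. For included labs the replicate consensus is the one
recomputed from the same replicate data (bootstrap leaves) or drawn
jointly (Bayesian leaves: `d* = lambda* + eps*`), carrying the
estimator–datum correlation; for excluded labs
`d* = mu* + lambda* + eps* - KCRV`, so the consensus uncertainty enters
with no correlation credit, and in the no-dark-uncertainty,
infinite-dof limit `U95` reduces to `1.96 sqrt(u_j^2 + u(KCRV)^2)`. The
weighted-median leaf simulates Gaussian pseudo-studies around the KCRV
and recomputes the weighted median per replicate.

## Synthetic data generator

`generate_kc` draws from the same random-effects model, one mode per
leaf: reported uncertainties log-uniform over `u_range` (mimicking the
order-of-magnitude spread of real comparisons), effects scaled to sd
`tau_true` (skew-t mean-centered via the offset above), and, under a
finite-dof policy, reported `u_j` that are chi-squared-noisy estimates of
the true scales. Defaults (15 labs, uncertainties 0.5–2) match the size
of typical comparisons. The generator emulates independent labs with
honestly reported uncertainty *scales*; it does not model correlated
labs, drift over time, or systematically over/under-stated uncertainty
budgets, so passing recovery tests demonstrates internal consistency of
the estimators, not robustness to those real-world failure modes.

## Numerical and design notes

* Q, DL and the Q-profile use only `(x_j, u_j)`; finite `nu_j` enter the
  bootstrap and the Bayesian likelihoods, matching the classical
  definitions of the tests.
* `dof_from_coverage_factor` inverts the two-sided Student-t quantile by
  Brent root finding over `nu in [0.01, 1e6]` and rounds to the nearest
  integer; coverage factors within 5e-3 of the Gaussian quantile map to
  infinite dof.
* Infinite dof is encoded as `math.inf` end to end; CSV round-trips leave
  it blank.
* All randomness flows through `numpy.random.default_rng(seed)`; every
  bootstrap, fit and pipeline artifact records its seed, and results are
  bit-reproducible given one.
* Small-n caveats: below 5 included results a prominent warning is
  attached (the gating tests are unreliable there); symmetry below n=30
  and shape below n=10 carry power warnings.

## Known limitations

* The adaptive-weighted-average bootstrap understates the contribution of
  `tau`'s own sampling uncertainty (see above); on a 4-lab comparison the
  published reference implementation reports ~6 % more uncertainty.
* Skew-t posteriors for `alpha` and `nu` are prior-driven below ~15 labs;
  report them with their posterior sds, not as point facts.
* The weighted-median uncertainty assumes exchangeable `(x_j, u_j)`
  pairs under nonparametric resampling; with n < 15 the parametric
  fallback leans on the Gaussian/Student error shape.
* Only unilateral DoEs are computed; pairwise (bilateral) DoEs and
  automated lab exclusion are out of scope by design — selecting which
  results enter the KCRV is a substantive decision for the study's
  organizers, not a statistical one.
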