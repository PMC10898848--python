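# kctree — decision tree for key comparisons

`kctree` reduces the results of a *key comparison* (KC) — an
interlaboratory study in which national metrology institutes measure the
same measurand — to a consensus value (the key comparison reference value,
KCRV), its standard uncertainty, and per-laboratory *degrees of
equivalence* (DoEs). It is written for metrologists and statisticians who
run or review interlaboratory studies and meta-analyses.

Each laboratory *j* reports a measured value `x_j`, a standard uncertainty
`u_j` (possibly as an expanded uncertainty `U_j` with coverage factor
`k_j`), and optionally the degrees of freedom `nu_j` supporting `u_j`.
The working model is the random-effects model

    x_j = mu + lambda_j + eps_j,        j = 1..n,

where `mu` is the true value of the measurand, `lambda_j` is the
laboratory effect with mean 0 and standard deviation `tau` (the *dark
uncertainty*: dispersion in excess of what the reported uncertainties
allow), and `eps_j ~ N(0, sigma_j)` is the measurement error, with
`sigma_j = u_j` when `nu_j` is infinite and `nu_j u_j^2 / sigma_j^2 ~
chi2(nu_j)` otherwise.

Three gating tests route a study to one of five estimators:

1. **Mutual consistency** — Cochran's `Q = sum w_j (x_j - xbar_w)^2`,
   `w_j = 1/u_j^2`, against `chi2(n-1)` (default size 10 %).
2. **Symmetry** — the Miao–Gel–Gastwirth statistic
   `T = (mean - median) / J`, `J = sqrt(pi/2) * mean|x - median|`, with a
   reflection-bootstrap null (default size 5 %).
3. **Gaussian shape** — Shapiro–Wilk and Anderson–Darling on the roughly
   standardized values `(x_j - median(x)) / u_j` (default size 5 %).

Consistent and Gaussian data get the **adaptive weighted average**
(DerSimonian–Laird: weights `1/(u_j^2 + tau_hat^2)`, parametric-bootstrap
uncertainty honoring finite `nu_j`); consistent but non-Gaussian data the
**weighted median** (weights `1/u_j^2`, nonparametric-bootstrap
uncertainty). Inconsistent data get a Bayesian hierarchical model whose
effects distribution is chosen by shape: **Gauss**, **Laplace** (heavy
tails dampen discrepant results), or **skew Student-t** (asymmetry
parameter `alpha`, tail dof `nu`), fitted by MCMC on the marginalized
posterior. DoEs `D_j = x_j - KCRV` carry expanded uncertainties
`U95(D_j)` computed predictively from the Monte Carlo draws, so dark
uncertainty and the estimator–datum correlation are propagated.

Eight historical datasets (CCQM-K45, CCQM-K145 Zn and Ni, CCQM-K88,
CCQM-K30.1, Zn-65 equivalent activity, the Sr-90 half-life series, and
CCEM.RF-K25.W) ship as packaged fixtures.

## Worked example

```python
from kctree import fixture, traverse, DecisionConfig, estimate, compute_does

k45 = fixture("K45")                      # tin in tomato paste, UME excluded
trace = traverse(k45, DecisionConfig(seed=1))
res = estimate(k45, trace.leaf, seed=1)
doe = compute_does(k45, res, seed=1)
```

or from the shell, with the same study written to CSV:

```sh
kctree run --input k45.csv --out k45_out --unit mg/kg --seed 1
```

which prints (abridged):

```
Gating tests
node                          statistic   p-value   size decision
homogeneity (Cochran Q)           3.918    0.2704  0.100 retain -> YES
Gaussian shape                    0.983    0.9197  0.050 retain -> YES

Recommended procedure: adaptive weighted average (DerSimonian-Laird)
KCRV = 226.515 mg/kg
u(KCRV) = 0.6667 mg/kg
dark uncertainty tau = 0.601 mg/kg (DL)
tau 95 % Q-profile interval: (0, 8.777) mg/kg

Degrees of equivalence (D_j +/- U95)
  KRISS        D =    -0.2548  U95 =      1.86  (included)
  LGC          D =     -1.915  U95 =     2.791  (included)
  LNE          D =     +3.905  U95 =     5.738  (included)
  PTB          D =    +0.4852  U95 =     1.545  (included)
  UME          D =     -16.71  U95 =     7.784  (excluded) *
```

Reading this: the four included results are mutually consistent
(Cochran p = 0.27) and Gaussian-looking (Shapiro–Wilk p = 0.92), so the
adaptive weighted average is recommended. The KCRV is 226.5 mg/kg with a
bootstrap standard uncertainty of 0.67 mg/kg — larger than the internal
(fixed-effects) value of 0.49 mg/kg because the DerSimonian–Laird estimate
of dark uncertainty is 0.601 mg/kg rather than zero. UME's deviation of
−16.7 mg/kg exceeds its U95 of 7.8 mg/kg, flagging it as beyond the range
the model allows; the warning block (not shown) cautions that with only
four included results the gating tests have little power and that the
Q-profile interval for `tau` reaches 8.8 mg/kg.

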