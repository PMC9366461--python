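# Methods

## The problem

Rates of phenotypic evolution vary enormously among lineages, and a core
macroevolutionary question is whether that variation is *caused* by the
state of another evolving trait (does a large brain speed up beak-shape
evolution? does body size damp it?).  Because the state of a Brownian-like
trait is uncorrelated with its own displacement, any causal effect of a
predictor x on the *rate* of a response y shows up only in second moments:
the squared deviation of y correlates with x even though y itself does not.
`rategls` therefore regresses squared trait deviations on an evolving
predictor, with regression weights derived from the joint stochastic
process, and translates the regression coefficients back into rate
parameters.

## The three models

All models make the rate variance of the response linear in the predictor,
`Var[dy] = (a + b x) dt`, on an ultrametric phylogeny rescaled to unit
height (so all rates are "per tree length"; the pre-scaling height is kept
for unit conversion).

**Model 1 — Brownian predictor.** `dy = sqrt(a + b x) dW1`,
`dx = sigma dW2`, roots at 0.  The tips of x are Gaussian with covariance
`sigma^2 T`, where `T[i, j]` is the shared branch length (depth of the most
recent common ancestor) of tips i and j.  After a unit of time,
`Cov[y^2, x] = b sigma^2 / 2`.  The best linear predictor of the vector of
squared, root-centered y on the root-centered x has slope matrix
`(I - (1/2)(T∘T)T^{-1})` (∘ is the Hadamard product), which becomes the
second design column; the residual covariance is

    Vr = 4 a v_y T + 2 (a^2 + b^2 v_x) T∘T
         + b^2 sigma^2 (T∘T∘T - (1/4)(T∘T) T^{-1} (T∘T)),

where `v_y = a / n_e` and `v_x = sigma^2 / n_e` are the error variances of
the root predictions and `n_e = 1'T^{-1}1` is the effective sample size.

**Model 2 — geometric Brownian predictor.** For strictly positive,
ratio-scale predictors whose causal effect is linear on the *original*
scale, x follows geometric Brownian motion (`ln x` is Brownian with rate
`sigma^2` per tree length, with the Ito drift exactly cancelled).  The
analysis standardizes x by the exponentiated predicted log-root and centers
it on its predicted tip mean `exp((sigma^2 - v_lnx)/2)`; the design and
residual matrices are built elementwise from matrices of the form
`[e^{c t_a} - 1]` evaluated at the shared branch lengths, combined with a
true matrix inverse of `[e^{sigma^2 t_a} - 1]`.  We verified this bracket
algebra decisively: the slope matrix equals the exact best-linear-predictor
matrix `Cov[y^2, x] Var[x]^{-1}` obtained by direct integration of the
joint lognormal moments (agreement ~1e-15 on small trees), whereas an
elementwise-ratio reading of the brackets is badly wrong.

The regression is only approximately linear; its accuracy improves as
`sigma^2` grows, but the estimator acquires a documented bias by
`sigma^2 = 2`.  At the other end, `sigma^2 < 0.5` triggers a warning (use
the simpler Model 1: mild multiplicative variation is well approximated by
additive dynamics) and `sigma^2 < 0.05` is an error.

**Model 3 — recent microevolution.** Short-term evolution is largely
decoupled from million-year divergence, so the current phenotype is modeled
as `y = y_macro + y_micro`: a Brownian macroevolutionary component with
covariance `V_macro = macro_sigma2 * T` (any user-supplied Gaussian
`V_macro` is accepted) plus independent per-species white noise with
variance `a + b x_i`.  The unobservable micro deviation is estimated by the
leave-one-out best linear predictor: with `V` the total covariance and
`d(.)` the operator that zeroes off-diagonal entries,

    y - y_hat = d(V^{-1})^{-1} V^{-1} (y - ybar),
    Var[y - y_hat] = (d(V^{-1}) V d(V^{-1}))^{-1}.

The squared deviations form the response; their covariance is twice the
elementwise square of `Var[y - y_hat]` (multivariate chi-square with one
degree of freedom).  The macroevolutionary "leakage" into the deviation,
`diag[P V_macro P']` with `P = d(V^{-1})^{-1} V^{-1}`, is subtracted from
the response before fitting, and measurement variances join both `V` and
that offset.

## Estimation

The statistical model is plain GLS, `Y = D beta + r, Var[r] = Vr`, solved
by Cholesky whitening (never an explicit inverse).  Because `Vr` depends on
(a, b), the fit iterates: OLS initial guess, GLS solve, back-transform the
intercept to a, rebuild `Vr`, repeat until the relative change in (a, b)
drops below 1e-6 (50 iterations maximum; convergence typically takes a
handful).  If the running a dips to zero or below, the *weighting* matrices
use a floor of 1e-12 times the response variance while the reported
estimate stays unclamped — the linear estimator stays unbiased, only the
weights are stabilized.

Intercept back-transforms:

* Model 1: `a = A_hat + v_y`, solved self-consistently
  (`a = A_hat * n_e/(n_e - 1)`).
* Model 2: `a = A_hat + v_y - b_hat * c`, where the mean-path term `c` is
  this package's closed-form derivation of the intercept correction: the
  expected squared response at the centered predictor's origin includes
  the rate accrued along the mean predictor path,
  `c = mean_i[(2/sigma^2) e^{v_lnx/2}(G_ii - 2(Gw)_i + w'Gw)]` with
  `G = [e^{sigma^2 t_a / 2} - 1]` and `w = T^{-1}1/n_e`.  This term is
  validated by simulation recovery of a and should be considered
  experimental.
* Model 3: the row sums of the Hadamard-squared prediction operator equal
  the intercept regressor exactly, so with a mean-centered slope column the
  intercept coefficient estimates `a + b xbar`; the fit reports
  `a = beta0 - b_hat * xbar` so that a is on the raw predictor scale.

`sigma^2` of the predictor (or of ln x) is profiled out beforehand by exact
Gaussian maximum likelihood on the predictor alone (`(z-m)'T^{-1}(z-m)/n`
with the GLS root value m).  Model 3's `macro_sigma2`, when not supplied,
comes from an ML fit of the Brownian + white-noise mixed model for y
(one-dimensional profile search over the noise/signal ratio; the grand mean
used for centering is that model's GLS mean).  Standard errors come from
`(D'Vr^{-1}D)^{-1}`; they cannot be converted into exact confidence
intervals because the residuals of squared responses are far from Gaussian
— the parametric bootstrap is the recommended uncertainty route, with
non-converged replicates dropped and counted, and percentile intervals
reported.

The weighted `R^2` diagnostic is `1 - (r'Wr)/((Y - mu)'W(Y - mu))` with
`W = Vr^{-1}` and mu the GLS mean of the response; this is this package's
own definition.  The closed-form ceiling
`R^2 = b^2 Var[x] / (2a^2 + 4ab xbar + 2b^2 xbar^2 + 3b^2 Var[x]) < 1/3`
shows why even strong rate effects explain only a few percent of disparity
— expect small values.

## Simulators and synthetic data

Models 1 and 2 are simulated by pre-order traversal: the predictor (or its
logarithm) advances by exact Gaussian increments, the response by
Euler–Maruyama with per-step rate `max(a + b x, 0)`; the default resolution
is 1000 steps per unit tree height and clamped steps are counted in the
result (the linear-rate model is undefined where `a + b x < 0`, so clamping
is a model approximation, not a numerical one; with a = 1, b = 0.5,
sigma^2 = 1 about 0.6% of steps clamp and the tip moments shift by under
2%).  Each branch consumes a private random substream keyed by
(seed, node index), so results are independent of traversal order and
bit-reproducible.  Model 3 is Gaussian and drawn exactly from its
covariance.

Fixture trees are pure Kingman coalescent trees (dendropy) rescaled to unit
height.  These are legitimate random ultrametric phylogenies but have very
small effective root-sample sizes (`n_e` around 2–4 for 200 tips, versus
roughly 10 for a comparable birth–death tree and much larger values for
big empirical supertrees), which deliberately stresses the estimators —
see the limitations below.  What the simulations do *not* emulate:
empirical tree shape, measurement error structure beyond the `2 se^4`
rule, non-Brownian predictor dynamics, or multivariate responses, so
passing tests demonstrate internal consistency of the method, not
robustness on real data.

## Numerical choices

* Ultrametry tolerance: relative tip-depth spread ≤ 1e-6; anything larger
  is an error, never a silent rescale.
* Near-singular matrices: one diagonal jitter of `1e-10 trace/n`, then a
  named error.  Tip order is canonical post-order; trait tables join by
  exact label match and any mismatch is an error.
* Negative fitted rates `a + b x_i` during estimation produce a warning
  naming the species (the fit itself is linear and proceeds); negative
  micro variances in Model 3's covariance are clamped only inside the
  weighting matrices.
* Test and acceptance problem sizes: moment checks use 1e5 Monte-Carlo
  replicates on 2-tip trees; recovery experiments use 150–300 replicates
  on 200-tip fixture trees with 500 Euler steps — sizes chosen so the
  whole suite runs in a few minutes while keeping Monte-Carlo error well
  below the effects being tested.

## Known limitations

* **Root-centering slope attenuation.**  The printed design matrices are
  the exact best-linear-predictor matrices for the squared response
  centered on the *true* root value.  Centering on the *estimated* root
  (the only option in practice) makes the expected squared response
  x-dependent in a way the design does not capture, attenuating the slope
  estimate by a factor of order (shared covariance)/n_e.  We verified this
  decomposition directly: with true-root centering the pooled slope is
  unbiased; with estimated-root centering on a 200-tip coalescent tree
  (n_e ≈ 2–4) the Model 1 slope attenuates by roughly 30–50%, shrinking
  quickly as n_e grows.  On empirical trees with hundreds of species and
  moderate depth the effect is small, but results on deep, few-basal-branch
  trees should be interpreted with care (and bootstrapped).
* **Heavy-tailed slope estimates.**  Squared-response regressions have
  chi-square-like residuals; on low-n_e trees the sampling distribution of
  b_hat is strongly right-skewed (median well below the mean).  Medians
  and bootstrap intervals are more informative than means and analytic
  standard errors.
* **Model 2 nonlinearity.**  The squared response also covaries with
  higher powers of the predictor; the induced bias is negligible for
  sigma^2 ≤ 1 but measurable at sigma^2 = 2.
* Only the response-side `2 se^4` observation variance is implemented;
  predictor-side attenuation corrections are not.
* No Ornstein–Uhlenbeck macroevolution generator (a user-supplied V_macro
  is the escape hatch), no multivariate responses, no exact-likelihood or
  Bayesian estimation (the joint distributions are not Gaussian and their
  likelihoods are unavailable in closed form).
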