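# Methods

This note records the statistical models behind `multibin`, the algorithmic
and numerical choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Marginal models and the hypothesis family

Each endpoint $j$ is modelled marginally: $y_{ji} \sim B(1, \pi_{ji})$ with
$\mathrm{logit}(\pi_{ji}) = x_i^\top \beta_j$.  Two systematic parts are
supported — a single dose slope (design columns $[1, x]$) and dummy-coded
dose groups with the lowest dose as control (Dunnett-type).  The tested
family consists of all non-intercept parameters across endpoints,
$M = JK$; intercepts are never tested.  All tests are two-sided Wald tests
with model-based standard errors.

Fitting is Newton–Raphson/IRLS with a relative-deviance convergence
criterion of 1e-8 and a cap of 25 iterations — conventional GLM defaults, so
results are interchangeable with mainstream GLM implementations (verified
against statsmodels to 1e-6 in the tests).  The fitter is *batched*: many
response columns sharing one design are fitted simultaneously with
BLAS-level operations, because the resampling and simulation machinery needs
on the order of millions of two-parameter fits per study.  Degeneracy is
flagged — never silently ignored — when a response is constant, the fit does
not converge, any $|\hat\beta| > 15$ on the logit scale, or any standard
error exceeds 100; those cutoffs operationalise "extreme coefficients and
standard errors" for separation and sparse-data failure.

## Stacked joint inference (MMM)

With $\tilde\psi_{ji} = x_i (y_{ji} - \hat\pi_{ji})$ the raw score of
individual $i$ in model $j$ and $\hat I_j$ the Fisher information, the
standardized contributions $\hat\Psi_{ji} = \tilde\psi_{ji} (\hat I_j/N)^{-1}$
are stacked across endpoints and

$$\hat\Sigma = \tfrac1N \sum_i \hat\Psi_i^\top \hat\Psi_i$$

estimates the joint covariance of $\sqrt N(\hat\beta - \beta)$; its
diagonal over $N$ is the familiar sandwich variance.  An algebraically
equivalent bread–meat–bread form $\tilde\Sigma = \hat B \hat M \hat B$ (with
$\hat B$ block-diagonal inverse average informations and $\hat M$ the raw
score second moment) is also computed; both are reported on the same scale
and can disagree only through floating-point effects when standard errors
explode.  The bread–meat–bread form is the default input to the correlation
matrix $\hat R$, and a discrepancy above 1e-6 between the two is a sign of
numerical trouble.

Two open choices were resolved as follows:

* **Which standard errors enter $t_{jk}$.**  The marginal Wald statistic is
  defined with the model-based standard error, and the established R
  machinery for this method does the same: it rescales the sandwich
  *correlation* by the model-based standard deviations.  `multibin`
  therefore defaults to model-based ses for the test statistics
  (`se_mode="model"`), with the stacked-sandwich alternative available as a
  switch.  With this convention the adjusted p-values agree with the R
  reference stack to ~2e-4 on a frozen dataset (integration noise of both
  implementations).
* **When joint inference is refused.**  `MMMUnavailable` is raised when any
  covariance diagonal entry is non-positive or non-finite — the documented
  numerical failure mode for sparse endpoints — and also when any marginal
  fit is flagged degenerate, since a constant or separated endpoint
  contributes a covariance row that is numerically computable but
  statistically meaningless.  The simulation harness counts such runs as
  "no rejection" for the MMM method and reports them separately, which makes
  the method look conservative exactly where the failure is frequent.

Rectangle probabilities $P(\max_q |z_q| \le c)$ under $\mathrm{MVN}(0,\hat
R)$ use a closed form for $M=1$, a deterministic 1-D quadrature reduction
for $M=2$, and Genz-style quasi-Monte-Carlo integration (absolute tolerance
1e-5) with a fixed internal seed for $M \ge 3$, so adjusted p-values are
bit-reproducible run to run.  The critical value solves
$P(\max|z_q| \le c) = 1-\alpha$ by bracketed root finding between the
marginal and Bonferroni quantiles.  Adjusted p-values are floored at the raw
p-value, making the union-bound bracket $p \le p^{MMM} \le Mp$ hold exactly.

## Bayesian model class

The weakly informative default: independent Cauchy priors centred at 0,
scale 10 for the intercept and 2.5 for other coefficients, applied after
standardizing numeric inputs to mean 0 and standard deviation 0.5 and
centring binary inputs.  The posterior mode is found by approximate-EM
augmented IRLS: each step solves a ridge-penalised weighted least squares
with per-coefficient prior variances $\sigma_k^2$, then updates
$\sigma_k^2 \leftarrow (\beta_k^2 + \nu s_k^2)/(\nu + 1)$ with $\nu = 1$
fixed (the Cauchy case; other prior scales are deliberately unexplored).
Standard errors come from the inverse penalised curvature at the mode, so
estimates and ses are finite for any dataset, including complete
separation; everything is mapped back to the original predictor scale.  The
mode matches a grid-search oracle to 1e-3 in the zero-event case and the
MLE to well below 1e-4 in the flat-prior limit.

For stacking, the score contributions of a Bayesian fit are the plain GLM
scores $x_i(y_i - \hat\pi_i)$ evaluated at the posterior mode — no prior
term — and the bread is the inverse curvature used for the reported ses.
This keeps the contributions well-defined and finite and reduces to the GLM
stacking when the prior is flat; it is an interpretation, not a uniquely
forced choice.

## minP resampling

A "row" is the $J$-vector of endpoint responses of one individual; rows are
resampled with replacement (bootstrap) or permuted (permutation) against the
*fixed* design, which enforces the complete null for all endpoints at once
while preserving their correlation.  The resampled fits use the same model
class and the same Wald test as the original analysis.  A resampled
endpoint whose fit is degenerate (e.g. an all-zero column) contributes
$p^* = 1$ for that endpoint in that resample — no evidence, never the
minimum — keeping the denominator at $B$; this mirrors the behaviour that
rare-event endpoints are effectively excluded from the adjustment without
being formally removed.  The comparison is $\min(p^*) \le p_{jk}$
(non-strict).  Resample $r$ draws from its own seed substream, so results
are independent of chunking or scheduling, and adjusted p-values live on
the grid $\{0, 1/B, \dots, 1\}$.

## Data generator

The shared-Poisson construction represents each endpoint as the indicator
that a Poisson total is zero.  Pairwise shared intensities are
$\lambda_{jk} = \ln(1 + \rho_{jk}\sqrt{q_j q_k/(\pi_j \pi_k)})$.  The
allocation places a component common to *all* endpoints at intensity
$\lambda_c = \min_{j<k} \lambda_{jk}$, per-pair residual components
$\lambda_{jk} - \lambda_c$, and per-endpoint own components topping the
total up to $-\ln \pi_j$.  The shared intensity between any pair is still
exactly $\lambda_{jk}$, so all pairwise correlations are preserved; the
common component is what makes equicorrelated blocks with $J > 2$ feasible
at all (a purely pairwise allocation needs
$\sum_{k \ne j} \lambda_{jk} \le -\ln\pi_j$, which already fails for five
endpoints at $\pi = 0.25$, $\rho = 0.5$).  For $J = 2$, or when any pair is
uncorrelated, the allocation reduces to the purely pairwise variant.
Infeasible specifications (negative own intensity) are rejected eagerly
with the offending endpoint index.  Only nonnegative target correlations
are supported.

Scenario datasets emulate dose-response studies: balanced groups at doses
{0, 2.5, 5, 10} by default, event probabilities
$\mathrm{expit}(\beta_{j0} + \beta_{j1}x)$ (or group offsets), the target
correlation applied within each dose group, and the null-block and
alternative-block endpoints drawn from independent seed substreams — so
their between-block correlation is zero in expectation and is never a user
input.  Each dose group within each block also has its own substream, so
enlarging one block never perturbs the other's draws.

What the generator does *not* emulate: negative correlations between
endpoints (such as mutually exclusive tumor subclasses), correlation
structure that changes with dose, overdispersion or litter/cluster effects,
and missing data.  Passing tests therefore demonstrate calibration and
error control under exchangeable, nonnegatively correlated Bernoulli noise,
not under every dependence structure real bioassays can produce.

## Simulation harness

Every method sees the same simulated dataset per run (a paired design,
chosen to cancel between-run Monte-Carlo noise in method comparisons;
estimates of each method's own FWER/power are unaffected).  Weak FWER is
the fraction of runs with any rejection when all endpoints are null; strong
FWER and any-pair power are tallied on the same runs of an alternative
scenario from the null-block and alternative-block rejections respectively.
For the MMM rejection decision the harness uses the equivalence
$\max_{q \in S} |t_q| > c_{1-\alpha}$ iff the adjusted p-value of the
subset's largest statistic is below $\alpha$, which costs one rectangle
probability per subset instead of a root search.  Monte-Carlo standard
errors are $\sqrt{\hat p(1-\hat p)/n_{sim}}$.

Default problem sizes are chosen so the shipped checks run in minutes on a
single core: 2,000 runs for the FWER-control check, 500 runs with $B=500$
for the power-ordering check, 5,000 datasets for generator calibration, and
$B = 1000$ inside simulations versus $B = 10{,}000$ for one-off data
analyses.  All are parameters, and factorial grids of arbitrary size can be
expressed through `scenario_grid` or the YAML config.

## Known limitations

* Only the logit link; no overdispersion, GEE-type working correlation, or
  extra covariates beyond dose (for resampling, the row-reassignment scheme
  is specific to a shared fixed design).
* Single-step adjustments only; step-down/step-up refinements are out of
  scope.
* The minP bootstrap's FWER control is approximate — resampling with
  replacement carries no finite-sample guarantee — and under extreme
  sparsity with very small samples it can run slightly liberal.
* Negative target correlations are not representable by the generator's
  construction.
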