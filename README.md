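# multibin

Simultaneous inference for multiple correlated binary endpoints.

In toxicology and early clinical research, one study often records many
binary outcomes per individual — tumor classifications in a carcinogenicity
bioassay, adverse-event types in a trial — and asks whether *any* of them
responds to dose.  Testing each endpoint separately inflates the family-wise
error rate (FWER), while classical corrections such as Bonferroni ignore the
correlation between endpoints and give up power.  `multibin` implements the
model-based alternatives, a matching data generator, and a Monte-Carlo
harness for studying their operating characteristics.

## What it computes

For endpoints $j = 1, \dots, J$ observed on $N$ individuals, a marginal
binomial GLM with logit link is fitted per endpoint: a dose-slope regression
$\mathrm{logit}(\pi_{ji}) = \beta_{j0} + \beta_{j1} x_i$, or a Dunnett-style
comparison of each dose group against control.  The family of hypotheses is
$H_{0jk}: \beta_{jk} = 0$ over all endpoints and effect parameters
($M = JK$), tested two-sided with Wald statistics
$t_{jk} = \hat\beta_{jk} / \widehat{se}(\hat\beta_{jk})$.  Three single-step
FWER adjustments are provided:

* **Bonferroni** — $\tilde p_{jk} = \min(M\, p_{jk},\, 1)$.
* **Multiple marginal models (MMM)** — the per-observation score
  contributions of all marginal fits are stacked; their empirical second
  moment, standardized by the per-model information ("sandwich" form),
  estimates the joint correlation $\hat R$ of the $t_{jk}$.  Adjusted
  p-values are tail probabilities of the max-$|z|$ statistic under
  $\mathrm{MVN}(0, \hat R)$, $p^{MMM}_{jk} = P(\max_q |z_q| > |t_{jk}|)$,
  and simultaneous confidence intervals are
  $\hat\beta_q \pm z_{1-\alpha,M,\hat R}\, \widehat{se}_q$.
* **Westfall–Young minP** — whole response rows are resampled (bootstrap or
  permutation) against the fixed design, enforcing the complete null while
  preserving the endpoint correlation; the adjusted p-value is the
  resampling estimate of $P(\min(p^*) \le p_{jk})$.

For sparse endpoints (rare events, separation), where maximum-likelihood
logistic fits explode and the MMM covariance can become uncomputable, a
Bayesian logistic model with weakly informative Cauchy priors (scale 10 on
the intercept, 2.5 on standardized coefficients; posterior mode via
approximate-EM augmented IRLS) is available as a drop-in model class.

The data generator draws correlated Bernoulli vectors by the shared-Poisson
construction: $Y_j = \mathbb{1}\{\text{Poisson sum} = 0\}$ with a component
of intensity $\lambda_{jk} = \ln\!\big(1 + \rho_{jk}\sqrt{q_j q_k / (\pi_j
\pi_k)}\big)$ shared between pairs, giving exact marginals $\pi_j$ and
pairwise correlations $\rho_{jk}$.

## Worked example

```sh
python examples/adjust_endpoints.py
```

analyses a simulated five-endpoint dose-response study (200 animals, doses
{0, 2.5, 5, 10}, within-family correlation 0.5, two endpoints truly
dose-responsive) and prints:

```
method    bonferroni  minp-bootstrap     mmm
endpoint
y1            0.0000          0.0000  0.0000
y2            0.0273          0.0155  0.0257
y3            1.0000          0.9750  0.9734
y4            1.0000          1.0000  1.0000
y5            1.0000          1.0000  1.0000
```

Each cell is that endpoint's dose-slope p-value after familywise adjustment:
the two responsive endpoints are detected by every method, Bonferroni is the
most conservative, and the minP bootstrap — which uses the observed
correlation between endpoints — gives the smallest adjusted p-values.  The
same pipeline runs on the real NTP methyleugenol bioassay when the
per-animal table is placed under `data/` (see `data/README.md`), via

```sh
multibin adjust data/ntp_methyleugenol.csv --min-events 5 --B 10000 --seed 1
```

Other examples: `generate_correlated_data.py` (generator calibration),
`simultaneous_intervals.py` (simultaneous CIs and their duality with the
adjusted tests), `fwer_power_study.py` (Monte-Carlo FWER/power comparison),
and `group_comparison_template.yaml` (editable Dunnett-style simulation
settings for `multibin simulate`).

## Layout

| path | contents |
|---|---|
| `src/multibin/datagen.py` | correlated-binary generator, scenarios |
| `src/multibin/glm.py` | marginal logistic fits (batched IRLS), Wald tests, scores |
| `src/multibin/bayes.py` | Cauchy-prior Bayesian logistic fits |
| `src/multibin/mmm.py` | stacking, MVN critical values, adjusted p, simultaneous CIs |
| `src/multibin/minp.py` | Westfall–Young minP bootstrap/permutation |
| `src/multibin/simstudy.py` | Monte-Carlo FWER/power harness, scenario grids |
| `src/multibin/io.py`, `cli.py` | CSV dialect, analysis configs, `multibin` CLI |
| `docs/methods.md` | models, algorithms, numerical choices, limitations |
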