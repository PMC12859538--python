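"""Monte-Carlo harness: family-wise error rate and any-pair power.

For each simulated dataset, every requested adjustment method is applied to
the *same* data (a paired design that removes between-method Monte-Carlo
noise), and rejections are tallied separately over the null-block and the
alternative-block hypotheses:

* weak FWER   — all endpoints null; fraction of runs with any rejection;
* strong FWER — fraction of runs with any rejection among null-block
  hypotheses, tallied on the same runs as power;
* any-pair power — fraction of runs with at least one rejection among
  alternative-block hypotheses.

Runs where the stacked correlation matrix cannot be computed (sparse
endpoints with exploding standard errors) count every MMM hypothesis as not
rejected and are reported in ``n_unavailable`` — the same accounting the
failure-prone settings require in practice.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .bayes import PriorSpec, fit_bayes_logit_batch
from .datagen import BinaryEndpointData, Scenario, generate_scenario, regression_scenario
from .glm import DesignSpec, MarginalFit, fit_logit_batch, wald_p_batch
from .minp import ResamplingPlan, minp_adjust
from .mmm import MMMUnavailable, max_abs_mvn_prob, stack

__all__ = ["StudyResult", "estimate_fwer", "estimate_power", "scenario_grid", "METHODS"]

METHODS = ("bonferroni", "mmm", "minp-bootstrap", "minp-permutation")


@dataclass(frozen=True)
class StudyResult:
    """One Monte-Carlo estimate (FWER or power) for one method."""

    scenario_id: str
    method: str
    model_class: str
    metric: str
    n_sim: int
    estimate: float
    n_unavailable: int
    seed: int | None

    @property
    def mc_se(self) -> float:
        return math.sqrt(self.estimate * (1.0 - self.estimate) / self.n_sim)


def _marginal_fits(
    data: BinaryEndpointData, design: DesignSpec, batch, model_class: str
) -> list[MarginalFit]:
    fits = []
    for j, lbl in enumerate(data.labels):
        fits.append(
            MarginalFit(
                coef=batch.coef[j],
                cov=batch.cov[j],
                fitted=batch.fitted[:, j],
                design=design,
                y=np.asarray(data.Y[:, j], dtype=float),
                converged=bool(batch.converged[j]),
                degenerate=bool(batch.degenerate[j]),
                n_iter=batch.n_iter,
                label=lbl,
                model_class=model_class,
            )
        )
    return fits


def _mmm_any_rejection(
    fits: list[MarginalFit], t_abs_subset_max: dict[str, float], alpha: float
) -> dict[str, bool]:
    """Whether the MMM test rejects anything within each subset of hypotheses.

    ``max_q |t_q| > c_{1-alpha}`` is equivalent to the adjusted p-value of the
    subset's largest statistic being below alpha, which needs one rectangle
    probability per subset instead of a root search for ``c``.
    """
    stacked = stack(fits)
    out = {}
    for key, tmax in t_abs_subset_max.items():
        if not np.isfinite(tmax):
            out[key] = False
        else:
            out[key] = (1.0 - max_abs_mvn_prob(tmax, stacked.R)) < alpha
    return out


def _run_study(
    scenario: Scenario,
    methods: Sequence[str],
    n_sim: int,
    seed: int,
    model_class: str,
    B: int,
    prior: PriorSpec | None = None,
):
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}; choose from {METHODS}")
    prior = prior or PriorSpec()
    alpha = scenario.alpha
    null_block = np.asarray(scenario.null_block, dtype=int)
    alt_block = np.asarray(scenario.alt_block, dtype=int)
    ss = np.random.SeedSequence(seed)
    run_streams = ss.spawn(n_sim)
    any_null = {m: 0 for m in methods}
    any_alt = {m: 0 for m in methods}
    unavailable = {m: 0 for m in methods}

    for r in range(n_sim):
        data_ss, resample_ss = run_streams[r].spawn(2)
        data = generate_scenario(scenario, data_ss)
        design = DesignSpec(kind=scenario.kind, dose=data.dose)
        X = design.matrix()
        tested = np.asarray(design.tested_indices)
        if model_class == "glm":
            batch = fit_logit_batch(X, np.asarray(data.Y, dtype=float))
        elif model_class == "bayesglm":
            batch = fit_bayes_logit_batch(X, np.asarray(data.Y, dtype=float), prior)
        else:
            raise ValueError(f"unknown model class {model_class!r}")
        p_raw = wald_p_batch(batch.coef[:, tested], batch.se[:, tested])
        p_raw[batch.degenerate] = 1.0  # no usable evidence from degenerate fits
        m_family = p_raw.size

        for method in methods:
            if method == "bonferroni":
                rej = (m_family * p_raw) < alpha
                if null_block.size and rej[null_block].any():
                    any_null[method] += 1
                if alt_block.size and rej[alt_block].any():
                    any_alt[method] += 1
            elif method == "mmm":
                with np.errstate(invalid="ignore", divide="ignore"):
                    t_abs = np.abs(batch.coef[:, tested] / batch.se[:, tested])
                subsets = {}
                if null_block.size:
                    subsets["null"] = float(np.nanmax(t_abs[null_block]))
                if alt_block.size:
                    subsets["alt"] = float(np.nanmax(t_abs[alt_block]))
                try:
                    fits = _marginal_fits(data, design, batch, model_class)
                    rej_sub = _mmm_any_rejection(fits, subsets, alpha)
                except MMMUnavailable:
                    unavailable[method] += 1
                    rej_sub = {k: False for k in subsets}
                if rej_sub.get("null"):
                    any_null[method] += 1
                if rej_sub.get("alt"):
                    any_alt[method] += 1
            else:
                sampler = "bootstrap" if method.endswith("bootstrap") else "permutation"
                plan = ResamplingPlan(
                    B=B,
                    sampler=sampler,
                    seed=resample_ss,
                    fit_producer="glm" if model_class == "glm" else "bayesglm",
                    prior=prior,
                )
                result = minp_adjust(data, design, plan, alpha=alpha)
                rej = result.p_adj.reshape(p_raw.shape) < alpha
                if null_block.size and rej[null_block].any():
                    any_null[method] += 1
                if alt_block.size and rej[alt_block].any():
                    any_alt[method] += 1
    return any_null, any_alt, unavailable


def estimate_fwer(
    scenario: Scenario,
    methods: Sequence[str] = ("bonferroni", "mmm"),
    n_sim: int = 1000,
    seed: int = 0,
    model_class: str = "glm",
    B: int = 1000,
    prior: PriorSpec | None = None,
) -> list[StudyResult]:
    """Estimate the FWER (weak if every endpoint is null) for each method."""
    any_null, _, unavailable = _run_study(
        scenario, methods, n_sim, seed, model_class, B, prior
    )
    metric = "fwer_weak" if not scenario.alt_block else "fwer_strong"
    return [
        StudyResult(
            scenario_id=scenario.scenario_id,
            method=m,
            model_class=model_class,
            metric=metric,
            n_sim=n_sim,
            estimate=any_null[m] / n_sim,
            n_unavailable=unavailable[m],
            seed=seed,
        )
        for m in methods
    ]


def estimate_power(
    scenario: Scenario,
    methods: Sequence[str] = ("bonferroni", "mmm"),
    n_sim: int = 1000,
    seed: int = 0,
    model_class: str = "glm",
    B: int = 1000,
    prior: PriorSpec | None = None,
) -> list[StudyResult]:
    """Any-pair power plus strong FWER, tallied on the same simulated runs."""
    if not scenario.alt_block:
        raise ValueError("power estimation needs a nonempty alternative block")
    any_null, any_alt, unavailable = _run_study(
        scenario, methods, n_sim, seed, model_class, B, prior
    )
    out = []
    for m in methods:
        out.append(
            StudyResult(
                scenario_id=scenario.scenario_id,
                method=m,
                model_class=model_class,
                metric="any_pair_power",
                n_sim=n_sim,
                estimate=any_alt[m] / n_sim,
                n_unavailable=unavailable[m],
                seed=seed,
            )
        )
        if scenario.null_block:
            out.append(
                StudyResult(
                    scenario_id=scenario.scenario_id,
                    method=m,
                    model_class=model_class,
                    metric="fwer_strong",
                    n_sim=n_sim,
                    estimate=any_null[m] / n_sim,
                    n_unavailable=unavailable[m],
                    seed=seed,
                )
            )
    return out


def scenario_grid(config: dict) -> list[Scenario]:
    """Expand a factorial configuration into a list of scenarios.

    Two forms are accepted.  The factorial form crosses list-valued keys as a
    Cartesian product: ``J``, ``N``, ``pi``, ``rho``, ``slope`` (default 0),
    ``n_alternative`` (default 0 = global null), plus scalar ``dose_levels``
    and ``alpha``.  The standard weak-FWER grid (J in {3,5,10} x N in
    {100,200,400} x six event probabilities x three correlations) expands to
    162 scenarios.  Alternatively an explicit ``scenarios`` list may spell
    out each setting (``kind``, ``N``, ``intercepts``, ``effects``, ``rho``,
    optional ``dose_levels``/``alpha``/``id``), which is how heterogeneous
    group-comparison settings — different intercepts and dose-group offsets
    per endpoint — are written down.
    """
    if "scenarios" in config:
        out = []
        for i, entry in enumerate(config["scenarios"]):
            out.append(
                Scenario(
                    kind=entry.get("kind", config.get("kind", "group_comparison")),
                    dose_levels=entry.get(
                        "dose_levels", config.get("dose_levels", (0.0, 2.5, 5.0, 10.0))
                    ),
                    n=int(entry["N"]),
                    intercepts=entry["intercepts"],
                    effects=entry["effects"],
                    rho=float(entry.get("rho", config.get("rho", 0.0))),
                    alpha=float(entry.get("alpha", config.get("alpha", 0.05))),
                    scenario_id=str(entry.get("id", f"scenario{i + 1}")),
                )
            )
        return out

    def listify(key, default):
        v = config.get(key, default)
        return list(v) if isinstance(v, (list, tuple, np.ndarray)) else [v]

    js = [int(v) for v in listify("J", [3])]
    ns = [int(v) for v in listify("N", [100])]
    pis = [float(v) for v in listify("pi", [0.25])]
    rhos = [float(v) for v in listify("rho", [0.0])]
    slopes = [float(v) for v in listify("slope", [0.0])]
    n_alts = [int(v) for v in listify("n_alternative", [0])]
    dose_levels = tuple(config.get("dose_levels", (0.0, 2.5, 5.0, 10.0)))
    alpha = float(config.get("alpha", 0.05))
    for pi in pis:
        if not 0.0 < pi < 1.0:
            raise ValueError(f"pi must lie in (0, 1), got {pi}")
    scenarios = []
    for j, n, pi, rho, slope, n_alt in itertools.product(
        js, ns, pis, rhos, slopes, n_alts
    ):
        if n_alt > j:
            raise ValueError("n_alternative cannot exceed J")
        sid = f"J{j}_N{n}_pi{pi:g}_rho{rho:g}_slope{slope:g}_alt{n_alt}"
        scenarios.append(
            regression_scenario(
                n=n,
                n_endpoints=j,
                pi0=pi,
                rho=rho,
                slopes=slope if n_alt else 0.0,
                n_alternative=n_alt if n_alt else None,
                dose_levels=dose_levels,
                alpha=alpha,
                scenario_id=sid,
            )
        )
    return scenarios
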