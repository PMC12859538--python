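"""Westfall-Young single-step minP adjustment by row-wise resampling.

The family's adjusted p-value for hypothesis ``jk`` is the resampling
estimate of ``P(min(p*) <= p_jk)`` where ``p*`` is the vector of raw p-values
recomputed on data whose *response rows* (the J-vector of endpoint indicators
of one individual) have been resampled — with replacement (bootstrap) or
without (permutation) — against the fixed design.  Reassigning whole response
rows to design rows enforces the complete null (no dose effect anywhere)
while preserving the between-endpoint correlation, without ever estimating
it.

Resampled endpoints whose fit is degenerate (e.g. an all-zero column after
resampling, or separation-scale estimates) contribute ``p* = 1`` for that
endpoint in that resample: they carry no evidence and cannot produce the
minimum, which keeps the denominator at ``B`` for every hypothesis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .bayes import PriorSpec, fit_bayes_logit_batch
from .datagen import BinaryEndpointData
from .glm import DesignSpec, fit_logit_batch, wald_p_batch
from .mmm import AdjustmentResult

__all__ = ["ResamplingPlan", "minp_adjust"]


@dataclass(frozen=True)
class ResamplingPlan:
    """Configuration of one minP run.

    ``sampler='bootstrap'`` draws N response rows with replacement;
    ``'permutation'`` shuffles them without replacement.  ``fit_producer``
    selects the marginal model class applied both to the original data and
    inside the resampling loop (like for like).
    """

    B: int = 10_000
    sampler: Literal["bootstrap", "permutation"] = "bootstrap"
    seed: int | np.random.SeedSequence = 0
    fit_producer: Literal["glm", "bayesglm"] = "glm"
    prior: PriorSpec = field(default_factory=PriorSpec)
    chunk_size: int = 200

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.sampler not in ("bootstrap", "permutation"):
            raise ValueError(f"unknown sampler {self.sampler!r}")
        if self.fit_producer not in ("glm", "bayesglm"):
            raise ValueError(f"unknown fit producer {self.fit_producer!r}")


def _batch_fit(X: np.ndarray, Y: np.ndarray, plan: ResamplingPlan):
    if plan.fit_producer == "glm":
        return fit_logit_batch(X, Y)
    return fit_bayes_logit_batch(X, Y, plan.prior)


def _raw_pvalues(X, Y, tested, plan) -> tuple[np.ndarray, np.ndarray]:
    """Per-endpoint raw Wald p-values for the tested parameters.

    Returns ``(p, degenerate)`` where ``p`` has shape (J, K); degenerate fits
    get p = 1 for all their parameters.
    """
    res = _batch_fit(X, Y, plan)
    p = wald_p_batch(res.coef[:, tested], res.se[:, tested])
    p[res.degenerate] = 1.0
    return p, res.degenerate


def minp_adjust(
    data: BinaryEndpointData,
    design: DesignSpec,
    plan: ResamplingPlan,
    alpha: float = 0.05,
) -> AdjustmentResult:
    """Single-step minP-adjusted p-values for all endpoint parameters.

    Adjusted p for hypothesis ``jk`` is ``#{resamples with min(p*) <= p_jk}/B``
    (the comparison is ``<=``).  Results are reproducible given the plan seed;
    resample ``r`` draws from its own substream, independent of execution
    order.
    """
    X = design.matrix()
    tested = np.asarray(design.tested_indices)
    Y = np.asarray(data.Y, dtype=float)
    n, j = Y.shape
    k = tested.shape[0]

    p_raw, degen = _raw_pvalues(X, Y, tested, plan)
    p_flat = p_raw.ravel()  # family order: endpoint-major, parameter-minor

    ss = (
        plan.seed
        if isinstance(plan.seed, np.random.SeedSequence)
        else np.random.SeedSequence(plan.seed)
    )
    streams = ss.spawn(plan.B)  # one substream per resample, order-independent
    counts = np.zeros(j * k, dtype=np.int64)
    n_degenerate_resamples = 0
    done = 0
    while done < plan.B:
        chunk = min(plan.chunk_size, plan.B - done)
        rngs = [np.random.default_rng(s) for s in streams[done : done + chunk]]
        if plan.sampler == "bootstrap":
            idx = np.stack([r.integers(0, n, size=n) for r in rngs])
        else:
            idx = np.stack([r.permutation(n) for r in rngs])
        # stack resampled response matrices column-wise: (n, chunk * j)
        Ystar = np.transpose(Y[idx], (1, 0, 2)).reshape(n, chunk * j)
        res = _batch_fit(X, Ystar, plan)
        pstar = wald_p_batch(
            res.coef[:, tested], res.se[:, tested]
        )  # (chunk * j, k)
        dg = res.degenerate
        pstar[dg] = 1.0
        n_degenerate_resamples += int(dg.sum())
        minp = pstar.reshape(chunk, j * k).min(axis=1)
        counts += (minp[:, None] <= p_flat[None, :]).sum(axis=0)
        done += chunk
    p_adj = counts / plan.B

    labels = []
    names = design.parameter_names
    for lbl in data.labels:
        for t in tested:
            labels.append(f"{lbl}:{names[t]}")
    return AdjustmentResult(
        labels=tuple(labels),
        p_raw=p_flat,
        p_adj=p_adj,
        method=f"minp-{plan.sampler}",
        alpha=alpha,
        diagnostics={
            "B": plan.B,
            "sampler": plan.sampler,
            "fit_producer": plan.fit_producer,
            "n_degenerate_original": int(degen.sum()),
            "n_degenerate_resample_fits": n_degenerate_resamples,
        },
    )
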