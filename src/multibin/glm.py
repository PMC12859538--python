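"""Marginal binomial GLMs with logit link, fitted by IRLS.

Each endpoint gets its own univariate logistic model — either a single dose
slope (regression design) or Dunnett-style dummy-coded comparisons of every
dose group against the control (lowest dose).  The fitter is written as a
batched Newton/IRLS over many response columns sharing one design matrix,
because the resampling and simulation machinery needs very large numbers of
small logit fits; a single-response wrapper provides the conventional API.

Alongside coefficients and model-based standard errors, every fit exposes the
per-observation score contributions ``x_i (y_i - pi_hat_i)`` and the Fisher
information ``X' W X`` that the multiple-marginal-models stacking consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "DesignSpec",
    "MarginalFit",
    "BatchFitResult",
    "fit_logit",
    "fit_logit_batch",
    "wald_test",
    "score_contributions",
]

#: IRLS stopping rule: relative deviance change below this, capped iterations.
IRLS_TOL = 1e-8
IRLS_MAXITER = 25

#: Degeneracy heuristics on the logit scale.
COEF_DEGENERATE = 15.0
SE_DEGENERATE = 100.0

_ETA_CLIP = 30.0


def _weighted_crossprods(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Batched ``X' diag(w_j) X`` for every weight column, via BLAS.

    ``X`` is (n, p), ``w`` is (n, j); returns (j, p, p).  Each distinct
    element is a single (1, n) @ (n, j) product of a precomputed column pair,
    which is far faster than a generic einsum for the small p used here.
    """
    n, p = X.shape
    j = w.shape[1]
    out = np.empty((j, p, p))
    for a in range(p):
        for b in range(a, p):
            v = (X[:, a] * X[:, b]) @ w  # (j,)
            out[:, a, b] = v
            out[:, b, a] = v
    return out


def _batched_inv(mats: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Invert a (j, p, p) stack; returns (inverses, ok_mask) without raising."""
    j = mats.shape[0]
    ok = np.ones(j, dtype=bool)
    try:
        inv = np.linalg.inv(mats)
        bad = ~np.isfinite(inv).all(axis=(1, 2))
        inv[bad] = np.nan
        ok[bad] = False
        return inv, ok
    except np.linalg.LinAlgError:
        inv = np.full_like(mats, np.nan)
        for i in range(j):
            try:
                inv[i] = np.linalg.inv(mats[i])
                ok[i] = np.all(np.isfinite(inv[i]))
            except np.linalg.LinAlgError:
                ok[i] = False
        return inv, ok


@dataclass(frozen=True)
class DesignSpec:
    """Systematic part of the marginal models.

    ``kind='regression'`` yields the design ``[1, dose]`` with a single tested
    slope; ``kind='group_comparison'`` dummy-codes the dose levels with the
    lowest dose as the reference (control) group, testing one offset per
    non-control group.
    """

    kind: Literal["regression", "group_comparison"]
    dose: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "dose", np.asarray(self.dose, dtype=float).ravel()
        )
        if self.kind not in ("regression", "group_comparison"):
            raise ValueError(f"unknown design kind {self.kind!r}")

    @property
    def levels(self) -> np.ndarray:
        return np.unique(self.dose)

    def matrix(self) -> np.ndarray:
        """N x P design matrix with an explicit intercept column."""
        n = self.dose.shape[0]
        if self.kind == "regression":
            return np.column_stack([np.ones(n), self.dose])
        levels = self.levels
        if levels.shape[0] < 2:
            raise ValueError("group comparison needs at least two dose levels")
        cols = [np.ones(n)]
        for lv in levels[1:]:
            cols.append((self.dose == lv).astype(float))
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is rank deficient")
        return X

    @property
    def tested_indices(self) -> tuple[int, ...]:
        """Column indices of the tested (non-intercept) parameters."""
        if self.kind == "regression":
            return (1,)
        return tuple(range(1, self.levels.shape[0]))

    @property
    def parameter_names(self) -> tuple[str, ...]:
        if self.kind == "regression":
            return ("intercept", "dose")
        levels = self.levels
        return ("intercept",) + tuple(
            f"dose{lv:g}-dose{levels[0]:g}" for lv in levels[1:]
        )


@dataclass
class BatchFitResult:
    """Vectorised fit of J response columns against one shared design.

    Arrays are indexed ``[column, parameter]``; ``fitted`` is N x J.
    ``degenerate`` marks all-0/all-1 responses, separation-scale estimates, and
    non-convergence — anything whose Wald inference should not be trusted.
    """

    coef: np.ndarray
    cov: np.ndarray
    fitted: np.ndarray
    converged: np.ndarray
    degenerate: np.ndarray
    n_iter: int

    @property
    def se(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.sqrt(np.einsum("jpp->jp", self.cov))


def fit_logit_batch(
    X: np.ndarray,
    Y: np.ndarray,
    *,
    tol: float = IRLS_TOL,
    maxiter: int = IRLS_MAXITER,
) -> BatchFitResult:
    """Fit a logistic model to every column of ``Y`` against the design ``X``.

    Newton-Raphson (equivalently IRLS for the canonical logit link) run
    simultaneously for all columns; convergence is a relative deviance change
    below ``tol``.  Constant response columns are flagged degenerate and kept
    at the intercept-only boundary fit rather than iterated to infinity.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    j = Y.shape[1]
    constant = (Y.min(axis=0) == Y.max(axis=0))
    coef = np.zeros((j, p))
    ybar = Y.mean(axis=0)
    with np.errstate(divide="ignore"):
        coef[:, 0] = np.clip(
            np.log(ybar / (1.0 - ybar)), -_ETA_CLIP, _ETA_CLIP
        )
    active = ~constant
    deviance = np.full(j, np.inf)
    n_iter = 0
    for it in range(maxiter):
        n_iter = it + 1
        idx = np.nonzero(active)[0]
        if idx.size == 0:
            break
        Ya = Y[:, idx]
        eta = np.clip(X @ coef[idx].T, -_ETA_CLIP, _ETA_CLIP)
        mu = expit(eta)
        w = mu * (1.0 - mu)
        grad = (Ya - mu).T @ X
        info = _weighted_crossprods(X, w)
        try:
            step = np.linalg.solve(info, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.stack(
                [
                    np.linalg.lstsq(info[i], grad[i], rcond=None)[0]
                    for i in range(idx.size)
                ]
            )
        coef[idx] += step
        eta = np.clip(X @ coef[idx].T, -_ETA_CLIP, _ETA_CLIP)
        mu = expit(eta)
        with np.errstate(divide="ignore", invalid="ignore"):
            dev = -2.0 * np.sum(
                Ya * np.log(np.clip(mu, 1e-300, None))
                + (1.0 - Ya) * np.log(np.clip(1.0 - mu, 1e-300, None)),
                axis=0,
            )
        rel = np.abs(dev - deviance[idx]) / (np.abs(dev) + 0.1)
        deviance[idx] = dev
        active[idx] = rel >= tol
        if not active.any():
            break
    converged = ~active & ~constant
    eta = np.clip(X @ coef.T, -_ETA_CLIP, _ETA_CLIP)
    mu = expit(eta)
    w = mu * (1.0 - mu)
    info = _weighted_crossprods(X, w)
    cov, ok = _batched_inv(info)
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.einsum("jpp->jp", cov))
    degenerate = (
        constant
        | ~converged
        | ~ok
        | (np.abs(coef) > COEF_DEGENERATE).any(axis=1)
        | ~np.isfinite(se).all(axis=1)
        | (np.nan_to_num(se, nan=np.inf) > SE_DEGENERATE).any(axis=1)
    )
    return BatchFitResult(
        coef=coef,
        cov=cov,
        fitted=mu,
        converged=converged,
        degenerate=degenerate,
        n_iter=n_iter,
    )


@dataclass
class MarginalFit:
    """A single endpoint's fitted marginal model.

    Holds everything downstream inference needs: coefficients, the model-based
    covariance (inverse observed information at the estimate — for a Bayesian
    fit, the inverse curvature including the prior), fitted probabilities, raw
    score contributions and the information matrix used as the stacking
    "bread".
    """

    coef: np.ndarray
    cov: np.ndarray
    fitted: np.ndarray
    design: DesignSpec
    y: np.ndarray
    converged: bool
    degenerate: bool
    n_iter: int
    label: str = ""
    model_class: str = "glm"

    @property
    def se(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.sqrt(np.diag(self.cov))

    @property
    def info(self) -> np.ndarray:
        """Curvature (inverse of the reported covariance)."""
        return np.linalg.inv(self.cov)

    def score_contributions(self) -> np.ndarray:
        """N x P matrix of per-observation scores ``x_i (y_i - pi_hat_i)``."""
        X = self.design.matrix()
        return X * (self.y - self.fitted)[:, None]


def fit_logit(y: np.ndarray, design: DesignSpec, label: str = "") -> MarginalFit:
    """Maximum-likelihood logistic fit of one binary response.

    Non-convergence, constant responses and separation-scale estimates are
    flagged via ``degenerate`` (and ``converged``), never silently returned as
    healthy fits.
    """
    y = np.asarray(y, dtype=float).ravel()
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("response must be binary 0/1")
    X = design.matrix()
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    res = fit_logit_batch(X, y[:, None])
    return MarginalFit(
        coef=res.coef[0],
        cov=res.cov[0],
        fitted=res.fitted[:, 0],
        design=design,
        y=y,
        converged=bool(res.converged[0]),
        degenerate=bool(res.degenerate[0]),
        n_iter=res.n_iter,
        label=label,
        model_class="glm",
    )


def wald_test(fit: MarginalFit, k: int) -> tuple[float, float]:
    """Two-sided Wald test of a non-intercept parameter.

    Returns ``(t, p)`` with ``t = coef_k / se_k`` and ``p = 2 (1 - Phi(|t|))``.
    ``k`` must index an effect parameter (the intercept is never tested).
    """
    if k < 1 or k >= fit.coef.shape[0]:
        raise ValueError("k must index a non-intercept parameter")
    t = float(fit.coef[k] / fit.se[k])
    p = float(2.0 * norm.sf(abs(t)))
    return t, p


def score_contributions(fit: MarginalFit) -> np.ndarray:
    """Convenience alias for :meth:`MarginalFit.score_contributions`."""
    return fit.score_contributions()


def wald_p_batch(coef: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Vectorised two-sided Wald p-values; NaN-safe (NaN -> p = 1)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        t = coef / se
    p = 2.0 * norm.sf(np.abs(t))
    return np.where(np.isfinite(p), p, 1.0)
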