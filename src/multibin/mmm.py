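"""Multiple marginal models: joint inference on stacked marginal estimates.

The marginal logistic fits are combined by stacking their per-observation
score contributions.  With ``psi_ji`` the raw score of individual ``i`` in
endpoint ``j``'s model and ``I_j`` the Fisher information, the standardized
contributions ``Psi_ji = psi_ji (I_j / N)^{-1}`` give the covariance estimate

    Sigma_hat = (1/N) sum_i Psi_i' Psi_i ,

whose ``diag/N`` is the familiar sandwich variance of the estimates.  An
algebraically equivalent form (the one used by the reference R machinery) is

    Sigma_tilde = (1/N) B_hat M_hat B_hat ,   B_hat_j = I_j^{-1} N ,
    M_hat = (1/N) psi' psi ,

which can disagree with Sigma_hat only through floating-point effects when
standard errors explode; non-positive diagonal entries raise
:class:`MMMUnavailable`, mirroring the documented failure mode for sparse
endpoints.

Standardizing the covariance gives the correlation matrix ``R_hat`` of the
test statistics, from which single-step adjusted p-values and simultaneous
confidence intervals follow via rectangle probabilities of the multivariate
normal distribution:  ``p_adj = P(max_q |z_q| > |t|)`` and the critical value
``c`` solving ``P(max_q |z_q| <= c) = 1 - alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import integrate, optimize
from scipy.stats import multivariate_normal, norm

from .glm import MarginalFit

__all__ = [
    "MMMUnavailable",
    "StackedInference",
    "AdjustmentResult",
    "stack",
    "stack_covariance",
    "stack_covariance_alt",
    "correlation_matrix",
    "max_abs_mvn_prob",
    "critical_value",
    "adjust_mmm",
    "bonferroni",
    "simultaneous_ci",
]

#: Internal seed for the quasi-Monte-Carlo MVN integration (M >= 3); fixed so
#: adjusted p-values are reproducible run to run.
_MVN_SEED = 52_493_881
_MVN_ABSEPS = 1e-5


class MMMUnavailable(RuntimeError):
    """Joint inference cannot proceed (non-positive covariance diagonal)."""


def _full_blocks(fits: Sequence[MarginalFit]):
    """Per-endpoint raw scores and total informations; checks row alignment."""
    n = fits[0].y.shape[0]
    for f in fits:
        if f.y.shape[0] != n:
            raise ValueError("all marginal fits must share the same N individuals")
    scores = [f.score_contributions() for f in fits]
    infos = []
    for f in fits:
        if not np.all(np.isfinite(f.cov)):
            raise MMMUnavailable(
                f"non-finite covariance in marginal fit {f.label or '?'}; "
                "stacked inference unavailable"
            )
        try:
            infos.append(f.info)
        except np.linalg.LinAlgError as exc:
            raise MMMUnavailable(
                f"singular covariance in marginal fit {f.label or '?'}"
            ) from exc
    return n, scores, infos


def stack_covariance(fits: Sequence[MarginalFit]) -> np.ndarray:
    """``Sigma_hat``: empirical second moment of standardized contributions.

    Computed over *all* parameters (intercepts included, since the per-model
    information mixes them); callers restrict to tested parameters afterwards.
    """
    n, scores, infos = _full_blocks(fits)
    psi_std = [s @ np.linalg.inv(i / n) for s, i in zip(scores, infos)]
    big = np.hstack(psi_std)
    return (big.T @ big) / n


def stack_covariance_alt(fits: Sequence[MarginalFit]) -> np.ndarray:
    """``Sigma_tilde``: bread-meat-bread form ``B_hat M_hat B_hat``.

    ``B_hat`` is block diagonal with blocks ``(I_j / N)^{-1}`` (inverse
    *average* information) and ``M_hat = (1/N) psi' psi`` is the empirical
    second moment of the raw scores.  Reported on the same scale as
    :func:`stack_covariance` (the asymptotic covariance of ``sqrt(N)
    (beta_hat - beta)``, i.e. ``N`` times the sandwich covariance of the
    estimates), so the two agree to numerical tolerance on well-conditioned
    fits and ``diag/N`` gives the sandwich variances either way.
    """
    n, scores, infos = _full_blocks(fits)
    psi = np.hstack(scores)
    m_hat = (psi.T @ psi) / n
    import scipy.linalg

    b_hat = scipy.linalg.block_diag(*[np.linalg.inv(i) * n for i in infos])
    return b_hat @ m_hat @ b_hat


def correlation_matrix(sigma: np.ndarray) -> np.ndarray:
    """Standardize a covariance to a correlation matrix.

    Raises :class:`MMMUnavailable` when any diagonal entry is non-finite or
    non-positive; off-diagonals exceeding 1 by more than 1e-10 also signal an
    invalid covariance.
    """
    d = np.diag(sigma)
    if np.any(~np.isfinite(d)) or np.any(d <= 0.0):
        raise MMMUnavailable(
            "covariance diagonal contains non-positive or non-finite entries; "
            "the correlation matrix of the stacked estimates cannot be formed "
            "(typically caused by sparse endpoints with exploding standard "
            "errors — consider the Bayesian model class)"
        )
    s = 1.0 / np.sqrt(d)
    r = sigma * np.outer(s, s)
    excess = np.max(np.abs(r)) - 1.0
    if excess > 1e-10:
        raise MMMUnavailable(
            f"correlation entries exceed 1 by {excess:.2e}; covariance invalid"
        )
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return 0.5 * (r + r.T)


def max_abs_mvn_prob(c: float, R: np.ndarray) -> float:
    """``P(max_q |Z_q| <= c)`` for ``Z ~ MVN(0, R)``.

    Closed form for M = 1, deterministic quadrature for M = 2, and seeded
    Genz-style integration (absolute tolerance ~1e-5) for larger families.
    """
    if c < 0:
        raise ValueError("threshold must be nonnegative")
    R = np.asarray(R, dtype=float)
    m = R.shape[0]
    if c == 0.0:
        return 0.0
    if m == 1:
        return float(2.0 * norm.cdf(c) - 1.0)
    if m == 2:
        rho = float(R[0, 1])
        if abs(rho) >= 1.0 - 1e-12:
            return float(2.0 * norm.cdf(c) - 1.0)
        s = np.sqrt(1.0 - rho * rho)

        def integrand(x: float) -> float:
            return norm.pdf(x) * (
                norm.cdf((c - rho * x) / s) - norm.cdf((-c - rho * x) / s)
            )

        val, _ = integrate.quad(integrand, -c, c, epsabs=1e-10, limit=200)
        return float(min(max(val, 0.0), 1.0))
    eigvals = np.linalg.eigvalsh(R)
    if eigvals[0] < -1e-8:
        raise ValueError("R is not positive semidefinite")
    lo = np.full(m, -c)
    hi = np.full(m, c)
    val = multivariate_normal.cdf(
        hi,
        mean=np.zeros(m),
        cov=R,
        allow_singular=True,
        lower_limit=lo,
        abseps=_MVN_ABSEPS,
        rng=np.random.default_rng(_MVN_SEED),
    )
    return float(min(max(val, 0.0), 1.0))


def critical_value(alpha: float, R: np.ndarray) -> float:
    """Two-sided equicoordinate quantile ``c``: ``P(max |z_q| <= c) = 1 - alpha``."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    target = 1.0 - alpha

    def f(c: float) -> float:
        return max_abs_mvn_prob(c, R) - target

    hi = norm.ppf(1.0 - alpha / (2.0 * R.shape[0])) + 0.5  # Bonferroni bound
    lo = norm.ppf(1.0 - alpha / 2.0) - 0.5
    lo = max(lo, 1e-6)
    while f(hi) < 0:
        hi += 1.0
    while f(lo) > 0:
        lo /= 2.0
    return float(optimize.brentq(f, lo, hi, xtol=1e-6))


@dataclass
class StackedInference:
    """Joint inference state for a family of M tested parameters."""

    estimates: np.ndarray
    se: np.ndarray
    t: np.ndarray
    R: np.ndarray
    sigma: np.ndarray
    sigma_alt: np.ndarray
    labels: tuple[str, ...]
    n: int
    se_mode: str = "sandwich"

    @property
    def m(self) -> int:
        return self.estimates.shape[0]

    @property
    def p_raw(self) -> np.ndarray:
        return 2.0 * norm.sf(np.abs(self.t))


def stack(
    fits: Sequence[MarginalFit],
    *,
    se_mode: Literal["model", "sandwich"] = "model",
    which_sigma: Literal["alt", "plain"] = "alt",
) -> StackedInference:
    """Build the stacked joint-inference object from marginal fits.

    The correlation matrix ``R_hat`` always comes from the stacked (sandwich)
    covariance.  ``se_mode='model'`` (default) takes the test-statistic
    standard errors from each marginal model, matching the usual marginal
    Wald statistic ``t_jk = beta_jk / se_model``; ``'sandwich'`` uses the
    stacked covariance diagonal instead.  ``which_sigma`` selects which
    covariance form feeds ``R_hat`` (the bread-meat-bread ``Sigma_tilde`` by
    default).
    """
    n = fits[0].y.shape[0]
    bad = [f.label or f"endpoint {i}" for i, f in enumerate(fits) if f.degenerate]
    if bad:
        raise MMMUnavailable(
            f"degenerate marginal fit(s) {bad}: constant response, separation "
            "or exploding standard errors make the stacked covariance "
            "meaningless (consider the Bayesian model class)"
        )
    tested: list[int] = []
    labels: list[str] = []
    offset = 0
    estimates = []
    model_se = []
    for f in fits:
        names = f.design.parameter_names
        for k in f.design.tested_indices:
            tested.append(offset + k)
            labels.append(f"{f.label or 'y'}:{names[k]}")
            estimates.append(f.coef[k])
            model_se.append(f.se[k])
        offset += f.coef.shape[0]
    idx = np.asarray(tested)
    sigma_full = stack_covariance(fits)
    sigma_alt_full = stack_covariance_alt(fits)
    sigma = sigma_full[np.ix_(idx, idx)]
    sigma_alt = sigma_alt_full[np.ix_(idx, idx)]
    chosen = sigma_alt if which_sigma == "alt" else sigma
    R = correlation_matrix(chosen)
    estimates = np.asarray(estimates)
    with np.errstate(invalid="ignore"):
        sandwich_se = np.sqrt(np.diag(chosen) / n)
    se = sandwich_se if se_mode == "sandwich" else np.asarray(model_se)
    if np.any(~np.isfinite(se)) or np.any(se <= 0):
        raise MMMUnavailable("non-finite or non-positive standard errors in family")
    t = estimates / se
    return StackedInference(
        estimates=estimates,
        se=se,
        t=t,
        R=R,
        sigma=sigma,
        sigma_alt=sigma_alt,
        labels=tuple(labels),
        n=n,
        se_mode=se_mode,
    )


@dataclass
class AdjustmentResult:
    """Raw and adjusted p-values for one family of hypotheses."""

    labels: tuple[str, ...]
    p_raw: np.ndarray
    p_adj: np.ndarray
    method: str
    alpha: float = 0.05
    estimates: np.ndarray | None = None
    se: np.ndarray | None = None
    t: np.ndarray | None = None
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def rejected(self) -> np.ndarray:
        return self.p_adj < self.alpha

    def to_frame(self):
        import pandas as pd

        cols = {
            "hypothesis": list(self.labels),
            "p_raw": self.p_raw,
            "p_adj": self.p_adj,
            "method": self.method,
        }
        for name in ("estimates", "se", "t", "ci_low", "ci_high"):
            v = getattr(self, name)
            if v is not None:
                cols[name.rstrip("s") if name == "estimates" else name] = v
        return pd.DataFrame(cols)


def adjust_mmm(stacked: StackedInference, alpha: float = 0.05) -> AdjustmentResult:
    """Single-step adjusted p-values ``P(max_q |z_q| > |t|)`` under MVN(0, R)."""
    p_adj = np.array(
        [1.0 - max_abs_mvn_prob(abs(t), stacked.R) for t in stacked.t]
    )
    p_adj = np.clip(np.maximum(p_adj, stacked.p_raw), 0.0, 1.0)
    return AdjustmentResult(
        labels=stacked.labels,
        p_raw=stacked.p_raw,
        p_adj=p_adj,
        method="mmm",
        alpha=alpha,
        estimates=stacked.estimates,
        se=stacked.se,
        t=stacked.t,
    )


def bonferroni(
    p_raw: np.ndarray,
    m: int | None = None,
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> AdjustmentResult:
    """Bonferroni single-step adjustment ``min(M p, 1)``."""
    p_raw = np.asarray(p_raw, dtype=float)
    if np.any(p_raw < 0) or np.any(p_raw > 1):
        raise ValueError("raw p-values must lie in [0, 1]")
    m = m if m is not None else p_raw.shape[0]
    labels = tuple(labels) if labels is not None else tuple(
        f"h{i + 1}" for i in range(p_raw.shape[0])
    )
    return AdjustmentResult(
        labels=labels,
        p_raw=p_raw,
        p_adj=np.minimum(m * p_raw, 1.0),
        method="bonferroni",
        alpha=alpha,
    )


def simultaneous_ci(
    stacked: StackedInference, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray, float]:
    """Simultaneous confidence intervals ``beta_q ± c se_q``.

    Uses the same standard errors as the test statistics, so the intervals
    are dual to the adjusted tests: 0 lies outside interval q exactly when
    ``p_adj_q < alpha`` (up to integration tolerance).
    """
    c = critical_value(alpha, stacked.R)
    return stacked.estimates - c * stacked.se, stacked.estimates + c * stacked.se, c
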