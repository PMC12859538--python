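"""Correlated multivariate binary data generation.

Implements the shared-Poisson-component construction of Park, Park & Shin:
endpoint ``j`` is the indicator that a sum of independent Poisson variables is
zero.  Each pair ``(j, k)`` with a positive target correlation shares a Poisson
component with intensity

    lambda_jk = ln(1 + rho_jk * sqrt(q_j q_k / (pi_j pi_k))),   q = 1 - pi,

allocated as a component common to *all* endpoints (intensity
``min_{j<k} lambda_jk``) plus per-pair residuals, with an "own" component per
endpoint topping its total intensity up to ``-ln(pi_j)``.  The event
``Y_j = 1`` occurs exactly when the total count is zero, which has
probability ``pi_j`` and yields pairwise correlation ``rho_jk``; the common
component makes equicorrelated blocks with J > 2 feasible, which a purely
pairwise allocation is not.

On top of the raw generator, :class:`Scenario` describes a dose-response
simulation setting (regression slopes or group offsets on the logit scale, a
null block and an alternative block of endpoints) and
:func:`generate_scenario` draws a complete dataset from it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.special import expit, logit

__all__ = [
    "CorrelatedBinarySpec",
    "Scenario",
    "BinaryEndpointData",
    "InfeasibleCorrelationError",
    "shared_intensity",
    "generate",
    "generate_scenario",
]


class InfeasibleCorrelationError(ValueError):
    """The requested (marginals, correlation) pair is not representable."""


def shared_intensity(rho: float, pi_j: float, pi_k: float) -> float:
    """Intensity of the Poisson component shared by a pair of endpoints.

    Parameters
    ----------
    rho : target Pearson correlation between the two binary endpoints.
    pi_j, pi_k : marginal event probabilities, both in (0, 1).

    Returns
    -------
    float
        ``ln(1 + rho * sqrt(q_j q_k / (pi_j pi_k)))`` with ``q = 1 - pi``;
        zero if and only if ``rho`` is zero.

    Raises
    ------
    InfeasibleCorrelationError
        If the log argument is not positive, i.e. the correlation cannot be
        realised for these marginals.
    """
    if not (0.0 < pi_j < 1.0 and 0.0 < pi_k < 1.0):
        raise ValueError("marginal probabilities must lie strictly in (0, 1)")
    q_j, q_k = 1.0 - pi_j, 1.0 - pi_k
    arg = 1.0 + rho * math.sqrt(q_j * q_k / (pi_j * pi_k))
    if arg <= 0.0:
        raise InfeasibleCorrelationError(
            f"correlation {rho} not representable for marginals "
            f"({pi_j}, {pi_k}): log argument {arg} <= 0"
        )
    return math.log(arg)


@dataclass(frozen=True)
class CorrelatedBinarySpec:
    """Marginals and pairwise correlations of a correlated binary vector.

    ``probs`` holds the event probabilities ``pi_j`` (strictly inside (0, 1)),
    ``corr`` the J x J target correlation matrix with unit diagonal and
    nonnegative off-diagonals.  Feasibility of the shared-component
    construction (every own intensity nonnegative) is verified eagerly.
    """

    probs: np.ndarray
    corr: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        probs = np.atleast_1d(np.asarray(self.probs, dtype=float))
        corr = np.asarray(self.corr, dtype=float)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "corr", corr)
        j = probs.shape[0]
        if np.any(probs <= 0.0) or np.any(probs >= 1.0):
            raise ValueError("all probabilities must lie strictly in (0, 1)")
        if corr.shape != (j, j):
            raise ValueError(f"corr must be {j}x{j}, got {corr.shape}")
        if not np.allclose(corr, corr.T):
            raise ValueError("corr must be symmetric")
        if not np.all(np.diag(corr) == 1.0):
            raise ValueError("corr diagonal must be exactly 1")
        off = corr[~np.eye(j, dtype=bool)]
        if np.any(off < 0.0) or np.any(off > 1.0):
            raise ValueError("off-diagonal correlations must lie in [0, 1]")
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(f"y{i + 1}" for i in range(j))
            )
        elif len(self.labels) != j:
            raise ValueError("labels must match the number of endpoints")
        # eager feasibility check; raises for infeasible settings
        self.intensities()

    @property
    def n_endpoints(self) -> int:
        return self.probs.shape[0]

    def intensities(self) -> tuple[float, np.ndarray, np.ndarray]:
        """Poisson intensity allocation ``(common, pairwise, own)``.

        A component with intensity ``common = min_{j<k} lambda_jk`` is shared
        by *all* endpoints; each pair keeps a residual component
        ``lambda_jk - common``; endpoint ``j`` keeps an own component making
        its total intensity ``-ln(pi_j)``.  The total intensity shared by a
        pair is still exactly ``lambda_jk``, so every pairwise correlation is
        preserved, while the common component makes equicorrelated blocks
        feasible for J > 2 (a purely pairwise allocation is not).
        """
        j = self.n_endpoints
        lam = np.zeros((j, j))
        for a in range(j):
            for b in range(a + 1, j):
                lam[a, b] = lam[b, a] = shared_intensity(
                    self.corr[a, b], self.probs[a], self.probs[b]
                )
        if j >= 3:
            common = float(min(lam[a, b] for a in range(j) for b in range(a + 1, j)))
        else:
            common = 0.0
        resid = lam - common
        np.fill_diagonal(resid, 0.0)
        own = -np.log(self.probs) - common - resid.sum(axis=1)
        bad = np.nonzero(own < -1e-12)[0]
        if bad.size:
            raise InfeasibleCorrelationError(
                f"own Poisson intensity negative for endpoint(s) {bad.tolist()}: "
                "the requested pairwise correlations are jointly infeasible "
                "for these marginals"
            )
        return common, resid, np.clip(own, 0.0, None)


def generate(
    spec: CorrelatedBinarySpec,
    n: int,
    rng: np.random.Generator | int | np.random.SeedSequence,
) -> np.ndarray:
    """Draw an ``n x J`` binary matrix with the spec's marginals/correlations.

    Reproducible given the seed; accepts a ``numpy`` Generator, a
    ``SeedSequence`` or a plain integer seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    common, resid, own = spec.intensities()
    j = spec.n_endpoints
    total = rng.poisson(own, size=(n, j))
    if common > 0.0:
        total += rng.poisson(common, size=n)[:, None]
    for a in range(j):
        for b in range(a + 1, j):
            if resid[a, b] > 0.0:
                shared = rng.poisson(resid[a, b], size=n)
                total[:, a] += shared
                total[:, b] += shared
    return (total == 0).astype(np.int8)


@dataclass
class BinaryEndpointData:
    """An N x J matrix of 0/1 endpoint indicators with a dose covariate."""

    Y: np.ndarray
    dose: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y)
        self.dose = np.asarray(self.dose, dtype=float)
        if self.Y.ndim != 2:
            raise ValueError("Y must be 2-dimensional")
        if self.dose.shape[0] != self.Y.shape[0]:
            raise ValueError("dose and Y must have the same number of rows")
        if not np.isin(self.Y, (0, 1)).all():
            raise ValueError("Y entries must all be 0 or 1")
        self.labels = tuple(self.labels)
        if len(self.labels) != self.Y.shape[1]:
            raise ValueError("labels must match the number of endpoint columns")

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def n_endpoints(self) -> int:
        return self.Y.shape[1]

    @property
    def group(self) -> np.ndarray:
        """Dose as an ordered group code (0 = lowest dose = control)."""
        levels = np.unique(self.dose)
        return np.searchsorted(levels, self.dose)


@dataclass
class Scenario:
    """One simulation setting: design, effect sizes, correlation, blocks.

    ``effects`` holds the per-endpoint effect parameters on the logit scale:
    a single slope per endpoint for ``kind='regression'``, or one offset per
    non-control dose group (length ``K``) for ``kind='group_comparison'``.
    Null-block endpoints must have all effect parameters equal to zero; the
    null and alternative blocks are sampled from independent random streams so
    their between-block correlation is not specified (zero in expectation).
    """

    kind: Literal["regression", "group_comparison"]
    dose_levels: Sequence[float]
    n: int
    intercepts: Sequence[float]
    effects: Sequence
    rho: float
    null_block: Sequence[int] = ()
    alt_block: Sequence[int] = ()
    alpha: float = 0.05
    labels: tuple[str, ...] = ()
    scenario_id: str = ""

    def __post_init__(self) -> None:
        self.dose_levels = tuple(float(x) for x in self.dose_levels)
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        j = self.intercepts.shape[0]
        eff = np.atleast_2d(np.asarray(self.effects, dtype=float))
        if eff.shape[0] == 1 and j > 1:
            eff = np.repeat(eff, j, axis=0)
        if eff.shape[0] != j:
            raise ValueError("effects must have one row per endpoint")
        if self.kind == "regression" and eff.shape[1] != 1:
            raise ValueError("regression scenarios take one slope per endpoint")
        if self.kind == "group_comparison" and eff.shape[1] != len(self.dose_levels) - 1:
            raise ValueError(
                "group comparison scenarios take one offset per non-control group"
            )
        self.effects = eff
        if self.n % len(self.dose_levels):
            raise ValueError("n must divide evenly across the dose groups")
        self.null_block = tuple(int(i) for i in self.null_block)
        self.alt_block = tuple(int(i) for i in self.alt_block)
        if not self.null_block and not self.alt_block:
            self.null_block = tuple(
                i for i in range(j) if not np.any(self.effects[i])
            )
            self.alt_block = tuple(
                i for i in range(j) if np.any(self.effects[i])
            )
        if sorted(self.null_block + self.alt_block) != list(range(j)):
            raise ValueError("null and alternative blocks must partition endpoints")
        if any(np.any(self.effects[i]) for i in self.null_block):
            raise ValueError("null-block endpoints must have zero effects")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not self.labels:
            self.labels = tuple(f"y{i + 1}" for i in range(j))

    @property
    def n_endpoints(self) -> int:
        return self.intercepts.shape[0]

    @property
    def group_size(self) -> int:
        return self.n // len(self.dose_levels)

    def event_probability(self, endpoint: int, dose_index: int) -> float:
        """Marginal event probability for an endpoint in one dose group."""
        b0 = self.intercepts[endpoint]
        if self.kind == "regression":
            eta = b0 + self.effects[endpoint, 0] * self.dose_levels[dose_index]
        else:
            eta = b0 + (
                self.effects[endpoint, dose_index - 1] if dose_index > 0 else 0.0
            )
        return float(expit(eta))


def _block_spec(scenario: Scenario, block: tuple[int, ...], dose_index: int) -> CorrelatedBinarySpec:
    probs = np.array(
        [scenario.event_probability(j, dose_index) for j in block]
    )
    j = len(block)
    corr = np.full((j, j), scenario.rho)
    np.fill_diagonal(corr, 1.0)
    return CorrelatedBinarySpec(
        probs=probs, corr=corr, labels=tuple(scenario.labels[i] for i in block)
    )


def generate_scenario(
    scenario: Scenario,
    seed: int | np.random.SeedSequence,
) -> BinaryEndpointData:
    """Draw one complete dataset from a scenario.

    The null block and the alternative block use independent random
    substreams, and within each block every dose group has its own substream,
    so adding endpoints to one block never perturbs the draws of the other.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    null_ss, alt_ss = ss.spawn(2)
    g = len(scenario.dose_levels)
    m = scenario.group_size
    dose = np.repeat(scenario.dose_levels, m)
    Y = np.empty((scenario.n, scenario.n_endpoints), dtype=np.int8)
    for block, block_ss in (
        (scenario.null_block, null_ss),
        (scenario.alt_block, alt_ss),
    ):
        if not block:
            continue
        group_streams = block_ss.spawn(g)
        cols = np.asarray(block)
        for d in range(g):
            spec = _block_spec(scenario, tuple(block), d)
            rows = slice(d * m, (d + 1) * m)
            Y[rows, cols] = generate(spec, m, group_streams[d])
    return BinaryEndpointData(Y=Y, dose=dose, labels=scenario.labels)


def regression_scenario(
    *,
    n: int,
    n_endpoints: int,
    pi0: float,
    rho: float,
    slopes: float | Sequence[float] = 0.0,
    dose_levels: Sequence[float] = (0.0, 2.5, 5.0, 10.0),
    alpha: float = 0.05,
    n_alternative: int | None = None,
    scenario_id: str = "",
) -> Scenario:
    """Convenience constructor for the standard dose-regression setting.

    ``pi0`` is the event probability at dose 0, so the common intercept is
    ``logit(pi0)``.  If ``n_alternative`` is given, the first
    ``n_alternative`` endpoints receive the (scalar) slope and the rest are
    null; otherwise ``slopes`` may be a per-endpoint sequence.
    """
    intercepts = np.full(n_endpoints, logit(pi0))
    blocks: dict = {}
    if n_alternative is not None:
        if not np.isscalar(slopes):
            raise ValueError("give a scalar slope with n_alternative")
        slope_vec = np.zeros(n_endpoints)
        slope_vec[:n_alternative] = float(slopes)
        blocks = dict(
            alt_block=tuple(range(n_alternative)),
            null_block=tuple(range(n_alternative, n_endpoints)),
        )
    else:
        slope_vec = np.broadcast_to(
            np.asarray(slopes, dtype=float), (n_endpoints,)
        ).copy()
    return Scenario(
        **blocks,
        kind="regression",
        dose_levels=dose_levels,
        n=n,
        intercepts=intercepts,
        effects=slope_vec[:, None],
        rho=rho,
        alpha=alpha,
        scenario_id=scenario_id,
    )
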