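"""Readers, writers, analysis configuration, and the end-to-end recipes.

The on-disk data dialect is a plain CSV with a header row, an optional ``id``
column, a numeric ``dose`` column, and one 0/1 column per endpoint.  The
worked-example recipe mirrors a typical long-term carcinogenicity analysis:
read the per-animal tumor indicators, drop endpoints with five or fewer
events in total, fit a marginal dose-slope logistic model per retained tumor
class, and adjust the slope p-values by Bonferroni, the stacked
multiple-marginal-models procedure, and minP bootstrap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .bayes import PriorSpec, fit_bayes_logit
from .datagen import BinaryEndpointData
from .glm import DesignSpec, fit_logit
from .minp import ResamplingPlan, minp_adjust
from .mmm import (
    MMMUnavailable,
    adjust_mmm,
    bonferroni,
    simultaneous_ci,
    stack,
)

__all__ = [
    "AnalysisConfig",
    "read_endpoint_csv",
    "write_endpoint_csv",
    "filter_endpoints",
    "run_adjust",
]


def read_endpoint_csv(path: str | Path) -> BinaryEndpointData:
    """Read a binary-endpoint CSV into a validated container.

    Requires a header with a ``dose`` column; every non-``id``/``dose``
    column is an endpoint and must be strictly 0/1 with no missing values.
    Validation errors name the offending rows and columns.
    """
    df = pd.read_csv(path)
    lowered = {c.lower(): c for c in df.columns}
    if "dose" not in lowered:
        raise ValueError(
            f"{path}: no 'dose' column found (columns: {list(df.columns)}); "
            "a header row with a dose column is required"
        )
    dose_col = lowered["dose"]
    endpoint_cols = [
        c for c in df.columns if c not in (dose_col, lowered.get("id"))
    ]
    if not endpoint_cols:
        raise ValueError(f"{path}: no endpoint columns found")
    problems = []
    for c in endpoint_cols:
        col = df[c]
        if col.isna().any():
            rows = (col[col.isna()].index + 2).tolist()[:5]
            problems.append(f"column {c!r}: missing values at file rows {rows}")
            continue
        bad = ~col.isin([0, 1])
        if bad.any():
            rows = (col[bad].index + 2).tolist()[:5]
            vals = col[bad].unique().tolist()[:5]
            problems.append(
                f"column {c!r}: non-binary values {vals} at file rows {rows}"
            )
    if df[dose_col].isna().any():
        problems.append(f"column {dose_col!r}: missing dose values")
    if problems:
        raise ValueError(f"{path}: invalid endpoint data — " + "; ".join(problems))
    return BinaryEndpointData(
        Y=df[endpoint_cols].to_numpy(dtype=np.int8),
        dose=df[dose_col].to_numpy(dtype=float),
        labels=tuple(endpoint_cols),
    )


def write_endpoint_csv(data: BinaryEndpointData, path: str | Path) -> None:
    """Write the ``id,dose,<endpoints...>`` CSV dialect (header mandatory)."""
    df = pd.DataFrame(
        {"id": np.arange(1, data.n + 1), "dose": data.dose}
    )
    for j, lbl in enumerate(data.labels):
        df[lbl] = data.Y[:, j].astype(int)
    df.to_csv(path, index=False)


def filter_endpoints(data: BinaryEndpointData, min_events: int) -> BinaryEndpointData:
    """Keep endpoints whose total event count is *strictly greater* than
    ``min_events`` (so ``min_events=5`` keeps endpoints with 6+ events)."""
    if min_events < 0:
        raise ValueError("min_events must be >= 0")
    totals = np.asarray(data.Y).sum(axis=0)
    keep = totals > min_events
    if not keep.any():
        raise ValueError(
            f"no endpoints with more than {min_events} events "
            f"(totals: {dict(zip(data.labels, totals.tolist()))})"
        )
    return BinaryEndpointData(
        Y=data.Y[:, keep],
        dose=data.dose,
        labels=tuple(l for l, k in zip(data.labels, keep) if k),
    )


@dataclass
class AnalysisConfig:
    """Everything an ``adjust`` run needs, serialisable to the manifest."""

    input_path: str
    design: Literal["regression", "group_comparison"] = "regression"
    model_class: Literal["glm", "bayesglm"] = "glm"
    methods: tuple[str, ...] = ("bonferroni", "mmm", "minp-bootstrap")
    alpha: float = 0.05
    B: int = 10_000
    seed: int = 1
    endpoints: tuple[str, ...] = ()
    min_events: int | None = None
    ci: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_events is not None and self.min_events < 0:
            raise ValueError("min_events must be >= 0")
        if not self.methods:
            raise ValueError("at least one adjustment method is required")


def _fit_all(data: BinaryEndpointData, design: DesignSpec, config: AnalysisConfig):
    fits = []
    for j, lbl in enumerate(data.labels):
        if config.model_class == "bayesglm":
            fits.append(fit_bayes_logit(data.Y[:, j], design, label=lbl))
        else:
            fits.append(fit_logit(data.Y[:, j], design, label=lbl))
    return fits


def run_adjust(config: AnalysisConfig, data: BinaryEndpointData | None = None) -> pd.DataFrame:
    """End-to-end analysis: read, filter, fit, adjust, tabulate.

    Returns one row per hypothesis and method with estimate, standard error,
    t statistic, raw and adjusted p-values (full precision), and simultaneous
    confidence bounds for the MMM method when ``config.ci`` is set.
    Deterministic given ``config.seed``.
    """
    if data is None:
        data = read_endpoint_csv(config.input_path)
    if config.endpoints:
        keep = [data.labels.index(e) for e in config.endpoints]
        data = BinaryEndpointData(
            Y=data.Y[:, keep], dose=data.dose, labels=tuple(config.endpoints)
        )
    if config.min_events is not None:
        data = filter_endpoints(data, config.min_events)
    design = DesignSpec(kind=config.design, dose=data.dose)
    fits = _fit_all(data, design, config)
    tested = design.tested_indices
    names = design.parameter_names
    rows = []
    labels = []
    est, se_model, t_model, p_model = [], [], [], []
    for f in fits:
        for k in tested:
            labels.append((f.label, names[k]))
            est.append(float(f.coef[k]))
            se_model.append(float(f.se[k]))
    est = np.asarray(est)
    se_model = np.asarray(se_model)
    with np.errstate(invalid="ignore"):
        t_model = est / se_model
    from scipy.stats import norm

    p_model = 2.0 * norm.sf(np.abs(t_model))
    p_model = np.where(np.isfinite(p_model), p_model, 1.0)
    m = len(labels)

    def emit(method, p_raw, p_adj, se_used, t_used, ci_low=None, ci_high=None, note=""):
        for i, (lbl, par) in enumerate(labels):
            rows.append(
                {
                    "endpoint": lbl,
                    "parameter": par,
                    "estimate": est[i],
                    "se": se_used[i],
                    "t": t_used[i],
                    "p_raw": p_raw[i],
                    "p_adj": p_adj[i],
                    "method": method,
                    "model_class": config.model_class,
                    "ci_low": np.nan if ci_low is None else ci_low[i],
                    "ci_high": np.nan if ci_high is None else ci_high[i],
                    "note": note,
                }
            )

    for method in config.methods:
        if method == "bonferroni":
            res = bonferroni(p_model, m, alpha=config.alpha)
            emit(method, p_model, res.p_adj, se_model, t_model)
        elif method == "mmm":
            try:
                stacked = stack(fits)
                res = adjust_mmm(stacked, alpha=config.alpha)
                ci_low = ci_high = None
                if config.ci:
                    ci_low, ci_high, _ = simultaneous_ci(stacked, config.alpha)
                emit(method, stacked.p_raw, res.p_adj, stacked.se, stacked.t,
                     ci_low, ci_high)
            except MMMUnavailable as exc:
                emit(
                    method,
                    p_model,
                    np.full(m, np.nan),
                    se_model,
                    t_model,
                    note=f"unavailable: {exc}; consider --model-class bayesglm",
                )
        elif method in ("minp-bootstrap", "minp-permutation"):
            plan = ResamplingPlan(
                B=config.B,
                sampler="bootstrap" if method.endswith("bootstrap") else "permutation",
                seed=config.seed,
                fit_producer=config.model_class,
            )
            res = minp_adjust(data, design, plan, alpha=config.alpha)
            emit(method, res.p_raw, res.p_adj, se_model, t_model)
        else:
            raise ValueError(f"unknown method {method!r}")
    return pd.DataFrame(rows)


def write_manifest(config: AnalysisConfig, path: str | Path) -> None:
    """Record config, seed and library versions next to the results."""
    import multibin

    manifest = {
        "config": asdict(config),
        "versions": {
            "multibin": multibin.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
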