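"""Unified model-fitting interface: one entry point for all ensemble members.

Normal-likelihood models are fit from summary statistics by quadrature
(zero Monte-Carlo error); t-likelihood models require raw data and go
through MCMC plus bridge sampling.  Every fit is tagged with a hash of
its input data so that Bayes factors can only be formed between fits of
the same data under the same priors.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import SummaryStats, TwoSampleData, summarize
from .marglik_normal import logml_normal, sample_posterior_normal
from .marglik_t import SamplerSettings, run_t_model
from .models import ModelSpec
from .priors import PriorSettings

__all__ = ["ModelFit", "fit_model", "bayes_factor", "BayesFactor", "SamplerSettings"]


@dataclass
class ModelFit:
    """Log marginal likelihood with uncertainty plus posterior draws.

    ``log_ml_se`` is the Monte-Carlo standard error of ``log_ml`` (zero
    for the quadrature path).  ``draws`` maps parameter names
    (mu/sigma/delta/rho/nu) to arrays; parameters fixed by the model
    spec appear as constants (delta = 0, rho = 0.5, nu = inf).
    """

    spec: ModelSpec
    log_ml: float
    log_ml_se: float = 0.0
    draws: dict[str, np.ndarray] | None = None
    diagnostics: dict = field(default_factory=dict)
    data_hash: str = ""

    def __post_init__(self):
        if not math.isfinite(self.log_ml):
            raise ValueError(f"{self.spec.name}: non-finite log marginal likelihood")
        if self.log_ml_se < 0:
            raise ValueError("log_ml_se must be nonnegative")

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", True))

    def to_json(self) -> str:
        d = {
            "spec": dataclasses.asdict(self.spec),
            "log_ml": self.log_ml,
            "log_ml_se": self.log_ml_se,
            "diagnostics": _jsonable(self.diagnostics),
            "data_hash": self.data_hash,
        }
        return json.dumps(d)

    def draws_frame(self) -> pd.DataFrame:
        if self.draws is None:
            raise ValueError("fit holds no posterior draws")
        return pd.DataFrame(
            {k: self.draws[k] for k in ("mu", "sigma", "delta", "rho", "nu")
             if k in self.draws}
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def fit_model(
    data_or_stats: TwoSampleData | SummaryStats,
    spec: ModelSpec,
    priors: PriorSettings | None = None,
    settings: SamplerSettings | None = None,
    include_draws: bool = True,
    n_normal_draws: int = 4000,
    rtol: float = 1e-8,
) -> ModelFit:
    """Fit one ensemble member and return its :class:`ModelFit`.

    Normal-likelihood models accept raw data or summary statistics;
    t-likelihood models require raw data (the Student-t likelihood has
    no sufficient-statistic reduction).
    """
    priors = priors or PriorSettings()
    if spec.likelihood == "normal":
        if isinstance(data_or_stats, TwoSampleData):
            stats_ = summarize(data_or_stats)
            data_hash = data_or_stats.data_hash()
        else:
            stats_ = data_or_stats
            data_hash = stats_.data_hash()
        log_ml = logml_normal(stats_, spec, priors, rtol=rtol)
        draws = None
        if include_draws:
            seed = settings.seed if settings is not None else 0
            rng = np.random.default_rng(np.random.SeedSequence((seed, 0xA11CE)))
            draws = sample_posterior_normal(
                stats_, spec, priors, n_draws=n_normal_draws, rng=rng
            )
        return ModelFit(
            spec=spec, log_ml=log_ml, log_ml_se=0.0, draws=draws,
            diagnostics={"method": "quadrature", "rtol": rtol, "converged": True},
            data_hash=data_hash,
        )

    if not isinstance(data_or_stats, TwoSampleData):
        raise TypeError(
            f"{spec.name}: t-likelihood models require raw data, not summary statistics"
        )
    res = run_t_model(data_or_stats, spec, priors, settings)
    draws = res.draws if include_draws else None
    return ModelFit(
        spec=spec, log_ml=res.log_ml, log_ml_se=res.log_ml_se, draws=draws,
        diagnostics={"method": "bridge", **res.diagnostics},
        data_hash=data_or_stats.data_hash(),
    )


@dataclass(frozen=True)
class BayesFactor:
    """A Bayes factor with the standard error of its logarithm."""

    value: float
    log_se: float = 0.0

    def __float__(self):
        return self.value

    @property
    def log10(self) -> float:
        return math.log10(self.value)

    def __repr__(self):
        return f"BayesFactor({format_bf(self.value)}, log_se={self.log_se:.3g})"


def format_bf(bf: float) -> str:
    """Report formatting: one decimal above 10, 3 significant digits below."""
    if bf >= 10:
        return f"{bf:.1f}"
    return f"{bf:.3g}"


def bayes_factor(fit1: ModelFit, fit0: ModelFit) -> BayesFactor:
    """BF10 = p(y | model 1) / p(y | model 0) with propagated standard error."""
    if fit1.data_hash != fit0.data_hash:
        raise ValueError(
            "Bayes factor requested between fits of different datasets "
            f"({fit1.data_hash} vs {fit0.data_hash})"
        )
    log_bf = fit1.log_ml - fit0.log_ml
    se = math.hypot(fit1.log_ml_se, fit0.log_ml_se)
    return BayesFactor(value=math.exp(log_bf), log_se=se)
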