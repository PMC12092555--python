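"""Posterior model probabilities, inclusion Bayes factors, model averaging.

This is the package's top-level entry point: :func:`fit_ensemble` fits
every member of the chosen ensemble (Student pair, Welch pair, the
four-model MB ensemble, or the eight-model robust RoMB ensemble),
combines the marginal likelihoods into posterior model probabilities,
computes the three inclusion Bayes factors (effect, unequal variances,
outliers), and produces model-averaged and conditional posterior
summaries of delta, the SD ratio, and nu.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import time
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

from .data import SummaryStats, TwoSampleData
from .marglik import ModelFit, SamplerSettings, fit_model
from .models import ENSEMBLES, ModelSpec
from .priors import PriorSettings, sdr_from_rho

__all__ = [
    "posterior_model_probs",
    "inclusion_bf",
    "model_averaged_posterior",
    "fit_ensemble",
    "EnsembleResult",
    "ParameterSummary",
]


def posterior_model_probs(log_mls, prior_probs) -> np.ndarray:
    """Posterior model probabilities ∝ prior probability × marginal likelihood.

    Computed as a log-sum-exp-stabilized softmax of
    ``log_ml + log prior``; models with zero prior probability get zero
    posterior probability regardless of their marginal likelihood.
    """
    log_mls = np.asarray(log_mls, dtype=float)
    prior_probs = np.asarray(prior_probs, dtype=float)
    if log_mls.shape != prior_probs.shape:
        raise ValueError(
            f"length mismatch: {log_mls.shape[0]} marginal likelihoods vs "
            f"{prior_probs.shape[0]} prior probabilities"
        )
    if np.any(prior_probs < 0) or abs(prior_probs.sum() - 1.0) > 1e-9:
        raise ValueError("prior_probs must be a probability vector")
    with np.errstate(divide="ignore"):
        score = log_mls + np.log(prior_probs)
    m = score[np.isfinite(score)].max()
    w = np.exp(score - m)
    return w / w.sum()


def inclusion_bf(model_probs, prior_probs, indicator) -> float:
    """Change from prior to posterior odds for a *set* of models.

    ``indicator`` is a boolean mask (or index list) selecting the models
    that share the component of interest; it must be neither empty nor
    the full set.
    """
    model_probs = np.asarray(model_probs, dtype=float)
    prior_probs = np.asarray(prior_probs, dtype=float)
    mask = np.zeros(model_probs.size, dtype=bool)
    idx = np.asarray(indicator)
    if idx.size:
        mask[idx.astype(int) if idx.dtype != bool else idx] = True
    if not mask.any() or mask.all():
        raise ValueError("indicator must select a proper nonempty subset of models")
    post_in, post_out = model_probs[mask].sum(), model_probs[~mask].sum()
    prior_in, prior_out = prior_probs[mask].sum(), prior_probs[~mask].sum()
    if post_out == 0.0 or prior_in == 0.0:
        warnings.warn("inclusion Bayes factor is infinite (zero denominator)")
        return math.inf
    return (post_in / post_out) / (prior_in / prior_out)


def inclusion_bf_log_se(log_mls, log_ml_ses, prior_probs, indicator) -> float:
    """Delta-method SE of the log inclusion BF from per-model log-ML SEs."""
    log_mls = np.asarray(log_mls, dtype=float)
    ses = np.asarray(log_ml_ses, dtype=float)
    prior = np.asarray(prior_probs, dtype=float)
    mask = np.zeros(log_mls.size, dtype=bool)
    mask[np.asarray(indicator)] = True
    post = posterior_model_probs(log_mls, prior)
    var = 0.0
    for part in (mask, ~mask):
        tot = post[part].sum()
        if tot > 0:
            w = post[part] / tot
            var += float(np.sum((w * ses[part]) ** 2))
    return math.sqrt(var)


@dataclass(frozen=True)
class ParameterSummary:
    """Central posterior summary: mean (median for nu) and 95% interval."""

    center: float
    ci_low: float
    ci_high: float
    statistic: str = "mean"
    n_draws: int = 0

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _param_draws(fit: ModelFit, parameter: str, priors: PriorSettings) -> np.ndarray:
    """Draws of the requested parameter, using spec-implied constants."""
    if parameter == "delta":
        if not fit.spec.delta_free:
            return np.array([0.0])
        return fit.draws["delta"]
    if parameter == "sdr":
        if not fit.spec.rho_free:
            return np.array([1.0])
        return np.asarray(sdr_from_rho(fit.draws["rho"], priors.sdr_convention))
    if parameter == "rho":
        if not fit.spec.rho_free:
            return np.array([0.5])
        return fit.draws["rho"]
    if parameter == "nu":
        if not fit.spec.nu_free:
            return np.array([np.inf])
        return fit.draws["nu"]
    raise ValueError(f"unknown parameter {parameter!r}")


def model_averaged_posterior(
    fits: list[ModelFit],
    model_probs,
    parameter: str,
    n_draws: int = 100_000,
    seed: int = 0,
    conditional: bool = False,
    priors: PriorSettings | None = None,
) -> tuple[np.ndarray, ParameterSummary]:
    """Mixture draws and summary of a model-averaged parameter.

    Implements the mixture algorithm directly: sample a model in
    proportion to its posterior probability, then draw a parameter value
    from that model (a spec-implied constant when the parameter is fixed
    there).  ``conditional=True`` restricts to models in which the
    parameter is free, renormalizing the weights.
    """
    priors = priors or PriorSettings()
    n_draws = int(n_draws)
    if n_draws < 1000:
        warnings.warn(f"n_draws={n_draws} is small; summaries will be noisy")
    probs = np.asarray(model_probs, dtype=float).copy()
    free_attr = {"delta": "delta_free", "sdr": "rho_free",
                 "rho": "rho_free", "nu": "nu_free"}[parameter]
    if conditional:
        keep = np.array([getattr(f.spec, free_attr) for f in fits])
        if not keep.any() or probs[keep].sum() <= 0:
            raise ValueError(
                f"conditional summary of {parameter!r} requested but no model "
                "with that parameter free carries posterior mass"
            )
        probs = np.where(keep, probs, 0.0)
        probs = probs / probs.sum()

    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_draws, probs)
    pieces = []
    for fit, k in zip(fits, counts):
        if k == 0:
            continue
        src = _param_draws(fit, parameter, priors)
        pieces.append(rng.choice(src, size=k, replace=True))
    mixed = np.concatenate(pieces)
    rng.shuffle(mixed)

    with np.errstate(invalid="ignore"):  # inf draws (nu) are legitimate
        ci_low, ci_high = np.quantile(mixed, [0.025, 0.975])
    if parameter == "nu":
        center = float(np.median(mixed))
        stat = "median"
    else:
        center = float(np.mean(mixed))
        stat = "mean"
    summary = ParameterSummary(
        center=center, ci_low=float(ci_low), ci_high=float(ci_high),
        statistic=stat, n_draws=n_draws,
    )
    return mixed, summary


@dataclass
class EnsembleResult:
    """Full output of a model-averaged analysis."""

    ensemble: str
    specs: tuple[ModelSpec, ...]
    log_mls: np.ndarray
    log_ml_ses: np.ndarray
    prior_probs: np.ndarray
    model_probs: np.ndarray
    incl_bf_effect: float | None
    incl_bf_variances: float | None
    incl_bf_outliers: float | None
    incl_bf_ses: dict[str, float]
    averaged: dict[str, dict[str, ParameterSummary]]
    fits: list[ModelFit]
    data_hash: str = ""
    seed: int = 0

    def model_table(self) -> list[dict]:
        rows = []
        for spec, lml, se, pp, mp in zip(
            self.specs, self.log_mls, self.log_ml_ses,
            self.prior_probs, self.model_probs,
        ):
            rows.append({
                "model": spec.name,
                "effect": spec.effect,
                "variances": spec.variances,
                "likelihood": spec.likelihood,
                "log_ml": float(lml),
                "log_ml_se": float(se),
                "prior_prob": float(pp),
                "posterior_prob": float(mp),
            })
        return rows

    def to_dict(self) -> dict:
        return {
            "ensemble": self.ensemble,
            "seed": self.seed,
            "data_hash": self.data_hash,
            "models": self.model_table(),
            "inclusion_bf": {
                "effect": self.incl_bf_effect,
                "variances": self.incl_bf_variances,
                "outliers": self.incl_bf_outliers,
            },
            "inclusion_bf_log_se": self.incl_bf_ses,
            "estimates": {
                param: {kind: s.as_dict() for kind, s in kinds.items()}
                for param, kinds in self.averaged.items()
            },
        }

    def to_json(self, **kwargs) -> str:
        def default(o):
            if isinstance(o, float) and math.isinf(o):
                return "inf" if o > 0 else "-inf"
            raise TypeError(o)
        return json.dumps(_sanitize(self.to_dict()), default=default, **kwargs)


def _sanitize(obj):
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and math.isinf(obj):
        return "inf" if obj > 0 else "-inf"
    return obj


def fit_ensemble(
    data_or_stats: TwoSampleData | SummaryStats,
    priors: PriorSettings | None = None,
    ensemble: str = "romb8",
    settings: SamplerSettings | None = None,
    seed: int | None = None,
    n_mixture_draws: int = 100_000,
    include_draws: bool = True,
) -> EnsembleResult:
    """Fit all members of an ensemble and assemble model-averaged inference.

    ``ensemble`` is one of ``student``, ``welch``, ``mb4``, ``romb8``.
    The robust ensemble requires raw data.  Deterministic given ``seed``
    (which overrides ``settings.seed`` when provided).
    """
    priors = priors or PriorSettings()
    if ensemble not in ENSEMBLES:
        raise ValueError(f"unknown ensemble {ensemble!r}; choose from {list(ENSEMBLES)}")
    specs = ENSEMBLES[ensemble]
    if any(s.likelihood == "t" for s in specs) and not isinstance(
        data_or_stats, TwoSampleData
    ):
        raise TypeError(f"ensemble {ensemble!r} requires raw data (t-likelihood members)")

    if priors.prior_model_probs is not None:
        prior_probs = np.asarray(priors.prior_model_probs, dtype=float)
        if prior_probs.size != len(specs):
            raise ValueError(
                f"prior_model_probs has length {prior_probs.size}, "
                f"ensemble {ensemble!r} has {len(specs)} members"
            )
    else:
        prior_probs = np.full(len(specs), 1.0 / len(specs))

    base_settings = settings or SamplerSettings()
    if seed is None:
        seed = base_settings.seed
    fits: list[ModelFit] = []
    for i, spec in enumerate(specs):
        model_settings = dataclasses.replace(base_settings, seed=seed * 1000 + i)
        t0 = time.perf_counter()
        try:
            fits.append(
                fit_model(data_or_stats, spec, priors, settings=model_settings,
                          include_draws=include_draws)
            )
        except Exception as err:
            raise RuntimeError(f"fit of model {spec.name} failed: {err}") from err
        logger.debug(
            "fitted %s in %.2fs (log_ml=%.4f, se=%.4f)",
            spec.name, time.perf_counter() - t0,
            fits[-1].log_ml, fits[-1].log_ml_se,
        )

    log_mls = np.array([f.log_ml for f in fits])
    ses = np.array([f.log_ml_se for f in fits])
    model_probs = posterior_model_probs(log_mls, prior_probs)

    def _incl(mask):
        idx = np.flatnonzero(mask)
        if idx.size == 0 or idx.size == len(specs):
            return None, None
        bf = inclusion_bf(model_probs, prior_probs, idx)
        se = inclusion_bf_log_se(log_mls, ses, prior_probs, idx)
        return bf, se

    eff_mask = np.array([s.delta_free for s in specs])
    var_mask = np.array([s.rho_free for s in specs])
    out_mask = np.array([s.nu_free for s in specs])
    bf_eff, se_eff = _incl(eff_mask)
    bf_var, se_var = _incl(var_mask)
    bf_out, se_out = _incl(out_mask)
    incl_ses = {
        k: v for k, v in
        (("effect", se_eff), ("variances", se_var), ("outliers", se_out))
        if v is not None
    }

    averaged: dict[str, dict[str, ParameterSummary]] = {}
    params = (
        (["delta", "sdr", "rho"] + (["nu"] if any(out_mask) else []))
        if include_draws else []
    )
    for j, param in enumerate(params):
        kinds = {}
        _, kinds["averaged"] = model_averaged_posterior(
            fits, model_probs, param, n_draws=n_mixture_draws,
            seed=seed * 100 + j, priors=priors,
        )
        free_attr = {"delta": eff_mask, "sdr": var_mask,
                     "rho": var_mask, "nu": out_mask}[param]
        if free_attr.any() and model_probs[free_attr].sum() > 0:
            _, kinds["conditional"] = model_averaged_posterior(
                fits, model_probs, param, n_draws=n_mixture_draws,
                seed=seed * 100 + 50 + j, conditional=True, priors=priors,
            )
        averaged[param] = kinds

    return EnsembleResult(
        ensemble=ensemble,
        specs=specs,
        log_mls=log_mls,
        log_ml_ses=ses,
        prior_probs=prior_probs,
        model_probs=model_probs,
        incl_bf_effect=bf_eff,
        incl_bf_variances=bf_var,
        incl_bf_outliers=bf_out,
        incl_bf_ses=incl_ses,
        averaged=averaged,
        fits=fits,
        data_hash=fits[0].data_hash,
        seed=seed,
    )
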