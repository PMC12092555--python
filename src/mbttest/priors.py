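"""Parametrization and prior distributions for the t-test ensembles.

The common parameter vector is (mu, sigma, delta, rho, nu):

* ``mu``     grand location (outcome units);
* ``sigma``  grand scale > 0, defined through sigma1^2 + sigma2^2 = 2 sigma^2;
* ``delta``  Cohen's delta, the standardized mean difference (mu2 - mu1)/sigma;
* ``rho``    precision proportion of group 1, in (0, 1) — the share of
  group 1's precision (inverse variance) in the total precision;
* ``nu``     degrees of freedom of the t likelihood, in (2, inf];
  ``nu = inf`` encodes the normal likelihood.

Default priors: delta ~ Cauchy(0, 1/sqrt(2)); rho ~ Beta(1.5, 1.5);
nu - 2 ~ Exponential(scale 1) (prior mean 3, interquartile range roughly
2.3 to 3.4, so the t likelihood always has finite mean and variance);
nuisance prior p(mu, sigma) ∝ 1/sigma (Jeffreys), shared across all
models so that its improper constant cancels in every Bayes factor.

The standard deviation ratio SDR = sigma1/sigma2 relates to rho as
SDR = sqrt((1 - rho)/rho): for example, variances 2 and 4 give
precisions 1/2 and 1/4, hence rho = 2/3 and SDR = sqrt(1/2).  A
``sdr_convention`` switch flips the reported ratio to sigma2/sigma1.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import yaml
from scipy import special, stats

__all__ = [
    "PriorSettings",
    "ParameterVector",
    "rho_from_variances",
    "sdr_from_rho",
    "rho_from_sdr",
    "group_params",
    "common_params",
    "t_scale",
    "log_prior",
    "prior_mass_sdr_interval",
    "nu_prior_summary",
]

DEFAULT_CAUCHY_SCALE = 1.0 / math.sqrt(2.0)


@dataclass(frozen=True)
class PriorSettings:
    """Hyperparameters of all parameter priors plus prior model probabilities.

    ``delta_truncation`` optionally restricts the Cauchy prior on delta to
    an interval (one-sided tests); ``prior_model_probs`` defaults to the
    uniform distribution over whichever ensemble is being fit.
    """

    delta_family: str = "cauchy"
    delta_location: float = 0.0
    delta_scale: float = DEFAULT_CAUCHY_SCALE
    delta_truncation: tuple[float, float] | None = None
    rho_a: float = 1.5
    rho_b: float = 1.5
    nu_shift: float = 2.0
    nu_scale: float = 1.0
    prior_model_probs: tuple[float, ...] | None = None
    sdr_convention: str = "group1_over_group2"

    def __post_init__(self):
        if self.delta_family != "cauchy":
            raise ValueError(f"unsupported delta prior family {self.delta_family!r}")
        if not self.delta_scale > 0:
            raise ValueError("Cauchy scale must be positive")
        if not (self.rho_a > 0 and self.rho_b > 0):
            raise ValueError("Beta shapes must be positive")
        if self.nu_shift < 2:
            raise ValueError(
                "nu prior shift must be >= 2 so the t likelihood has finite variance"
            )
        if not self.nu_scale > 0:
            raise ValueError("nu prior scale must be positive")
        if self.sdr_convention not in ("group1_over_group2", "group2_over_group1"):
            raise ValueError(f"unknown sdr_convention {self.sdr_convention!r}")
        if self.delta_truncation is not None:
            lo, hi = self.delta_truncation
            if not lo < hi:
                raise ValueError("delta truncation must satisfy lo < hi")
            object.__setattr__(self, "delta_truncation", (float(lo), float(hi)))
        if self.prior_model_probs is not None:
            p = np.asarray(self.prior_model_probs, dtype=float)
            if np.any(p < 0):
                raise ValueError("prior model probabilities must be nonnegative")
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValueError("prior model probabilities must sum to 1")
            object.__setattr__(self, "prior_model_probs", tuple(p))

    # --- delta prior -------------------------------------------------
    def _delta_dist(self):
        return stats.cauchy(loc=self.delta_location, scale=self.delta_scale)

    def _delta_trunc_mass(self) -> float:
        if self.delta_truncation is None:
            return 1.0
        d = self._delta_dist()
        lo, hi = self.delta_truncation
        return float(d.cdf(hi) - d.cdf(lo))

    def delta_logpdf(self, delta):
        # direct Cauchy log-density (avoids frozen-distribution overhead
        # in samplers that call this once per MCMC step)
        z = (np.asarray(delta, dtype=float) - self.delta_location) / self.delta_scale
        lp = -np.log1p(z * z) - math.log(math.pi * self.delta_scale)
        if self.delta_truncation is not None:
            lo, hi = self.delta_truncation
            lp = np.where(
                (np.asarray(delta) >= lo) & (np.asarray(delta) <= hi),
                lp - math.log(self._delta_trunc_mass()),
                -np.inf,
            )
        return lp

    def delta_ppf(self, u):
        """Quantile function of the (possibly truncated) delta prior."""
        d = self._delta_dist()
        if self.delta_truncation is None:
            return d.ppf(u)
        lo, hi = self.delta_truncation
        a, b = d.cdf(lo), d.cdf(hi)
        return d.ppf(a + (b - a) * np.asarray(u))

    # --- rho prior ---------------------------------------------------
    def rho_logpdf(self, rho):
        rho = np.asarray(rho, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            lp = (
                (self.rho_a - 1.0) * np.log(rho)
                + (self.rho_b - 1.0) * np.log1p(-rho)
                - special.betaln(self.rho_a, self.rho_b)
            )
        return np.where((rho > 0) & (rho < 1), lp, -np.inf)

    def rho_ppf(self, u):
        return stats.beta(self.rho_a, self.rho_b).ppf(u)

    def rho_cdf(self, rho):
        return stats.beta(self.rho_a, self.rho_b).cdf(rho)

    # --- nu prior ----------------------------------------------------
    def nu_logpdf(self, nu):
        nu = np.asarray(nu, dtype=float)
        z = (nu - self.nu_shift) / self.nu_scale
        return np.where(z >= 0, -z - math.log(self.nu_scale), -np.inf)

    def nu_ppf(self, u):
        return self.nu_shift - self.nu_scale * np.log1p(-np.asarray(u))

    # --- serialization ----------------------------------------------
    def to_dict(self) -> dict:
        return {
            "delta": {
                "family": self.delta_family,
                "location": self.delta_location,
                "scale": self.delta_scale,
                "truncation": list(self.delta_truncation)
                if self.delta_truncation
                else None,
            },
            "rho": {"a": self.rho_a, "b": self.rho_b},
            "nu": {"shift": self.nu_shift, "scale": self.nu_scale},
            "model_probs": list(self.prior_model_probs)
            if self.prior_model_probs
            else None,
            "sdr_convention": self.sdr_convention,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSettings":
        delta = d.get("delta", {})
        rho = d.get("rho", {})
        nu = d.get("nu", {})
        trunc = delta.get("truncation")
        return cls(
            delta_family=delta.get("family", "cauchy"),
            delta_location=delta.get("location", 0.0),
            delta_scale=delta.get("scale", DEFAULT_CAUCHY_SCALE),
            delta_truncation=tuple(trunc) if trunc else None,
            rho_a=rho.get("a", 1.5),
            rho_b=rho.get("b", 1.5),
            nu_shift=nu.get("shift", 2.0),
            nu_scale=nu.get("scale", 1.0),
            prior_model_probs=tuple(d["model_probs"]) if d.get("model_probs") else None,
            sdr_convention=d.get("sdr_convention", "group1_over_group2"),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict())

    @classmethod
    def from_yaml(cls, text: str) -> "PriorSettings":
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "PriorSettings":
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class ParameterVector:
    """A point in the common (mu, sigma, delta, rho, nu) parameter space."""

    mu: float
    sigma: float
    delta: float = 0.0
    rho: float = 0.5
    nu: float = math.inf

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        if not 0.0 < self.rho < 1.0:
            raise ValueError("rho must lie strictly inside (0, 1)")
        if not (self.nu > 2.0 or math.isinf(self.nu)):
            raise ValueError("nu must exceed 2 (or be inf for the normal likelihood)")


def rho_from_variances(var1: float, var2: float) -> float:
    """Group-1 precision share: (1/var1) / (1/var1 + 1/var2)."""
    if not (var1 > 0 and var2 > 0):
        raise ValueError("variances must be positive")
    return float(var2 / (var1 + var2))


def sdr_from_rho(rho, convention: str = "group1_over_group2"):
    """Standard deviation ratio sigma1/sigma2 implied by rho."""
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0) or np.any(rho >= 1):
        raise ValueError("rho must lie strictly inside (0, 1)")
    out = np.sqrt((1.0 - rho) / rho)
    if convention == "group2_over_group1":
        out = 1.0 / out
    return out if out.ndim else float(out)


def rho_from_sdr(sdr, convention: str = "group1_over_group2"):
    """Inverse of :func:`sdr_from_rho`."""
    sdr = np.asarray(sdr, dtype=float)
    if np.any(sdr <= 0) or np.any(~np.isfinite(sdr)):
        raise ValueError("SDR must be a positive finite real")
    if convention == "group2_over_group1":
        sdr = 1.0 / sdr
    out = 1.0 / (1.0 + sdr**2)
    return out if out.ndim else float(out)


def group_params(theta: ParameterVector) -> tuple[float, float, float, float]:
    """Per-group (mu1, mu2, sigma1, sigma2) implied by the common parameters.

    The mean difference is MD = delta * sigma, split symmetrically around
    mu; the group variances satisfy sigma1^2 + sigma2^2 = 2 sigma^2 with
    rho the group-1 precision share.
    """
    md = theta.delta * theta.sigma
    mu1 = theta.mu - 0.5 * md
    mu2 = theta.mu + 0.5 * md
    sigma1 = theta.sigma * math.sqrt(2.0 * (1.0 - theta.rho))
    sigma2 = theta.sigma * math.sqrt(2.0 * theta.rho)
    return mu1, mu2, sigma1, sigma2


def common_params(
    mu1: float, mu2: float, sigma1: float, sigma2: float, nu: float = math.inf
) -> ParameterVector:
    """Inverse of :func:`group_params` (bijection on the valid domain)."""
    if not (sigma1 > 0 and sigma2 > 0):
        raise ValueError("group scales must be positive")
    sigma = math.sqrt(0.5 * (sigma1**2 + sigma2**2))
    rho = rho_from_variances(sigma1**2, sigma2**2)
    return ParameterVector(
        mu=0.5 * (mu1 + mu2),
        sigma=sigma,
        delta=(mu2 - mu1) / sigma,
        rho=rho,
        nu=nu,
    )


def t_scale(sigma_g, nu):
    """Scale of the t density such that its SD is exactly ``sigma_g``.

    A Student-t with nu > 2 degrees of freedom and scale s has standard
    deviation s * sqrt(nu/(nu - 2)); we therefore shrink the scale to
    s = sigma_g * sqrt((nu - 2)/nu).
    """
    nu = np.asarray(nu, dtype=float)
    if np.any(nu <= 2):
        raise ValueError("nu must exceed 2 for the t likelihood SD to exist")
    out = np.asarray(sigma_g, dtype=float) * np.sqrt((nu - 2.0) / nu)
    return out if out.ndim else float(out)


def log_prior(theta: ParameterVector, priors: PriorSettings, spec) -> float:
    """Joint log prior density of the free parameters under ``spec``.

    The Jeffreys nuisance factor p(mu, sigma) ∝ 1/sigma is always
    included (improper, constant across models); free parameters among
    (delta, rho, nu) contribute their proper prior densities.  A
    parameter value inconsistent with the spec's constraints raises.
    """
    if not spec.delta_free and theta.delta != 0.0:
        raise ValueError(f"{spec.name}: delta must be 0 under the null")
    if not spec.rho_free and theta.rho != 0.5:
        raise ValueError(f"{spec.name}: rho must be 0.5 under equal variances")
    if not spec.nu_free and not math.isinf(theta.nu):
        raise ValueError(f"{spec.name}: nu must be inf under the normal likelihood")
    lp = -math.log(theta.sigma)
    if spec.delta_free:
        lp += float(priors.delta_logpdf(theta.delta))
    if spec.rho_free:
        lp += float(priors.rho_logpdf(theta.rho))
    if spec.nu_free:
        lp += float(priors.nu_logpdf(theta.nu))
    return lp


def prior_mass_sdr_interval(
    lo: float,
    hi: float,
    beta_shapes: tuple[float, float] = (1.5, 1.5),
    convention: str = "group1_over_group2",
) -> float:
    """P(lo <= SDR <= hi) under rho ~ Beta(a, b).

    Computed through the regularized incomplete beta function on the
    rho-interval implied by the SDR bounds (SDR is monotone decreasing
    in rho under the group1/group2 convention).
    """
    if not (0 < lo < hi):
        raise ValueError("bounds must satisfy 0 < lo < hi")
    a, b = beta_shapes
    if not (a > 0 and b > 0):
        raise ValueError("Beta shapes must be positive")
    r_lo = rho_from_sdr(hi, convention) if math.isfinite(hi) else 0.0
    r_hi = rho_from_sdr(lo, convention)
    r_lo, r_hi = min(r_lo, r_hi), max(r_lo, r_hi)
    return float(special.betainc(a, b, r_hi) - special.betainc(a, b, r_lo))


def nu_prior_summary(priors: PriorSettings) -> dict[str, float]:
    """Mean and quartiles of the shifted-exponential prior on nu."""
    shift, scale = priors.nu_shift, priors.nu_scale
    return {
        "mean": shift + scale,
        "q1": shift - scale * math.log(0.75),
        "median": shift - scale * math.log(0.5),
        "q3": shift - scale * math.log(0.25),
    }
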