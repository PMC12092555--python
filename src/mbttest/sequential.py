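"""Sequential evidence trajectories and replication Bayes factors.

Sequential analysis re-fits the full ensemble on growing prefixes of the
data (no path dependence: each checkpoint is a complete fresh analysis).
The replication Bayes factor follows the evidence-updating identity:
the Bayes factor of the combined data (original + replication) divided
by the Bayes factor of the original study alone, which is equivalent to
analyzing the replication under the original study's posterior — both
for individual-model BFs and for inclusion BFs with updated prior model
probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .data import TwoSampleData
from .ensemble import EnsembleResult, fit_ensemble
from .marglik import SamplerSettings
from .priors import PriorSettings

__all__ = [
    "SequentialTrajectory",
    "sequential_trajectory",
    "replication_bf",
    "replication_analysis",
    "ReplicationResult",
]


@dataclass
class SequentialTrajectory:
    """Ordered ensemble results at strictly increasing sample sizes."""

    checkpoints: list[tuple[int, int, EnsembleResult]]
    schedule: str

    def __post_init__(self):
        totals = [n1 + n2 for n1, n2, _ in self.checkpoints]
        if any(b <= a for a, b in zip(totals, totals[1:])):
            raise ValueError("checkpoints must be strictly increasing in total n")

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (one row per checkpoint) for plotting."""
        rows = []
        for n1, n2, res in self.checkpoints:
            row = {
                "n1": n1,
                "n2": n2,
                "bf_effect": res.incl_bf_effect,
                "bf_variances": res.incl_bf_variances,
                "bf_outliers": res.incl_bf_outliers,
            }
            for spec, p in zip(res.specs, res.model_probs):
                row[f"p_{spec.name}"] = float(p)
            rows.append(row)
        return pd.DataFrame(rows)


def _pairwise_schedule(n1: int, n2: int) -> list[tuple[int, int]]:
    """One observation per group per checkpoint, starting at 2 + 2."""
    out = []
    k = 2
    while True:
        out.append((min(k, n1), min(k, n2)))
        if k >= n1 and k >= n2:
            break
        k += 1
    return out


def sequential_trajectory(
    data: TwoSampleData,
    priors: PriorSettings | None = None,
    ensemble: str = "mb4",
    schedule: str | list[tuple[int, int]] = "pairwise",
    settings: SamplerSettings | None = None,
    seed: int = 0,
) -> SequentialTrajectory:
    """Ensemble results over accumulating data.

    ``schedule`` is either ``"pairwise"`` (add one observation per group
    per checkpoint) or an explicit list of (n1, n2) index pairs; the
    first checkpoint must give each group at least two observations.
    Every checkpoint uses the same seed, so the final checkpoint is a
    fresh full-data fit.
    """
    if schedule == "pairwise":
        points = _pairwise_schedule(data.n1, data.n2)
        name = "pairwise"
    else:
        points = [(int(a), int(b)) for a, b in schedule]
        name = "custom"
    if not points:
        raise ValueError("empty checkpoint schedule")
    if points[0][0] < 2 or points[0][1] < 2:
        raise ValueError(
            f"first checkpoint {points[0]} leaves a group with fewer than 2 observations"
        )
    checkpoints = []
    for k1, k2 in points:
        sub = data.subset(k1, k2)
        res = fit_ensemble(
            sub, priors, ensemble=ensemble, settings=settings, seed=seed
        )
        checkpoints.append((k1, k2, res))
    return SequentialTrajectory(checkpoints=checkpoints, schedule=name)


def replication_bf(bf_combined: float, bf_original: float) -> float:
    """Replication Bayes factor by evidence updating.

    The evidence the replication adds beyond the original study:
    BF_rep = BF_combined / BF_original.
    """
    if not (bf_combined > 0 and bf_original > 0):
        raise ValueError("Bayes factors must be positive")
    return bf_combined / bf_original


@dataclass
class ReplicationResult:
    """Replication Bayes factors plus the pooled-data analysis."""

    bf_rep_effect: float
    bf_rep_variances: float | None
    bf_rep_outliers: float | None
    original: EnsembleResult
    combined: EnsembleResult


def replication_analysis(
    original: TwoSampleData,
    replication: TwoSampleData,
    priors: PriorSettings | None = None,
    ensemble: str = "romb8",
    settings: SamplerSettings | None = None,
    seed: int = 0,
) -> ReplicationResult:
    """Replication Bayes factors for effect, variances, and outliers.

    Fits the original data and the pooled data (original + replication)
    and forms the quotient of the corresponding inclusion Bayes factors;
    this updates both the parameter priors and the prior model
    probabilities to the original study's posterior.  The pooled fit
    also provides the combined model-averaged estimates.
    """
    res_orig = fit_ensemble(
        original, priors, ensemble=ensemble, settings=settings, seed=seed
    )
    pooled = original.pooled_with(replication)
    res_comb = fit_ensemble(
        pooled, priors, ensemble=ensemble, settings=settings, seed=seed
    )

    def _quot(a, b):
        if a is None or b is None:
            return None
        return replication_bf(a, b)

    return ReplicationResult(
        bf_rep_effect=replication_bf(res_comb.incl_bf_effect, res_orig.incl_bf_effect),
        bf_rep_variances=_quot(res_comb.incl_bf_variances, res_orig.incl_bf_variances),
        bf_rep_outliers=_quot(res_comb.incl_bf_outliers, res_orig.incl_bf_outliers),
        original=res_orig,
        combined=res_comb,
    )
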