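"""Two-group data containers, validation, and summary-statistic reduction.

The observational unit throughout the package is a pair of independent
groups of real-valued measurements.  All models condition on these data;
the normal-likelihood models additionally admit a sufficient reduction to
per-group sample size, mean, and standard deviation (divisor ``n - 1``),
which is what :class:`SummaryStats` stores.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TwoSampleData",
    "SummaryStats",
    "summarize",
    "read_two_group_csv",
    "write_two_group_csv",
    "make_fixture_from_summary",
]


class ValidationError(ValueError):
    """Raised when input data violate the two-sample contract."""


def _validate_group(values: np.ndarray, label: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size < 2:
        raise ValidationError(
            f"group {label!r} has {arr.size} observation(s); at least 2 required"
        )
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"group {label!r} contains non-finite values")
    if np.var(arr, ddof=1) <= 0.0:
        raise ValidationError(f"group {label!r} has zero sample variance")
    return arr


@dataclass(frozen=True)
class TwoSampleData:
    """Raw observations for two independent groups.

    Parameters
    ----------
    group1, group2
        Vectors of finite real observations, at least two per group and
        with nonzero sample variance.
    labels
        Group identifiers; group order is meaningful (the precision
        proportion ``rho`` is defined as group 1's precision share).
    """

    group1: np.ndarray
    group2: np.ndarray
    labels: tuple[str, str] = ("group1", "group2")

    def __post_init__(self):
        g1 = _validate_group(self.group1, self.labels[0])
        g2 = _validate_group(self.group2, self.labels[1])
        object.__setattr__(self, "group1", g1)
        object.__setattr__(self, "group2", g2)
        object.__setattr__(self, "labels", (str(self.labels[0]), str(self.labels[1])))

    @property
    def n1(self) -> int:
        return int(self.group1.size)

    @property
    def n2(self) -> int:
        return int(self.group2.size)

    def swapped(self) -> "TwoSampleData":
        """Return the same data with group labels exchanged."""
        return TwoSampleData(self.group2, self.group1, (self.labels[1], self.labels[0]))

    def subset(self, k1: int, k2: int) -> "TwoSampleData":
        """First ``k1``/``k2`` observations of each group (sequential prefixes)."""
        return TwoSampleData(self.group1[:k1], self.group2[:k2], self.labels)

    def pooled_with(self, other: "TwoSampleData") -> "TwoSampleData":
        """Concatenate two datasets group-wise (original + replication)."""
        return TwoSampleData(
            np.concatenate([self.group1, other.group1]),
            np.concatenate([self.group2, other.group2]),
            self.labels,
        )

    def data_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.group1.tobytes())
        h.update(b"|")
        h.update(self.group2.tobytes())
        return h.hexdigest()[:16]


@dataclass(frozen=True)
class SummaryStats:
    """Sufficient statistics of a two-group sample (SD divisor ``n - 1``)."""

    n1: int
    mean1: float
    sd1: float
    n2: int
    mean2: float
    sd2: float

    def __post_init__(self):
        for field in ("n1", "n2"):
            n = getattr(self, field)
            if int(n) != n or n < 2:
                raise ValidationError(f"{field} must be an integer >= 2, got {n!r}")
            object.__setattr__(self, field, int(n))
        for field in ("mean1", "mean2"):
            object.__setattr__(self, field, float(getattr(self, field)))
        for field in ("sd1", "sd2"):
            sd = float(getattr(self, field))
            if not (np.isfinite(sd) and sd > 0):
                raise ValidationError(f"{field} must be a positive real, got {sd!r}")
            object.__setattr__(self, field, sd)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "SummaryStats":
        d = json.loads(text)
        return cls(**{k: d[k] for k in ("n1", "mean1", "sd1", "n2", "mean2", "sd2")})

    def data_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def summarize(data: TwoSampleData) -> SummaryStats:
    """Per-group sample size, mean, and SD (divisor ``n - 1``)."""
    return SummaryStats(
        n1=data.n1,
        mean1=float(np.mean(data.group1)),
        sd1=float(np.std(data.group1, ddof=1)),
        n2=data.n2,
        mean2=float(np.mean(data.group2)),
        sd2=float(np.std(data.group2, ddof=1)),
    )


def read_two_group_csv(
    path,
    value_column: str,
    group_column: str,
    group_order: Sequence[str] | None = None,
) -> TwoSampleData:
    """Read a two-group dataset from a CSV file.

    Rows with missing values in either column are dropped (with a logged
    count); group 1 is the first label encountered unless ``group_order``
    is given explicitly.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    if frame.empty:
        raise ValidationError(f"{path}: CSV file contains no data rows")
    for col in (value_column, group_column):
        if col not in frame.columns:
            raise ValidationError(
                f"{path}: column {col!r} not found (available: {list(frame.columns)})"
            )
    sub = frame[[value_column, group_column]]
    n_before = len(sub)
    sub = sub.dropna()
    n_dropped = n_before - len(sub)
    if n_dropped:
        logger.warning("%s: dropped %d row(s) with missing values", path, n_dropped)
    values = pd.to_numeric(sub[value_column], errors="coerce")
    if values.isna().any():
        bad = sub[value_column][values.isna()].iloc[0]
        raise ValidationError(
            f"{path}: non-numeric entry {bad!r} in value column {value_column!r}"
        )
    groups = sub[group_column].astype(str)
    seen = list(dict.fromkeys(groups))  # first-appearance order
    if len(seen) != 2:
        raise ValidationError(
            f"{path}: expected exactly 2 group labels, found {len(seen)}: {seen}"
        )
    if group_order is not None:
        order = [str(g) for g in group_order]
        if sorted(order) != sorted(seen):
            raise ValidationError(
                f"{path}: group_order {order} does not match labels {seen}"
            )
        seen = order
    g1 = values[groups == seen[0]].to_numpy(dtype=float)
    g2 = values[groups == seen[1]].to_numpy(dtype=float)
    return TwoSampleData(g1, g2, (seen[0], seen[1]))


def write_two_group_csv(
    data: TwoSampleData,
    path,
    value_column: str = "value",
    group_column: str = "group",
) -> None:
    """Write a two-group dataset to CSV in long format.

    Values are serialized with full round-trip precision, so reading the
    file back reproduces every finite double bit-for-bit.
    """
    frame = pd.DataFrame({
        value_column: np.concatenate([data.group1, data.group2]),
        group_column: [data.labels[0]] * data.n1 + [data.labels[1]] * data.n2,
    })
    frame.to_csv(path, index=False)  # str() is shortest-round-trip in py3


def _standardized_sample(n: int, rng: np.random.Generator) -> np.ndarray:
    """A draw of size n with sample mean exactly 0 and sample SD exactly 1."""
    x = rng.standard_normal(n)
    x = x - x.mean()
    s = x.std(ddof=1)
    while s == 0.0:  # pragma: no cover - probability zero
        x = rng.standard_normal(n)
        x = x - x.mean()
        s = x.std(ddof=1)
    return x / s


def make_fixture_from_summary(stats: SummaryStats, rng_seed: int = 0) -> TwoSampleData:
    """Construct raw data reproducing the given summary statistics exactly.

    Gaussian noise is generated and then affinely re-standardized per
    group, so ``summarize`` recovers ``stats`` to floating-point accuracy.
    Different seeds give different datasets with identical summaries.
    """
    rng = np.random.default_rng(rng_seed)
    g1 = stats.mean1 + stats.sd1 * _standardized_sample(stats.n1, rng)
    g2 = stats.mean2 + stats.sd2 * _standardized_sample(stats.n2, rng)
    return TwoSampleData(g1, g2)
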