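"""Human-readable reports and evidence labels.

Bayes factors are mapped to the conventional verbal categories: values
in (1, 3) are weak evidence, (3, 10) moderate, above 10 strong; a BF of
exactly 1 (and, by convention, the open boundaries) is labeled as
equivocal.  Values below 1 are inverted and labeled as evidence for the
complementary hypothesis.
"""

from __future__ import annotations

import math

from .ensemble import EnsembleResult
from .marglik import format_bf

__all__ = ["evidence_label", "text_report", "format_bf"]


def evidence_label(bf: float, favoring: tuple[str, str] = ("H1", "H0")) -> str:
    """Verbal evidence category for a Bayes factor."""
    if not bf > 0:
        raise ValueError("Bayes factor must be positive")
    target, complement = favoring
    if bf == 1.0:
        return "no evidence / equivocal"
    if bf < 1.0:
        inv_label = evidence_label(1.0 / bf, (complement, target))
        return inv_label
    if bf <= 3.0:
        strength = "weak"
    elif bf <= 10.0:
        strength = "moderate"
    else:
        strength = "strong"
    return f"{strength} evidence for {target}"


_INCL_NAMES = {
    "effect": ("difference in means", ("H1", "H0")),
    "variances": ("unequal variances", ("unequal", "equal")),
    "outliers": ("outliers (t likelihood)", ("t", "normal")),
}


def _fmt(x: float | None) -> str:
    if x is None:
        return "-"
    if math.isinf(x):
        return "inf"
    return format_bf(x)


def text_report(result: EnsembleResult) -> str:
    """Plain-text summary mirroring the package's JSON report."""
    lines = []
    lines.append(f"Model-averaged Bayesian t test — ensemble: {result.ensemble}")
    lines.append(f"data hash: {result.data_hash}   seed: {result.seed}")
    lines.append("")
    lines.append(f"{'model':<14}{'log ML':>12}{'SE':>9}{'prior':>8}{'posterior':>11}")
    for row in result.model_table():
        lines.append(
            f"{row['model']:<14}{row['log_ml']:>12.4f}{row['log_ml_se']:>9.4f}"
            f"{row['prior_prob']:>8.3f}{row['posterior_prob']:>11.4f}"
        )
    lines.append("")
    lines.append("Inclusion Bayes factors:")
    for key, bf in (
        ("effect", result.incl_bf_effect),
        ("variances", result.incl_bf_variances),
        ("outliers", result.incl_bf_outliers),
    ):
        if bf is None:
            continue
        desc, favoring = _INCL_NAMES[key]
        lines.append(f"  BF[{key}] = {_fmt(bf)}  ({desc}: {evidence_label(bf, favoring)})")
    if result.averaged:
        lines.append("")
        lines.append("Posterior estimates (95% central credible intervals):")
        for param, kinds in result.averaged.items():
            for kind, s in kinds.items():
                lines.append(
                    f"  {param:<6}{kind:<13}{s.statistic} = "
                    f"{_num(s.center)}, CI [{_num(s.ci_low)}, {_num(s.ci_high)}]"
                )
    return "\n".join(lines)


def _num(x: float) -> str:
    if math.isinf(x):
        return "inf" if x > 0 else "-inf"
    return f"{x:.3g}"
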