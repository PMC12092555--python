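"""Model-space enumeration for the model-averaged two-sample t tests.

Each ensemble member is indexed by three binary flags:

* ``effect``: the standardized mean difference delta is 0 (null) or free
  (alternative);
* ``variances``: the precision proportion rho is fixed at 1/2 (equal) or
  free (unequal, the Welch case);
* ``likelihood``: observations are normal (nu = infinity) or Student-t
  with unknown degrees of freedom nu (robust to outliers).

The four normal-likelihood members form the MB ensemble; all eight form
the robust (RoMB) ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ModelSpec", "ENSEMBLES", "MB4", "ROMB8", "STUDENT", "WELCH"]

_EFFECTS = ("null", "alternative")
_VARIANCES = ("equal", "unequal")
_LIKELIHOODS = ("normal", "t")


@dataclass(frozen=True)
class ModelSpec:
    """One member of the 2 x 2 x 2 model ensemble."""

    effect: str
    variances: str
    likelihood: str

    def __post_init__(self):
        if self.effect not in _EFFECTS:
            raise ValueError(f"effect must be one of {_EFFECTS}, got {self.effect!r}")
        if self.variances not in _VARIANCES:
            raise ValueError(
                f"variances must be one of {_VARIANCES}, got {self.variances!r}"
            )
        if self.likelihood not in _LIKELIHOODS:
            raise ValueError(
                f"likelihood must be one of {_LIKELIHOODS}, got {self.likelihood!r}"
            )

    @property
    def delta_free(self) -> bool:
        return self.effect == "alternative"

    @property
    def rho_free(self) -> bool:
        return self.variances == "unequal"

    @property
    def nu_free(self) -> bool:
        return self.likelihood == "t"

    @property
    def name(self) -> str:
        """Compact label, e.g. ``H1-rho-t`` for the fully free model."""
        e = "H1" if self.delta_free else "H0"
        v = "rho" if self.rho_free else "rhobar"
        l = "t" if self.nu_free else "n"
        return f"{e}-{v}-{l}"

    def free_parameters(self) -> tuple[str, ...]:
        """Free members of (mu, sigma, delta, rho, nu) under this spec."""
        free = ["mu", "sigma"]
        if self.delta_free:
            free.append("delta")
        if self.rho_free:
            free.append("rho")
        if self.nu_free:
            free.append("nu")
        return tuple(free)


def _all_specs() -> tuple[ModelSpec, ...]:
    return tuple(
        ModelSpec(e, v, l)
        for l in _LIKELIHOODS
        for v in _VARIANCES
        for e in _EFFECTS
    )


ROMB8: tuple[ModelSpec, ...] = _all_specs()
MB4: tuple[ModelSpec, ...] = tuple(s for s in ROMB8 if s.likelihood == "normal")
STUDENT: tuple[ModelSpec, ...] = tuple(
    s for s in MB4 if s.variances == "equal"
)
WELCH: tuple[ModelSpec, ...] = tuple(
    s for s in MB4 if s.variances == "unequal"
)

ENSEMBLES: dict[str, tuple[ModelSpec, ...]] = {
    "student": STUDENT,
    "welch": WELCH,
    "mb4": MB4,
    "romb8": ROMB8,
}
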