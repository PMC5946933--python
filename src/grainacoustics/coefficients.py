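"""Published activity-vs-depletion regression coefficients.

The three linear models relate an activity response to oxygen depletion
(initial minus residual O2, percentage points) across hermetic treatments:

* ``rb``    : Log10(Rb / Nt + 1)    = a + b * depletion
* ``nb``    : Nb                    = a + b * depletion
* ``rbimp`` : Log10(Rbimp / Nt + 1) = a + b * depletion

Coefficients are stored exactly as printed, on a x1e-3 scale, with the
scale explicit to avoid magnitude bugs; they serve as the default
generating parameters of the synthetic experiment module.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ActivityCoefficients", "REFERENCE_COEFFICIENTS", "MEASURES"]

MEASURES = ("rb", "nb", "rbimp")


@dataclass(frozen=True)
class ActivityCoefficients:
    """Intercept/slope of one activity model, stored on a x1e-3 scale."""

    intercept_e3: float
    slope_e3: float
    intercept_sem_e3: float
    slope_sem_e3: float
    scale: float = 1e-3

    @property
    def intercept(self) -> float:
        return self.intercept_e3 * self.scale

    @property
    def slope(self) -> float:
        return self.slope_e3 * self.scale


#: Reported intercepts and slopes (+/- SEM), all on the printed x1e-3 scale.
REFERENCE_COEFFICIENTS: dict[str, ActivityCoefficients] = {
    "rb": ActivityCoefficients(2.26, -0.156, 0.477, 0.0507),
    "nb": ActivityCoefficients(4132.0, -50.87, 176.0, 20.08),
    "rbimp": ActivityCoefficients(10.8, -0.818, 2.8, 0.329),
}
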