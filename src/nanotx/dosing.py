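"""Injection schedules and the time-varying Dirichlet boundary.

Systemic circulation is not modeled explicitly: an injection raises the NP
field's Dirichlet boundary value (the vascular far-field concentration),
and systemic clearance decays each injection's contribution exponentially.
Overlapping injections superpose, representing added plasma concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .units import rate_from_half_life_days


@dataclass(frozen=True)
class Schedule:
    """Injection times/doses mapped to the NP boundary concentration.

    ``injections`` holds (time in minutes, dose as a multiple of the
    reference dose). ``reference_dose`` is the boundary concentration
    (NPs/um^3) produced by a unit dose at the moment of injection.
    """

    injections: tuple = ((0.0, 1.0),)
    clearance_rate: float = rate_from_half_life_days(4.0)  # 1/min
    reference_dose: float = 0.2  # NPs/um^3

    def __post_init__(self):
        errs = []
        times = [t for t, _ in self.injections]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            errs.append("injection times must be non-decreasing")
        if any(dose < 0 for _, dose in self.injections):
            errs.append("doses must be >= 0")
        if self.clearance_rate < 0:
            errs.append(f"clearance rate must be >= 0, got {self.clearance_rate}")
        if self.reference_dose < 0:
            errs.append(f"reference dose must be >= 0, got {self.reference_dose}")
        if errs:
            raise ConfigurationError("invalid schedule", errs)

    @property
    def total_dose_multiple(self) -> float:
        return float(sum(dose for _, dose in self.injections))


def boundary_concentration(t: float, s: Schedule) -> float:
    """NP Dirichlet boundary value at time t (minutes).

    Sum over past injections of dose * reference_dose *
    exp(-clearance_rate * (t - t_injection)).
    """
    total = 0.0
    for t_k, dose_k in s.injections:
        if t >= t_k:
            total += dose_k * np.exp(-s.clearance_rate * (t - t_k))
    return s.reference_dose * total
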