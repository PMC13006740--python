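"""Drug effect on cell phenotype.

The pharmacodynamic effect E follows a sigmoidal (Hill) response in either
the instantaneous intracellular drug concentration c = C/V (model "hill") or
the accumulated exposure AUC = integral of c dt (model "auc"). The targeted
phenotype rate is then a linear interpolation between its base value b0 and
the maximally altered value bmax, with E/Emax as the interpolant:

    b_phenotype = b0 + (bmax - b0) * E / Emax

Cytostatic drugs target the cycle-entry rate (bmax <= b0, default full
arrest, bmax = 0); cytotoxic drugs target the apoptosis rate (bmax >= b0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .nano import NPCompartment

logger = logging.getLogger(__name__)

HILL, AUC = "hill", "auc"
CYTOSTATIC, CYTOTOXIC = "cytostatic", "cytotoxic"


@dataclass(frozen=True)
class PDParams:
    model: str = HILL
    mode: str = CYTOTOXIC
    Emax: float = 1.0
    EC50: float = 1.2        # umol/um^3 (hill) or umol*min/um^3 (auc); assumption
    hill_n: float = 4.0
    b0: float = 5.3167e-05   # base value of the targeted rate, 1/min
    bmax: float = 1.0e-03    # maximally altered value of the targeted rate, 1/min

    def __post_init__(self):
        errs = []
        if self.model not in (HILL, AUC):
            errs.append(f"pd.model must be 'hill' or 'auc', got {self.model!r}")
        if self.mode not in (CYTOSTATIC, CYTOTOXIC):
            errs.append(f"pd.mode must be 'cytostatic' or 'cytotoxic', got {self.mode!r}")
        if self.Emax <= 0:
            errs.append(f"pd.Emax must be > 0, got {self.Emax}")
        if self.EC50 <= 0:
            errs.append(f"pd.EC50 must be > 0, got {self.EC50}")
        if self.hill_n < 0:
            errs.append(f"pd.hill_n must be >= 0, got {self.hill_n}")
        if self.mode == CYTOSTATIC and self.bmax > self.b0:
            errs.append("cytostatic mode requires bmax <= b0 (drug slows cycling)")
        if self.mode == CYTOTOXIC and self.bmax < self.b0:
            errs.append("cytotoxic mode requires bmax >= b0 (drug raises apoptosis)")
        if errs:
            raise ConfigurationError("invalid pharmacodynamics parameters", errs)


def _hill(x, p: PDParams):
    x = np.asarray(x, dtype=float)
    xn = np.where(x > 0, x, 0.0) ** p.hill_n
    with np.errstate(invalid="ignore"):
        out = p.Emax * xn / (p.EC50 ** p.hill_n + xn)
    return np.where(x > 0, out, 0.0)


def hill_effect(c, p: PDParams):
    """E = Emax c^n / (EC50^n + c^n); at c = EC50 the effect is Emax/2."""
    return _hill(c, p)


def auc_effect(comp: NPCompartment, p: PDParams):
    """Hill response applied to the compartment's accumulated AUC.

    The AUC accumulator is maintained by the intracellular kinetics step
    (rectangle rule at the phenotype cadence), so E is non-decreasing over a
    cell's lifetime.
    """
    return float(_hill(comp.auc, p))


def interpolate_phenotype(E, p: PDParams, b0=None):
    """Targeted rate b0 + (bmax - b0) * E / Emax.

    ``b0`` may override the stored base rate — the engine passes the
    oxygen-modulated cycle rate as the cytostatic base, so hypoxia and drug
    effects compose. E above Emax is clipped with a logged warning.
    """
    E = np.asarray(E, dtype=float)
    if np.any(E > p.Emax):
        logger.warning("effect E exceeds Emax=%g; clipping", p.Emax)
        E = np.minimum(E, p.Emax)
    base = p.b0 if b0 is None else np.asarray(b0, dtype=float)
    return base + (p.bmax - base) * E / p.Emax
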