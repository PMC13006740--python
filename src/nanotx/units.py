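"""Unit helpers.

Internal units throughout the package: lengths in micrometers, time in
minutes, oxygen partial pressure in mmHg, nanoparticle field concentration in
NPs/um^3, drug amounts in umol and intracellular drug concentration in
umol/um^3. Rates are 1/min unless stated otherwise.
"""

import math

MINUTES_PER_DAY = 1440.0
MINUTES_PER_HOUR = 60.0


def rate_from_half_life(half_life_min: float) -> float:
    """First-order decay rate (1/min) for a given half-life in minutes."""
    if half_life_min <= 0:
        raise ValueError(f"half-life must be positive, got {half_life_min}")
    return math.log(2.0) / half_life_min


def rate_from_half_life_days(half_life_days: float) -> float:
    """First-order decay rate (1/min) for a half-life given in days."""
    return rate_from_half_life(half_life_days * MINUTES_PER_DAY)


def half_life_days_from_rate(rate_per_min: float) -> float:
    """Half-life in days for a first-order decay rate in 1/min."""
    if rate_per_min <= 0:
        raise ValueError(f"rate must be positive, got {rate_per_min}")
    return math.log(2.0) / rate_per_min / MINUTES_PER_DAY


def days(t_days: float) -> float:
    """Convert days to minutes."""
    return t_days * MINUTES_PER_DAY


def hours(t_hours: float) -> float:
    """Convert hours to minutes."""
    return t_hours * MINUTES_PER_HOUR
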