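"""Shared distance-decay kernel.

Encounter, harvest and telemetry all attenuate with distance from an
individual's activity center through the *same* exponential hazard term

    d / (2 sigma_sex^2),

with ``d`` measured in trap-spacing units (5 km by default) and
``sigma_sex = exp(log_sigma_sex)``.  Keeping the term in one function is a
structural guarantee that the three observation processes share their scale
parameters, which is what lets harvest and telemetry data inform the
capture-recapture likelihood.
"""

from __future__ import annotations

import numpy as np


def distance_decay_exponent(distance_units, log_sigma: float):
    """Return d / (2 sigma^2) for distances in trap-spacing units.

    Parameters
    ----------
    distance_units : array-like
        Non-negative distances in scaled (5-km) units.
    log_sigma : float
        Natural log of the sex-specific scale parameter.
    """
    d = np.asarray(distance_units, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    sigma = np.exp(log_sigma)
    return d / (2.0 * sigma * sigma)


def decay_weight(distance_units, log_sigma: float):
    """exp(-d / (2 sigma^2)) — the multiplicative hazard weight."""
    return np.exp(-distance_decay_exponent(distance_units, log_sigma))
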