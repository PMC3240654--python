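"""Isthmian molecular-clock calibration and divergence dating.

A geminate species pair separated by the rise of the Isthmus of Panama
provides the calibration: the observed K2P distance between the pair,
divided by the closure age, gives a rate of TOTAL pairwise divergence
per unit time.  Dividing an observed between-population distance by that
rate dates the populations' split.  Because the calibration rate is a
total-divergence rate (both lineages accumulating change), no factor of
two appears anywhere; ``per_lineage=True`` halves the rate for users who
prefer the per-lineage convention (times then double).

Units are whatever the caller uses consistently: percent with MY gives a
rate in %/MY and times in MY.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import InputError


@dataclass(frozen=True)
class ClockCalibration:
    d_cal: float
    T_cal: float
    rate: float
    per_lineage: bool = False


@dataclass(frozen=True)
class DivergenceEstimate:
    d_obs: float
    T: float
    T_low: float | None = None
    T_high: float | None = None


def calibrate(d_cal: float, T_cal: float, per_lineage: bool = False) -> ClockCalibration:
    """Rate from a calibration distance and age: r = d_cal / T_cal."""
    if d_cal <= 0 or T_cal <= 0:
        raise InputError("calibration distance and age must be positive")
    rate = d_cal / T_cal
    if per_lineage:
        rate /= 2.0
    return ClockCalibration(d_cal=d_cal, T_cal=T_cal, rate=rate, per_lineage=per_lineage)


def date_divergence(
    d_obs: float,
    calibration: ClockCalibration,
    se_d: float | None = None,
) -> DivergenceEstimate:
    """Divergence time T = d_obs / r.

    When a standard error for ``d_obs`` is supplied (e.g. a site-bootstrap
    SE), it is propagated linearly into a ±2 SE interval for T — an
    extension beyond the point estimate; calibration-age uncertainty is
    not modelled.
    """
    if d_obs < 0:
        raise InputError("observed distance must be >= 0")
    T = d_obs / calibration.rate
    low = high = None
    if se_d is not None:
        low = max(0.0, (d_obs - 2.0 * se_d) / calibration.rate)
        high = (d_obs + 2.0 * se_d) / calibration.rate
    return DivergenceEstimate(d_obs=d_obs, T=T, T_low=low, T_high=high)
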