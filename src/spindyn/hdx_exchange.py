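"""Amide H/D exchange rates, protection factors and open-state populations.

After dissolution of a lyophilized protonated sample in D2O, backbone amide
peak intensities decay mono-exponentially with the exchange rate k_ex.
Protection factors PF = k_int/k_ex (k_int being the intrinsic, unprotected
rate predicted for the sequence under the same conditions and consumed here
as an input table) measure how much slower an amide exchanges than a random
coil; under fast local opening/closing equilibria PF is of the order of the
inverse open-state population, PF ~ 1/p_open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from spindyn.io_tables import IntensityDecaySeries, ResidueID
from spindyn.relaxation import FitError, fit_monoexponential

#: PF below this exchanges too fast to observe in a typical HSQC series
PF_UNOBSERVABLE = 1e2
#: PF at or above this marks high protection (stable hydrogen bonding)
PF_HIGH = 2e3

#: factor on the noise level below which the first point counts as "already
#: exchanged away" (too fast to quantify)
TOO_FAST_NOISE_FACTOR = 3.0


@dataclass
class HDXRecord:
    """Per-residue H/D exchange result.

    ``status`` is ``quantified`` (rate fit converged), ``too_fast`` (signal
    already at noise level at the first time point), or ``lower_bound``
    (no significant decay over the series; ``k_ex`` is then an upper bound
    and ``pf`` a lower bound).
    """

    residue: ResidueID
    k_int: float                 # /h
    k_ex: float | None = None    # /h
    k_ex_err: float | None = None
    pf: float | None = None
    p_open: float | None = None
    status: str = "quantified"
    band: str | None = None

    def __post_init__(self) -> None:
        if self.k_int <= 0:
            raise ValueError("k_int must be > 0")
        if self.status not in ("quantified", "too_fast", "lower_bound"):
            raise ValueError(f"unknown status {self.status!r}")


def fit_hdx_rate(
    series: IntensityDecaySeries,
    noise_sd: float | None = None,
) -> tuple[float | None, float | None, str]:
    """Fit k_ex (/h) from an H/D intensity time course.

    Returns (k_ex, k_ex_err, status).  Times are in hours with t = 0 at
    reconstitution; the first measured point is data, not baseline.
    ``too_fast``: the first point is already below 3x the noise level (no
    rate can be fit).  ``lower_bound``: the fitted rate's 95% confidence
    interval includes zero, i.e. no significant decay; k_ex then holds the
    95% upper bound on the rate.
    """
    if noise_sd is None:
        noise_sd = (
            float(np.median(series.sigmas)) if series.sigmas is not None else 0.0
        )
    if noise_sd > 0 and series.intensities[0] < TOO_FAST_NOISE_FACTOR * noise_sd:
        return None, None, "too_fast"
    try:
        fit = fit_monoexponential(series, "decay")
    except FitError:
        return None, None, "too_fast"
    if not fit.converged:
        return None, None, "too_fast"
    if fit.rate - 1.96 * fit.rate_err <= 0.0:
        upper = max(fit.rate, 0.0) + 1.96 * fit.rate_err
        return upper, fit.rate_err, "lower_bound"
    return fit.rate, fit.rate_err, "quantified"


def protection_factor(k_int: float, k_ex: float) -> tuple[float, float, str]:
    """PF = k_int/k_ex and p_open = 1/PF, with a protection band.

    Bands (half-open, monotone in PF): ``unobservable`` for PF < 1e2,
    ``moderate`` for 1e2 <= PF < 2e3, ``high`` for PF >= 2e3.
    """
    if k_int <= 0 or k_ex < 0:
        raise ValueError("rates must be positive")
    if k_ex == 0:
        return math.inf, 0.0, "high"
    pf = k_int / k_ex
    p_open = 1.0 / pf
    if pf < PF_UNOBSERVABLE:
        band = "unobservable"
    elif pf < PF_HIGH:
        band = "moderate"
    else:
        band = "high"
    return pf, p_open, band


def analyze_hdx(
    series_list: list[IntensityDecaySeries],
    k_int: dict[ResidueID, float] | dict[int, float],
    noise_sd: float | None = None,
) -> list[HDXRecord]:
    """Fit all series and convert to protection factors.

    ``k_int`` maps residue (or residue number) to the intrinsic rate in /h.
    For ``lower_bound`` records PF is computed from the k_ex upper bound
    and is therefore itself a lower bound.
    """
    def lookup(rid: ResidueID) -> float | None:
        if rid in k_int:
            return k_int[rid]  # type: ignore[index]
        return k_int.get(rid.number)  # type: ignore[call-overload, return-value]

    out: list[HDXRecord] = []
    for s in series_list:
        ki = lookup(s.residue)
        if ki is None:
            continue
        k_ex, k_err, status = fit_hdx_rate(s, noise_sd=noise_sd)
        rec = HDXRecord(s.residue, ki, k_ex, k_err, status=status)
        if k_ex is not None and k_ex > 0:
            rec.pf, rec.p_open, rec.band = protection_factor(ki, k_ex)
        elif status == "too_fast":
            rec.band = "unobservable"
        out.append(rec)
    return out
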