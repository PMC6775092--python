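"""Extraction of 15N relaxation observables from peak-intensity decays.

R1 comes from inversion-recovery series, R1rho from spin-lock series (both
mono-exponential least-squares fits), R2 from the standard tilted-frame
correction of R1rho, and the heteronuclear {1H}15N NOE from the
saturated/reference intensity ratio.  Errors are propagated from the fit
covariance matrix or from the spectral noise level.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from spindyn.io_tables import IntensityDecaySeries, ResidueID

logger = logging.getLogger(__name__)

#: heteronuclear NOE below this marks significantly increased internal
#: mobility of the backbone amide
NOE_MOBILE_THRESHOLD = 0.65


class FitError(ValueError):
    """Decay series cannot support the requested fit."""


@dataclass
class SpinLockSetup:
    """Spin-lock field strength; tilt angle follows from the resonance offset.

    ``omega1_hz`` is the spin-lock field strength nu_1 in Hz (2020 Hz is a
    typical value).  The tilt angle of the effective field is
    theta = arctan(omega1 / Omega) for a residue at offset Omega (Hz) from
    the carrier; on resonance theta = 90 deg and R1rho = R2.
    """

    omega1_hz: float

    def __post_init__(self) -> None:
        if self.omega1_hz <= 0:
            raise ValueError("spin-lock field strength must be > 0")

    def tilt_angle(self, offset_hz: float) -> float:
        """Tilt angle theta in radians for a given resonance offset."""
        if self.omega1_hz == 0 and offset_hz == 0:
            raise ValueError("undefined tilt: omega1 and offset both zero")
        return math.atan2(self.omega1_hz, offset_hz)


@dataclass
class MonoExpFit:
    """Result of a mono-exponential rate fit."""

    rate: float
    rate_err: float
    amplitude: float
    amplitude_err: float
    plateau: float | None = None  # inversion recovery only
    chi2: float = 0.0
    converged: bool = True
    flags: list[str] = field(default_factory=list)


@dataclass
class RelaxationRecord:
    """Per-residue relaxation observables at one static field (1H MHz)."""

    residue: ResidueID
    field_mhz: float
    r1: float | None = None
    r1_err: float | None = None
    r1rho: float | None = None
    r1rho_err: float | None = None
    r2: float | None = None
    r2_err: float | None = None
    noe: float | None = None
    noe_err: float | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.field_mhz <= 0:
            raise ValueError("field must be > 0 MHz")


def _initial_rate_guess(t: np.ndarray, y: np.ndarray) -> float:
    """Log-linear slope over the positive part of the decay."""
    pos = y > 0
    if pos.sum() >= 2 and np.ptp(t[pos]) > 0:
        slope = np.polyfit(t[pos], np.log(y[pos]), 1)[0]
        if slope < 0:
            return -slope
    span = np.ptp(t)
    return 1.0 / span if span > 0 else 1.0


def fit_monoexponential(
    series: IntensityDecaySeries, model: str = "decay"
) -> MonoExpFit:
    """Fit a mono-exponential model to a decay series by least squares.

    ``model='decay'`` fits the 2-parameter I(t) = I0 * exp(-R t) (spin lock,
    CPMG reference decays, H/D exchange); ``model='inversion_recovery'``
    fits the 3-parameter I(t) = Iinf - (Iinf - I0) * exp(-R t), which
    tolerates imperfect inversion.  Duplicate time points enter as
    independent observations.  The rate error is the square root of the
    corresponding diagonal element of the fit covariance matrix.

    Non-convergence or a degenerate (flat) series yields a flagged result
    rather than an exception; too few points is a hard :class:`FitError`.
    """
    t = series.times
    y = series.intensities
    npar = 3 if model == "inversion_recovery" else 2
    if model not in ("decay", "inversion_recovery"):
        raise ValueError(f"unknown model {model!r}")
    if series.n_distinct_times < npar or t.size < npar + 1:
        raise FitError(
            f"{series.residue}: need > {npar} points for {model} fit, "
            f"have {t.size} ({series.n_distinct_times} distinct)"
        )
    sigma = series.sigmas
    if sigma is None and series.duplicates:
        # seed a flat sigma from the spread of duplicate observations
        devs = []
        for tv in series.duplicates:
            vals = y[t == tv]
            devs.append(np.std(vals, ddof=1))
        s = float(np.mean(devs))
        if s > 0:
            sigma = np.full_like(y, s)
    flat = np.allclose(y, y[0], rtol=1e-12, atol=1e-300 + 1e-12 * abs(y[0]))
    scale = float(np.max(np.abs(y))) or 1.0

    if model == "decay":
        def f(tt, i0, r):
            return i0 * np.exp(-r * tt)
        p0 = [y[0], _initial_rate_guess(t, y)]
    else:
        def f(tt, iinf, i0, r):
            return iinf - (iinf - i0) * np.exp(-r * tt)
        p0 = [y[-1], y[0], _initial_rate_guess(t, np.abs(y - y[-1]) + 1e-12 * scale)]

    try:
        popt, pcov = curve_fit(
            f, t, y, p0=p0, sigma=sigma,
            absolute_sigma=sigma is not None, maxfev=10000,
        )
        perr = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    except (RuntimeError, ValueError):
        res = MonoExpFit(0.0, np.inf, float(y[0]), np.inf, converged=False)
        res.flags.append("non-convergent")
        return res

    resid = y - f(t, *popt)
    w = sigma if sigma is not None else np.ones_like(y)
    chi2 = float(np.sum((resid / w) ** 2))
    if model == "decay":
        fit = MonoExpFit(popt[1], perr[1], popt[0], perr[0], chi2=chi2)
    else:
        fit = MonoExpFit(popt[2], perr[2], popt[1], perr[1],
                         plateau=popt[0], chi2=chi2)
    if flat or not np.isfinite(fit.rate_err):
        fit.flags.append("degenerate")
    if fit.rate <= 0 or (fit.rate_err > 0 and fit.rate_err >= abs(fit.rate)):
        fit.flags.append("rate-undetermined")
    return fit


def r2_from_r1rho(
    r1rho: float,
    r1: float,
    setup: SpinLockSetup,
    offset_hz: float = 0.0,
    r1rho_err: float = 0.0,
    r1_err: float = 0.0,
) -> tuple[float, float]:
    """Transverse relaxation rate from R1rho and R1 via the tilted frame.

    R2 = (R1rho - R1 cos^2 theta) / sin^2 theta with
    theta = arctan(omega1 / Omega).  On resonance (Omega = 0) this reduces
    to R2 = R1rho.  The error is propagated to first order.  A combination
    implying negative R2 (R1rho < R1 cos^2 theta) is rejected.
    """
    theta = setup.tilt_angle(offset_hz)
    c2 = math.cos(theta) ** 2
    s2 = math.sin(theta) ** 2
    if s2 == 0:
        raise ValueError("tilt angle of 0: spin lock has no transverse component")
    if r1rho < r1 * c2:
        raise ValueError(
            f"R1rho = {r1rho:g}/s < R1 cos^2(theta) = {r1 * c2:g}/s "
            "would give negative R2"
        )
    r2 = (r1rho - r1 * c2) / s2
    err = math.sqrt((r1rho_err / s2) ** 2 + (r1_err * c2 / s2) ** 2)
    return r2, err


def het_noe(
    i_sat: float, i_ref: float, noise_sd: float = 0.0
) -> tuple[float, float, list[str]]:
    """Heteronuclear {1H}15N NOE from saturated and reference intensities.

    NOE = I_sat / I_ref with the error propagated from the spectral noise
    standard deviation through the ratio.  Negative values are legitimate
    (highly flexible residues).  Returns (noe, error, flags): ``mobile``
    when NOE < 0.65, ``undetermined`` when the reference intensity is
    consistent with zero within 3x noise.
    """
    flags: list[str] = []
    if i_ref == 0:
        raise ZeroDivisionError("reference intensity is zero")
    if abs(i_ref) < 3.0 * noise_sd:
        flags.append("undetermined")
    noe = i_sat / i_ref
    err = (
        abs(noe) * math.sqrt((noise_sd / i_sat) ** 2 + (noise_sd / i_ref) ** 2)
        if i_sat != 0
        else abs(noise_sd / i_ref)
    )
    if noe < NOE_MOBILE_THRESHOLD:
        flags.append("mobile")
    return noe, err, flags


def extract_rates(
    ir_series: list[IntensityDecaySeries],
    sl_series: list[IntensityDecaySeries],
    noe_pairs: dict[ResidueID, tuple[float, float, float]],
    field_mhz: float,
    setup: SpinLockSetup,
    offsets_hz: dict[ResidueID, float] | None = None,
) -> list[RelaxationRecord]:
    """Assemble per-residue relaxation records from the three experiments.

    ``noe_pairs`` maps residue -> (I_sat, I_ref, noise_sd).  ``offsets_hz``
    gives per-residue resonance offsets from the spin-lock carrier; if not
    supplied, on-resonance is assumed (with a logged warning), in which
    case R2 = R1rho.
    """
    if offsets_hz is None:
        logger.warning("no spin-lock offsets given; assuming on-resonance")
        offsets_hz = {}
    by_res: dict[ResidueID, RelaxationRecord] = {}

    def rec(rid: ResidueID) -> RelaxationRecord:
        return by_res.setdefault(rid, RelaxationRecord(rid, field_mhz))

    for s in ir_series:
        fit = fit_monoexponential(s, "inversion_recovery")
        r = rec(s.residue)
        if fit.converged and "rate-undetermined" not in fit.flags:
            r.r1, r.r1_err = fit.rate, fit.rate_err
        else:
            r.flags.append("R1-fit-failed")
    for s in sl_series:
        fit = fit_monoexponential(s, "decay")
        r = rec(s.residue)
        if fit.converged and "rate-undetermined" not in fit.flags:
            r.r1rho, r.r1rho_err = fit.rate, fit.rate_err
        else:
            r.flags.append("R1rho-fit-failed")
    for rid, (i_sat, i_ref, noise) in noe_pairs.items():
        r = rec(rid)
        noe, err, flags = het_noe(i_sat, i_ref, noise)
        r.noe, r.noe_err = noe, err
        r.flags.extend(flags)
    for r in by_res.values():
        if r.r1 is not None and r.r1rho is not None:
            try:
                r.r2, r.r2_err = r2_from_r1rho(
                    r.r1rho, r.r1, setup,
                    offsets_hz.get(r.residue, 0.0),
                    r.r1rho_err or 0.0, r.r1_err or 0.0,
                )
            except ValueError:
                r.flags.append("R2-negative")
    return sorted(by_res.values(), key=lambda r: r.residue)
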