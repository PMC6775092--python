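"""15N CPMG relaxation dispersion: profiles, simulation, and global fitting.

Effective transverse relaxation rates R2,eff(nu_cpmg) are computed from
constant-time CPMG intensities, simulated for a two-site exchange model by
numerical propagation of the Bloch-McConnell equations, and fit globally
across residues and static fields with shared exchange parameters (kex,
pB), per-residue 15N chemical-shift differences |dw| (ppm, shared across
fields), and per-residue-per-field intrinsic rates R2,0.

The independently implemented Carver-Richards closed form serves as a fast
initial-guess engine and as a cross-check oracle for the numerical
propagator.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import f as f_dist

from spindyn.diffusion_modelfree import GAMMA_H, GAMMA_N
from spindyn.io_tables import ResidueID

logger = logging.getLogger(__name__)

#: minimum relative error on R2,eff, accounting for offset effects and
#: other systematic imperfections
ERROR_FLOOR = 0.02


class ScheduleError(ValueError):
    """CPMG frequency list incompatible with the constant-time interval."""


class GlobalFitError(RuntimeError):
    """Global dispersion fit failed from every starting point."""


def nu_delta_convert(value: float) -> float:
    """Convert between CPMG frequency and inter-pulse delay.

    nu_cpmg = 1/(2 delta) where delta is the time between consecutive
    refocusing pulses; the transform is its own inverse, so this single
    function converts delta (s) -> nu (Hz) and nu (Hz) -> delta (s).
    """
    if value <= 0:
        raise ValueError("delay/frequency must be > 0")
    return 1.0 / (2.0 * value)


@dataclass
class CPMGSchedule:
    """Constant-time CPMG sampling schedule at one static field.

    Every nu must fit a whole number of echo blocks into the constant-time
    interval: T_cpmg * nu must be an even positive integer.
    """

    field_mhz: float
    t_cpmg: float
    nu_hz: np.ndarray
    duplicates: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        self.nu_hz = np.asarray(self.nu_hz, dtype=float)
        if self.field_mhz <= 0 or self.t_cpmg <= 0:
            raise ValueError("field and T_cpmg must be > 0")
        if np.any(self.nu_hz <= 0):
            raise ScheduleError("all nu_cpmg must be > 0")
        n = self.t_cpmg * self.nu_hz
        n_round = np.round(n)
        # tolerance admits values that round-tripped through 6-significant-
        # figure report tables, but rejects genuinely fractional blocks
        bad = (np.abs(n - n_round) > 1e-4 * np.maximum(n, 1.0)) | (
            n_round % 2 != 0
        ) | (n_round <= 0)
        if np.any(bad):
            raise ScheduleError(
                f"T_cpmg*nu must be an even positive integer; offending nu: "
                f"{self.nu_hz[bad]}"
            )

    @property
    def n_blocks(self) -> np.ndarray:
        """Whole echo-block count T*nu per scheduled frequency."""
        return np.round(self.t_cpmg * self.nu_hz).astype(int)

    @staticmethod
    def valid_nu(t_cpmg: float, nu: float) -> float:
        """Snap a frequency to the nearest valid one (T*nu even integer)."""
        n = max(2.0, 2.0 * round(t_cpmg * nu / 2.0))
        return n / t_cpmg


@dataclass
class DispersionProfile:
    """R2,eff(nu_cpmg) for one residue on one schedule.

    ``nu_hz`` may contain repeated entries (duplicate measurements); the
    arrays are point-wise aligned.  ``sigma`` may be None until
    :func:`estimate_sigma` is applied.
    """

    residue: ResidueID
    schedule: CPMGSchedule
    nu_hz: np.ndarray
    r2eff: np.ndarray
    sigma: np.ndarray | None = None
    i0: float = 1.0

    def __post_init__(self) -> None:
        self.nu_hz = np.asarray(self.nu_hz, dtype=float)
        self.r2eff = np.asarray(self.r2eff, dtype=float)
        if self.nu_hz.shape != self.r2eff.shape:
            raise ValueError("nu and R2eff must be point-wise aligned")
        if not np.all(np.isfinite(self.r2eff)):
            raise ValueError("non-finite R2eff")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)


@dataclass
class TwoStateModel:
    """Global two-site exchange parameters and per-residue quantities."""

    kex: float                     # /s, k_AB + k_BA
    pb: float                      # minor-state population, fraction
    dw_ppm: dict[ResidueID, float]
    r20: dict[tuple[int, float], float]   # (residue number, field) -> /s
    kex_err: float = 0.0
    pb_err: float = 0.0
    dw_err: dict[ResidueID, float] = field(default_factory=dict)
    r20_err: dict[tuple[int, float], float] = field(default_factory=dict)
    chi2: float = 0.0
    n_points: int = 0
    n_params: int = 0
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 < self.pb < 0.5):
            raise ValueError("pB must lie in (0, 0.5)")
        if self.kex <= 0:
            raise ValueError("kex must be > 0")
        if any(d < 0 for d in self.dw_ppm.values()):
            raise ValueError("|dw| must be >= 0")

    @property
    def pa(self) -> float:
        return 1.0 - self.pb


def r2eff_from_intensity(i: float, i0: float, t_cpmg: float) -> float:
    """R2,eff = -ln(I/I0) / T_cpmg.

    Negative results (I > I0, possible through noise) are allowed but
    logged; non-positive intensities are rejected.
    """
    if t_cpmg <= 0:
        raise ValueError("T_cpmg must be > 0")
    if i <= 0 or i0 <= 0:
        raise ValueError(f"non-positive intensity (I={i}, I0={i0})")
    r2eff = -math.log(i / i0) / t_cpmg
    if r2eff < 0:
        logger.info("negative R2eff %.3f/s (I > I0); keeping, flag downstream",
                    r2eff)
    return r2eff


def estimate_sigma(profile: DispersionProfile) -> np.ndarray:
    """Point-wise R2,eff errors from duplicates with a 2% relative floor.

    The standard deviation pooled over all duplicated nu values is floored
    point-wise at ``ERROR_FLOOR * R2eff``.  Points with R2eff <= 0 get the
    floor of the median positive R2eff instead (documented fallback).
    Without any duplicates the floor alone is used, with a warning.
    """
    nu = profile.nu_hz
    r2 = profile.r2eff
    uniq, counts = np.unique(nu, return_counts=True)
    ss = 0.0
    dof = 0
    for u, c in zip(uniq, counts):
        if c > 1:
            vals = r2[nu == u]
            ss += float(np.sum((vals - vals.mean()) ** 2))
            dof += c - 1
    if dof > 0:
        pooled = math.sqrt(ss / dof)
    else:
        pooled = 0.0
        logger.warning(
            "%s: no duplicate nu values; sigma is the %.1f%% floor only",
            profile.residue, 100 * ERROR_FLOOR,
        )
    floor_base = np.abs(r2)
    pos = r2 > 0
    fallback = float(np.median(r2[pos])) if np.any(pos) else 1.0
    floor_base = np.where(pos, floor_base, fallback)
    sigma = np.maximum(pooled, ERROR_FLOOR * floor_base)
    profile.sigma = sigma
    return sigma


# ---------------------------------------------------------------------------
# two-site exchange engines

def dw_rad_per_ppm(field_mhz: float) -> float:
    """rad/s per ppm of 15N shift difference at a given 1H field (MHz)."""
    return 2.0 * math.pi * field_mhz * abs(GAMMA_N) / GAMMA_H


def _expm2(mats: np.ndarray) -> np.ndarray:
    """Closed-form matrix exponential of stacked complex 2x2 matrices."""
    a = mats[..., 0, 0]
    b = mats[..., 0, 1]
    c = mats[..., 1, 0]
    d = mats[..., 1, 1]
    m = 0.5 * (a + d)
    q = np.sqrt(0.25 * (a - d) ** 2 + b * c + 0j)
    coshq = np.cosh(q)
    small = np.abs(q) < 1e-8
    qs = np.where(small, 1.0, q)
    sinhc = np.where(small, 1.0 + q**2 / 6.0, np.sinh(qs) / qs)
    em = np.exp(m)
    out = np.empty_like(mats)
    out[..., 0, 0] = em * (coshq + sinhc * (a - m))
    out[..., 0, 1] = em * sinhc * b
    out[..., 1, 0] = em * sinhc * c
    out[..., 1, 1] = em * (coshq + sinhc * (d - m))
    return out


def _matpow(mats: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Stacked 2x2 matrix power with per-matrix integer exponents >= 1."""
    n = np.asarray(n, dtype=int)
    result = np.zeros_like(mats)
    result[..., 0, 0] = 1.0
    result[..., 1, 1] = 1.0
    power = mats.copy()
    remaining = n.copy()
    while np.any(remaining > 0):
        odd = remaining % 2 == 1
        if np.any(odd):
            result[odd] = result[odd] @ power[odd]
        remaining //= 2
        if np.any(remaining > 0):
            power = power @ power
    return result


def bm_rex(
    nu_hz: np.ndarray,
    n_blocks: np.ndarray,
    t_cpmg: np.ndarray | float,
    kex: float,
    pb: float,
    dw_rad: np.ndarray | float,
) -> np.ndarray:
    """Exchange contribution to R2,eff by Bloch-McConnell propagation.

    The intrinsic rate R2,0 (assumed equal in both states) commutes with
    the exchange evolution and enters additively, so it is omitted here:
    the returned value is R2,eff - R2,0.  The constant-time train is
    propagated as T*nu palindromic two-pulse units
    (delta/2 - 180 - delta - 180 - delta/2) of duration 1/nu each, with
    ideal 180 pulses implemented as complex conjugation.
    """
    nu_hz = np.atleast_1d(np.asarray(nu_hz, dtype=float))
    n_blocks = np.broadcast_to(np.asarray(n_blocks, dtype=int), nu_hz.shape)
    t = np.broadcast_to(np.asarray(t_cpmg, dtype=float), nu_hz.shape)
    dw = np.broadcast_to(np.asarray(dw_rad, dtype=float), nu_hz.shape)
    pa = 1.0 - pb
    kab = pb * kex
    kba = pa * kex
    delta = 1.0 / (2.0 * nu_hz)

    L = np.zeros(nu_hz.shape + (2, 2), dtype=complex)
    L[..., 0, 0] = -kab
    L[..., 0, 1] = kba
    L[..., 1, 0] = kab
    L[..., 1, 1] = -kba + 1j * dw
    e_half = _expm2(L * (0.5 * delta)[..., None, None])
    e_full = _expm2(L * delta[..., None, None])
    # 180-degree pulses as conjugation: K E K = conj(E), so one unit is
    # E(d/2) conj(E(d)) E(d/2), a complex-linear map
    unit = e_half @ np.conj(e_full) @ e_half
    total = _matpow(unit, n_blocks)
    m0 = np.array([pa, pb], dtype=complex)
    m_final = total @ m0
    mag = np.abs(m_final[..., 0] + m_final[..., 1])
    return -np.log(mag) / t


def simulate_bm(
    kex: float,
    pb: float,
    dw_ppm: float,
    r20: float,
    schedule: CPMGSchedule,
) -> np.ndarray:
    """R2,eff(nu) for one residue slice of a two-state model on a schedule."""
    dw_rad = dw_ppm * dw_rad_per_ppm(schedule.field_mhz)
    return r20 + bm_rex(
        schedule.nu_hz, schedule.n_blocks, schedule.t_cpmg, kex, pb, dw_rad
    )


def cr_rex(
    nu_hz: np.ndarray,
    kex: float,
    pb: float,
    dw_rad: np.ndarray | float,
) -> np.ndarray:
    """Carver-Richards closed-form exchange contribution R2,eff - R2,0.

    Equal intrinsic rates in both states are assumed.  In numerically
    unstable corners the arccosh argument is evaluated in the complex plane
    and the real part returned; callers wanting full accuracy there should
    use :func:`bm_rex`.
    """
    nu = np.atleast_1d(np.asarray(nu_hz, dtype=float))
    dw = np.broadcast_to(np.asarray(dw_rad, dtype=float), nu.shape)
    pa = 1.0 - pb
    dk = kex * (pb - pa)
    psi = dk * dk - dw * dw + 4.0 * pa * pb * kex * kex
    zeta = -2.0 * dw * dk
    root = np.sqrt(psi * psi + zeta * zeta)
    d_plus = 0.5 * (1.0 + (psi + 2.0 * dw * dw) / root)
    d_minus = 0.5 * (-1.0 + (psi + 2.0 * dw * dw) / root)
    eta_plus = np.sqrt(np.maximum(psi + root, 0.0)) / (2.0 * math.sqrt(2.0) * nu)
    eta_minus = np.sqrt(np.maximum(root - psi, 0.0)) / (2.0 * math.sqrt(2.0) * nu)
    arg = d_plus * np.cosh(eta_plus) - d_minus * np.cos(eta_minus)
    acosh = np.log(arg.astype(complex) + np.sqrt(arg.astype(complex) ** 2 - 1.0))
    return 0.5 * kex - nu * np.real(acosh)


def carver_richards(
    kex: float,
    pb: float,
    dw_ppm: float,
    r20: float,
    schedule: CPMGSchedule,
) -> np.ndarray:
    """Closed-form R2,eff(nu) profile (oracle / initial-guess engine)."""
    dw_rad = dw_ppm * dw_rad_per_ppm(schedule.field_mhz)
    out = r20 + cr_rex(schedule.nu_hz, kex, pb, dw_rad)
    if not np.all(np.isfinite(out)):
        bad = ~np.isfinite(out)
        out[bad] = r20 + bm_rex(
            schedule.nu_hz[bad], schedule.n_blocks[bad], schedule.t_cpmg,
            kex, pb, dw_rad,
        )
    return out


def luz_meiboom_rex(nu_hz: np.ndarray, kex: float, phi: float) -> np.ndarray:
    """Fast-exchange-limit exchange contribution (phi = pA pB dw^2)."""
    nu = np.asarray(nu_hz, dtype=float)
    return (phi / kex) * (1.0 - (4.0 * nu / kex) * np.tanh(kex / (4.0 * nu)))


# ---------------------------------------------------------------------------
# global fitting

KEX_GRID_DEFAULT = (100.0, 300.0, 1000.0, 3000.0)
PB_GRID_DEFAULT = (0.005, 0.02, 0.10)


def _flatten(profiles: list[DispersionProfile]):
    """Stack all profile points into flat arrays with index maps."""
    residues = sorted({p.residue for p in profiles})
    res_index = {rid: i for i, rid in enumerate(residues)}
    prof_keys: list[tuple[int, float]] = []
    nu, nb, tt, dwf, obs, sig, ri, pi = [], [], [], [], [], [], [], []
    for p in profiles:
        if p.sigma is None:
            raise ValueError(f"{p.residue}: sigma not populated; "
                             "run estimate_sigma first")
        key = (p.residue.number, p.schedule.field_mhz)
        if key not in prof_keys:
            prof_keys.append(key)
        k = prof_keys.index(key)
        n_pt = p.nu_hz.size
        nu.append(p.nu_hz)
        nb.append(np.round(p.schedule.t_cpmg * p.nu_hz).astype(int))
        tt.append(np.full(n_pt, p.schedule.t_cpmg))
        dwf.append(np.full(n_pt, dw_rad_per_ppm(p.schedule.field_mhz)))
        obs.append(p.r2eff)
        sig.append(p.sigma)
        ri.append(np.full(n_pt, res_index[p.residue], dtype=int))
        pi.append(np.full(n_pt, k, dtype=int))
    return (
        residues, prof_keys,
        np.concatenate(nu), np.concatenate(nb), np.concatenate(tt),
        np.concatenate(dwf), np.concatenate(obs), np.concatenate(sig),
        np.concatenate(ri), np.concatenate(pi),
    )


def fit_global_two_state(
    profiles: list[DispersionProfile],
    kex_grid: tuple[float, ...] = KEX_GRID_DEFAULT,
    pb_grid: tuple[float, ...] = PB_GRID_DEFAULT,
    dw_scan_max: float = 8.0,
) -> TwoStateModel:
    """Global two-state fit of dispersion profiles across residues/fields.

    A single (kex, pB) is shared by all residues; each residue has one
    |dw| in ppm shared across fields and one R2,0 per field.  Multi-start
    initial guesses are generated on the (kex, pB) grid with per-residue
    dw scanned against the Carver-Richards form (R2,0 profiled out
    analytically); the best grid start seeds a full nonlinear least-squares
    refinement against the Bloch-McConnell propagator.  Parameter errors
    come from the covariance matrix at the optimum.
    """
    if not profiles:
        raise ValueError("no profiles")
    (residues, prof_keys, nu, nb, tt, dwf, obs, sig, ri, pi) = _flatten(profiles)
    n_res = len(residues)
    n_prof = len(prof_keys)
    n_pts = nu.size

    dw_scan = np.linspace(0.0, dw_scan_max, 33)

    def grid_score(kex, pb):
        """chi2 and per-residue dw / per-profile r20 for fixed (kex, pb)."""
        dw_best = np.zeros(n_res)
        r20_best = np.zeros(n_prof)
        chi2 = 0.0
        for r in range(n_res):
            mask = ri == r
            best = (np.inf, 0.0, {})
            for dw in dw_scan:
                rex = cr_rex(nu[mask], kex, pb, dw * dwf[mask])
                c2 = 0.0
                r20s = {}
                for k in np.unique(pi[mask]):
                    sub = mask & (pi == k)
                    rexs = cr_rex(nu[sub], kex, pb, dw * dwf[sub])
                    w = 1.0 / sig[sub] ** 2
                    r20k = float(np.sum(w * (obs[sub] - rexs)) / np.sum(w))
                    c2 += float(np.sum(((obs[sub] - rexs - r20k) / sig[sub]) ** 2))
                    r20s[int(k)] = r20k
                if c2 < best[0]:
                    best = (c2, dw, r20s)
            chi2 += best[0]
            dw_best[r] = best[1]
            for k, v in best[2].items():
                r20_best[k] = v
        return chi2, dw_best, r20_best

    starts = []
    for kex0 in kex_grid:
        for pb0 in pb_grid:
            c2, dw0, r200 = grid_score(kex0, pb0)
            starts.append((c2, kex0, pb0, dw0, r200))
    starts.sort(key=lambda s: s[0])
    _, kex0, pb0, dw0, r200 = starts[0]

    def residual(x):
        kex, pb = x[0], x[1]
        dw = x[2 : 2 + n_res]
        r20 = x[2 + n_res :]
        rex = bm_rex(nu, nb, tt, kex, pb, dw[ri] * dwf)
        return (r20[pi] + rex - obs) / sig

    x0 = np.concatenate([[kex0, pb0], dw0, r200])
    lb = np.concatenate([[1e-2, 1e-6], np.zeros(n_res), np.full(n_prof, 0.0)])
    ub = np.concatenate(
        [[1e6, 0.5 - 1e-9], np.full(n_res, 50.0), np.full(n_prof, 1e3)]
    )
    x0 = np.clip(x0, lb + 1e-12, ub - 1e-12)
    diagnostics = []
    sol = least_squares(
        residual, x0, bounds=(lb, ub),
        x_scale=np.concatenate(
            [[1000.0, 0.01], np.full(n_res, 1.0), np.full(n_prof, 10.0)]
        ),
        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=400 * (n_res + n_prof + 2),
    )
    if not sol.success and not np.isfinite(sol.cost):
        diagnostics.append(f"start (kex={kex0}, pb={pb0}): {sol.message}")
        raise GlobalFitError("global fit failed: " + "; ".join(diagnostics))

    x = sol.x
    # covariance from the jacobian of the sigma-weighted residuals
    jtj = sol.jac.T @ sol.jac
    try:
        cov = np.linalg.inv(jtj)
        perr = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    except np.linalg.LinAlgError:
        perr = np.full(x.size, np.inf)

    model = TwoStateModel(
        kex=float(x[0]),
        pb=float(x[1]),
        dw_ppm={rid: float(x[2 + i]) for i, rid in enumerate(residues)},
        r20={key: float(x[2 + n_res + k]) for k, key in enumerate(prof_keys)},
        kex_err=float(perr[0]),
        pb_err=float(perr[1]),
        dw_err={rid: float(perr[2 + i]) for i, rid in enumerate(residues)},
        r20_err={key: float(perr[2 + n_res + k])
                 for k, key in enumerate(prof_keys)},
        chi2=float(np.sum(sol.fun**2)),
        n_points=n_pts,
        n_params=2 + n_res + n_prof,
    )
    if model.pb_err >= model.pb:
        model.flags.append("pB-unidentifiable")
    return model


def screen_significant(
    profiles: list[DispersionProfile],
    amplitude_factor: float = 3.0,
    alpha: float = 0.01,
    kex_starts: tuple[float, ...] = (100.0, 300.0, 1000.0, 3000.0),
) -> tuple[list[DispersionProfile], list[tuple[ResidueID, str]]]:
    """Keep residues with measurable and significant dispersion.

    A residue passes if (max R2eff - min R2eff) >= amplitude_factor times
    the median sigma over its points (inclusive boundary) AND a per-residue
    fast-exchange fit improves chi2 over a flat (R2,0-only) model at
    p < alpha by an F-test.  Both thresholds are logged per exclusion.
    """
    by_res: dict[ResidueID, list[DispersionProfile]] = {}
    for p in profiles:
        if p.sigma is None:
            estimate_sigma(p)
        by_res.setdefault(p.residue, []).append(p)

    kept: list[DispersionProfile] = []
    log: list[tuple[ResidueID, str]] = []
    for rid in sorted(by_res):
        group = by_res[rid]
        r2 = np.concatenate([p.r2eff for p in group])
        sg = np.concatenate([p.sigma for p in group])
        amp = float(r2.max() - r2.min())
        med = float(np.median(sg))
        if amp < amplitude_factor * med:
            log.append(
                (rid, f"amplitude {amp:.3g} < {amplitude_factor}*median sigma "
                      f"{amplitude_factor * med:.3g}")
            )
            continue
        # flat model: one R2,0 per profile
        chi2_flat = 0.0
        for p in group:
            w = 1.0 / p.sigma**2
            r20 = float(np.sum(w * p.r2eff) / np.sum(w))
            chi2_flat += float(np.sum(((p.r2eff - r20) / p.sigma) ** 2))
        n = r2.size
        k_flat = len(group)
        k_ex = k_flat + 2

        def ex_resid(x):
            kex, phi = math.exp(x[0]), math.exp(x[1])
            out = []
            for j, p in enumerate(group):
                scale = (p.schedule.field_mhz / group[0].schedule.field_mhz) ** 2
                rex = luz_meiboom_rex(p.nu_hz, kex, phi * scale)
                out.append((x[2 + j] + rex - p.r2eff) / p.sigma)
            return np.concatenate(out)

        chi2_ex = chi2_flat
        for kex0 in kex_starts:
            x0 = [math.log(kex0), math.log(max(amp * kex0, 1.0))] + [
                float(np.median(p.r2eff)) for p in group
            ]
            sol = least_squares(ex_resid, x0, xtol=1e-10, ftol=1e-10)
            chi2_ex = min(chi2_ex, float(np.sum(sol.fun**2)))
        df2 = n - k_ex
        if df2 <= 0 or chi2_ex <= 0:
            p_val = 0.0
        else:
            f_stat = ((chi2_flat - chi2_ex) / 2.0) / (chi2_ex / df2)
            p_val = float(f_dist.sf(max(f_stat, 0.0), 2, df2))
        if p_val < alpha:
            kept.extend(group)
        else:
            log.append((rid, f"F-test p = {p_val:.3g} >= {alpha}"))
    return kept, log


def rmsd_vs_random_coil(
    dw_ppm: dict[ResidueID, float],
    rc_shifts: dict[ResidueID, float],
) -> float:
    """RMS difference (ppm) between fitted |dw| and a random-coil table."""
    common = sorted(set(dw_ppm) & set(rc_shifts))
    if not common:
        raise ValueError("no residues shared between dw set and reference")
    d = np.array([dw_ppm[r] - rc_shifts[r] for r in common])
    return float(np.sqrt(np.mean(d**2)))
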