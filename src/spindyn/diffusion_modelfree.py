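"""Rotational diffusion tensor and Lipari-Szabo model-free analysis.

The overall tumbling of the molecule is described by an axially symmetric
(or isotropic) rotational diffusion tensor estimated from the R2/R1 ratios
of rigid residues; internal motion of each backbone amide is then described
by the model-free spectral density

    J(w) = (2/5) sum_k A_k(alpha) [ S2 tau_k / (1 + (w tau_k)^2)
                                    + (S2f - S2) tau_k'' / (1 + (w tau_k'')^2) ]

with 1/tau_k'' = 1/tau_k + 1/tau_e, the three axial correlation times
tau_A = 1/(6 Dperp), tau_B = 1/(5 Dperp + Dpar), tau_C = 1/(2 Dperp + 4 Dpar)
and Woessner amplitudes A_k(alpha) of the NH vector at angle alpha to the
unique axis.  R1, R2 and the heteronuclear NOE follow from the standard
15N dipolar + CSA expressions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from spindyn.io_tables import ResidueID
from spindyn.relaxation import NOE_MOBILE_THRESHOLD, RelaxationRecord

logger = logging.getLogger(__name__)

# physical constants (SI)
GAMMA_H = 2.6752218744e8   # 1H gyromagnetic ratio, rad/s/T
GAMMA_N = -2.7126189e7     # 15N gyromagnetic ratio, rad/s/T (negative)
HBAR = 1.054571817e-34     # J s
MU0_4PI = 1e-7             # T^2 m^3 / J

# defaults for the 15N amide interaction parameters (configurable)
RNH_DEFAULT = 1.02e-10     # N-H bond length, m
CSA_DEFAULT = -160e-6      # 15N chemical shift anisotropy, dimensionless

RATIO_DEVIATION_LIMIT = 0.10   # rigid-core R2/R1 filter: +/-10% of the mean
MIN_RIGID_RESIDUES = 10


class TensorFitError(ValueError):
    """Rigid subset too small or degenerate for a diffusion-tensor fit."""


@dataclass
class DiffusionTensor:
    """Axially symmetric (or isotropic) rotational diffusion tensor.

    ``orientation`` holds the polar angles (theta, phi) of the unique axis
    in the coordinate frame of the reference structure.  For the isotropic
    shape ``d_par == d_perp == d_iso``.  An oblate tensor has
    ``d_par < d_perp``.
    """

    shape: str                       # "isotropic" | "axial"
    d_iso: float                     # /s
    d_par: float                     # /s
    d_perp: float                    # /s
    orientation: tuple[float, float] = (0.0, 0.0)   # radians

    def __post_init__(self) -> None:
        if self.shape not in ("isotropic", "axial"):
            raise ValueError(f"unknown tensor shape {self.shape!r}")
        if min(self.d_iso, self.d_par, self.d_perp) <= 0:
            raise ValueError("diffusion coefficients must be > 0")
        if not math.isclose(
            self.d_iso, (self.d_par + 2.0 * self.d_perp) / 3.0, rel_tol=1e-6
        ):
            raise ValueError("d_iso must equal (d_par + 2 d_perp)/3")

    @classmethod
    def isotropic(cls, d_iso: float) -> "DiffusionTensor":
        return cls("isotropic", d_iso, d_iso, d_iso)

    @classmethod
    def axial(
        cls, d_par: float, d_perp: float,
        orientation: tuple[float, float] = (0.0, 0.0),
    ) -> "DiffusionTensor":
        return cls("axial", (d_par + 2 * d_perp) / 3.0, d_par, d_perp, orientation)

    @property
    def is_oblate(self) -> bool:
        return self.d_par < self.d_perp

    @property
    def axis(self) -> np.ndarray:
        th, ph = self.orientation
        return np.array(
            [math.sin(th) * math.cos(ph), math.sin(th) * math.sin(ph), math.cos(th)]
        )


def correlation_times(tensor: DiffusionTensor) -> dict[str, float]:
    """Overall rotational autocorrelation times (s) of the tensor.

    tau_A = 1/(6 Dperp), tau_B = 1/(5 Dperp + Dpar),
    tau_C = 1/(2 Dperp + 4 Dpar), tau_iso = 1/(6 Diso).  For an isotropic
    tensor all four coincide at 1/(6 D).
    """
    return {
        "tau_a": 1.0 / (6.0 * tensor.d_perp),
        "tau_b": 1.0 / (5.0 * tensor.d_perp + tensor.d_par),
        "tau_c": 1.0 / (2.0 * tensor.d_perp + 4.0 * tensor.d_par),
        "tau_iso": 1.0 / (6.0 * tensor.d_iso),
    }


def _axial_weights(cos_alpha: float) -> np.ndarray:
    """Woessner amplitudes (A_A, A_B, A_C); they sum to 1."""
    x2 = cos_alpha * cos_alpha
    return np.array(
        [
            ((3.0 * x2 - 1.0) / 2.0) ** 2,
            3.0 * x2 * (1.0 - x2),
            0.75 * (1.0 - x2) ** 2,
        ]
    )


def spectral_density(
    omega: np.ndarray,
    tensor: DiffusionTensor,
    nh_vector: np.ndarray,
    s2: float,
    tau_e: float = 0.0,
    s2f: float = 1.0,
) -> np.ndarray:
    """Model-free spectral density J(omega) in s/rad for one NH vector."""
    ct = correlation_times(tensor)
    taus = np.array([ct["tau_a"], ct["tau_b"], ct["tau_c"]])
    v = np.asarray(nh_vector, dtype=float)
    v = v / np.linalg.norm(v)
    cos_alpha = float(np.dot(v, tensor.axis))
    weights = _axial_weights(cos_alpha)
    omega = np.asarray(omega, dtype=float)
    j = np.zeros_like(omega)
    for a_k, tau_k in zip(weights, taus):
        j += a_k * s2 * tau_k / (1.0 + (omega * tau_k) ** 2)
        if s2f - s2 != 0.0 and tau_e > 0.0:
            tau_kk = 1.0 / (1.0 / tau_k + 1.0 / tau_e)
            j += a_k * (s2f - s2) * tau_kk / (1.0 + (omega * tau_kk) ** 2)
    return 0.4 * j


def _interaction_constants(field_mhz: float, rnh: float, csa: float):
    omega_h = 2.0 * math.pi * field_mhz * 1e6
    omega_n = omega_h * abs(GAMMA_N) / GAMMA_H
    d = MU0_4PI * HBAR * GAMMA_H * abs(GAMMA_N) / rnh**3
    c2 = (omega_n * csa) ** 2 / 3.0
    return omega_h, omega_n, d * d, c2


def predict_rates(
    tensor: DiffusionTensor,
    nh_vector: np.ndarray,
    field_mhz: float,
    s2: float = 1.0,
    tau_e: float = 0.0,
    rex: float = 0.0,
    s2f: float = 1.0,
    rnh: float = RNH_DEFAULT,
    csa: float = CSA_DEFAULT,
) -> dict[str, float]:
    """Predict {R1, R2, NOE} for a backbone amide 15N spin.

    Standard dipolar + CSA expressions with the model-free spectral density;
    ``rex`` is an additive exchange contribution to R2 at this field.  With
    S2 = 1, tau_e = 0, rex = 0 the rigid-tumbling rates are returned.
    """
    if field_mhz <= 0:
        raise ValueError("field must be > 0")
    omega_h, omega_n, d2, c2 = _interaction_constants(field_mhz, rnh, csa)
    freqs = np.array(
        [0.0, omega_n, omega_h - omega_n, omega_h, omega_h + omega_n]
    )
    j0, jn, jhmn, jh, jhpn = spectral_density(
        freqs, tensor, nh_vector, s2, tau_e, s2f
    )
    r1 = (d2 / 4.0) * (jhmn + 3.0 * jn + 6.0 * jhpn) + c2 * jn
    r2 = (
        (d2 / 8.0) * (4.0 * j0 + jhmn + 3.0 * jn + 6.0 * jh + 6.0 * jhpn)
        + (c2 / 6.0) * (4.0 * j0 + 3.0 * jn)
        + rex
    )
    noe = 1.0 + (d2 / 4.0) * (GAMMA_H / GAMMA_N) * (6.0 * jhpn - jhmn) / r1
    return {"R1": r1, "R2": r2, "NOE": noe}


def filter_rigid_residues(
    records: list[RelaxationRecord],
) -> tuple[list[RelaxationRecord], list[tuple[ResidueID, str]]]:
    """Select rigid-core residues suitable for the diffusion-tensor fit.

    Excludes residues with NOE < 0.65 (increased internal mobility) and,
    after recomputing the mean R2/R1 once over the NOE survivors, residues
    whose R2/R1 ratio deviates from that mean by more than 10% (exchange
    contributions or fast internal motion).  Returns the surviving records
    and an exclusion log of (residue, reason).
    """
    log: list[tuple[ResidueID, str]] = []
    complete = []
    for r in records:
        if r.r1 is None or r.r2 is None or r.noe is None:
            log.append((r.residue, "incomplete"))
        else:
            complete.append(r)
    noe_ok = []
    for r in complete:
        if r.noe < NOE_MOBILE_THRESHOLD:
            log.append((r.residue, f"NOE<{NOE_MOBILE_THRESHOLD}"))
        else:
            noe_ok.append(r)
    kept: list[RelaxationRecord] = []
    if noe_ok:
        ratios = np.array([r.r2 / r.r1 for r in noe_ok])
        mean = float(np.mean(ratios))
        for r, ratio in zip(noe_ok, ratios):
            if abs(ratio - mean) > RATIO_DEVIATION_LIMIT * mean:
                log.append(
                    (r.residue,
                     f"|R2/R1-mean|>{RATIO_DEVIATION_LIMIT:.0%} of mean")
                )
            else:
                kept.append(r)
    if len(kept) < MIN_RIGID_RESIDUES:
        raise TensorFitError(
            f"only {len(kept)} rigid residues survive filtering; "
            f">= {MIN_RIGID_RESIDUES} required for a tensor fit"
        )
    return kept, log


def _predicted_ratio(
    tensor: DiffusionTensor, nh: np.ndarray, field_mhz: float,
    rnh: float, csa: float,
) -> float:
    r = predict_rates(tensor, nh, field_mhz, rnh=rnh, csa=csa)
    return r["R2"] / r["R1"]


@dataclass
class DiffusionFit:
    """Isotropic and axial tensor fits with their chi-square values."""

    isotropic: DiffusionTensor
    chi2_isotropic: float
    axial: DiffusionTensor
    chi2_axial: float
    n_residues: int = 0

    @property
    def best(self) -> DiffusionTensor:
        return self.axial if self.chi2_axial < self.chi2_isotropic else self.isotropic


def fit_diffusion_tensor(
    ratios: dict[ResidueID, tuple[float, float]],
    nh_vectors: dict[ResidueID, np.ndarray],
    field_mhz: float,
    rnh: float = RNH_DEFAULT,
    csa: float = CSA_DEFAULT,
) -> DiffusionFit:
    """Fit isotropic and axially symmetric diffusion tensors to R2/R1 ratios.

    ``ratios`` maps residue -> (R2/R1, error); ``nh_vectors`` gives the NH
    bond unit vectors from one designated reference model.  Only rigid-core
    residues (see :func:`filter_rigid_residues`) should be passed.  Both
    fits are returned with chi-square values for model comparison.
    """
    common = [rid for rid in ratios if rid in nh_vectors]
    if len(common) < MIN_RIGID_RESIDUES:
        raise TensorFitError(
            f"{len(common)} residues with both ratio and NH vector; "
            f">= {MIN_RIGID_RESIDUES} required"
        )
    obs = np.array([ratios[rid][0] for rid in common])
    err = np.array([ratios[rid][1] or 1.0 for rid in common])
    err = np.where(err > 0, err, 1.0)
    vecs = np.array([np.asarray(nh_vectors[rid], float) for rid in common])
    vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
    # near-parallel NH vector distribution cannot constrain the orientation
    spread = np.linalg.norm(np.cross(vecs, vecs[0]), axis=1).max()
    if spread < 0.1:
        logger.warning(
            "NH vectors nearly parallel (max sine %.3f); axial orientation "
            "will be unreliable", spread,
        )

    def iso_resid(log_d):
        t = DiffusionTensor.isotropic(math.exp(log_d[0]))
        pred = np.array(
            [_predicted_ratio(t, v, field_mhz, rnh, csa) for v in vecs]
        )
        return (pred - obs) / err

    # initial isotropic guess from the mean ratio via a 1-D search over tau_c
    mean_ratio = float(np.mean(obs))

    def ratio_miss(tau_ns):
        t = DiffusionTensor.isotropic(1.0 / (6.0 * tau_ns * 1e-9))
        return (
            _predicted_ratio(t, np.array([0.0, 0.0, 1.0]), field_mhz, rnh, csa)
            - mean_ratio
        ) ** 2

    tau0 = minimize_scalar(ratio_miss, bounds=(1.0, 40.0), method="bounded").x
    d0 = 1.0 / (6.0 * tau0 * 1e-9)
    sol_iso = least_squares(iso_resid, [math.log(d0)], xtol=1e-14, ftol=1e-14)
    d_iso_fit = math.exp(sol_iso.x[0])
    chi2_iso = float(np.sum(sol_iso.fun**2))

    def axial_resid(x):
        log_d, log_rho, th, ph = x
        d_iso = math.exp(log_d)
        rho = math.exp(log_rho)          # Dpar/Dperp
        d_perp = 3.0 * d_iso / (rho + 2.0)
        t = DiffusionTensor.axial(rho * d_perp, d_perp, (th, ph))
        pred = np.array(
            [_predicted_ratio(t, v, field_mhz, rnh, csa) for v in vecs]
        )
        return (pred - obs) / err

    best = None
    for th0, ph0 in [(0.5, 0.5), (1.2, 2.0), (2.0, 4.0), (0.9, 5.5)]:
        sol = least_squares(
            axial_resid,
            [math.log(d_iso_fit), 0.0, th0, ph0],
            xtol=1e-14, ftol=1e-14,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    log_d, log_rho, th, ph = best.x
    d_iso = math.exp(log_d)
    rho = math.exp(log_rho)
    d_perp = 3.0 * d_iso / (rho + 2.0)
    tensor_ax = DiffusionTensor.axial(
        rho * d_perp, d_perp, (th % math.pi, ph % (2 * math.pi))
    )
    return DiffusionFit(
        isotropic=DiffusionTensor.isotropic(d_iso_fit),
        chi2_isotropic=chi2_iso,
        axial=tensor_ax,
        chi2_axial=float(np.sum(best.fun**2)),
        n_residues=len(common),
    )


# ---------------------------------------------------------------------------
# model-free fitting

#: model id -> free parameter names (S2f only in the extended model 5)
MODELFREE_MODELS = {
    1: ("s2",),
    2: ("s2", "tau_e"),
    3: ("s2", "rex"),
    4: ("s2", "tau_e", "rex"),
    5: ("s2f", "s2", "tau_e"),
}

TAU_E_MAX = 5e-9   # s; internal motion must be faster than overall tumbling
REX_MAX = 100.0    # /s


@dataclass
class ModelFreeParams:
    """Selected model-free model and parameters for one residue."""

    residue: ResidueID
    model: int
    s2: float
    tau_e: float = 0.0
    rex: float = 0.0
    s2f: float = 1.0
    chi2: float = 0.0
    s2_err: float = 0.0
    tau_e_err: float = 0.0
    rex_err: float = 0.0
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.s2 <= 1.0 + 1e-9):
            raise ValueError("S2 must lie in [0, 1]")
        if self.tau_e < 0 or self.rex < 0:
            raise ValueError("tau_e and Rex must be >= 0")


def _unpack(model: int, x: np.ndarray) -> tuple[float, float, float, float]:
    """(s2, tau_e [s], rex, s2f) from the fit-unit vector of a model.

    tau_e is carried in ns inside the optimizer so that all free parameters
    are of order unity.
    """
    if model == 1:
        return x[0], 0.0, 0.0, 1.0
    if model == 2:
        return x[0], x[1] * 1e-9, 0.0, 1.0
    if model == 3:
        return x[0], 0.0, x[1], 1.0
    if model == 4:
        return x[0], x[1] * 1e-9, x[2], 1.0
    # model 5: parametrized as (s2f, s2s, tau_e) so that s2 = s2f*s2s <= s2f
    return x[0] * x[1], x[2] * 1e-9, 0.0, x[0]


_TAU_NS_MAX = TAU_E_MAX * 1e9
_S2_STARTS = (0.5, 0.85)
_TAU_STARTS = (0.02, 0.2, 1.0)
_REX_STARTS = (1.0, 5.0)
_X0 = {
    1: [[s] for s in _S2_STARTS],
    2: [[s, t] for s in _S2_STARTS for t in _TAU_STARTS],
    3: [[s, r] for s in _S2_STARTS for r in _REX_STARTS],
    4: [[s, t, r] for s in _S2_STARTS for t in _TAU_STARTS
        for r in _REX_STARTS],
    5: [[0.9, s, t] for s in _S2_STARTS for t in _TAU_STARTS],
}
_BOUNDS = {
    1: ([0.0], [1.0]),
    2: ([0.0, 0.0], [1.0, _TAU_NS_MAX]),
    3: ([0.0, 0.0], [1.0, REX_MAX]),
    4: ([0.0, 0.0, 0.0], [1.0, _TAU_NS_MAX, REX_MAX]),
    5: ([0.0, 0.0, 0.0], [1.0, 1.0, _TAU_NS_MAX]),
}


def _residual_builder(
    datasets: list[tuple[float, np.ndarray, np.ndarray]],
    tensor: DiffusionTensor,
    nh: np.ndarray,
    rnh: float,
    csa: float,
    field_ref: float,
):
    """datasets: list of (field_mhz, obs[R1,R2,NOE], err[3])."""

    def residuals(x, model):
        s2, tau_e, rex, s2f = _unpack(model, x)
        out = []
        for field_mhz, obs, err in datasets:
            rex_f = rex * (field_mhz / field_ref) ** 2
            p = predict_rates(
                tensor, nh, field_mhz, s2=s2, tau_e=tau_e, rex=rex_f,
                s2f=s2f, rnh=rnh, csa=csa,
            )
            pred = np.array([p["R1"], p["R2"], p["NOE"]])
            out.append((pred - obs) / err)
        return np.concatenate(out)

    return residuals


def fit_modelfree(
    records: list[RelaxationRecord],
    tensor: DiffusionTensor,
    nh_vectors: dict[ResidueID, np.ndarray],
    n_mc: int = 200,
    seed: int | None = None,
    rnh: float = RNH_DEFAULT,
    csa: float = CSA_DEFAULT,
    chi2_reject: float = 11.34,
) -> list[ModelFreeParams]:
    """Fit model-free models 1-5 per residue against a fixed tensor.

    Model selection uses the corrected Akaike information criterion; when
    the AICc small-sample correction is undefined for any candidate
    (k >= n-1, the usual situation with single-field data), plain AIC is
    used for all models of that residue.  Parameter errors come from
    ``n_mc`` seeded Monte-Carlo redraws of the data within their errors.
    A residue whose best chi-square still exceeds ``chi2_reject`` is
    flagged, with the best model reported regardless.
    """
    rng = np.random.default_rng(seed)
    by_res: dict[ResidueID, list[RelaxationRecord]] = {}
    for r in records:
        if r.r1 is None or r.r2 is None or r.noe is None:
            continue
        by_res.setdefault(r.residue, []).append(r)
    field_ref = max((r.field_mhz for r in records), default=600.0)

    results: list[ModelFreeParams] = []
    for rid in sorted(by_res):
        if rid not in nh_vectors:
            continue
        recs = by_res[rid]
        datasets = []
        for r in recs:
            obs = np.array([r.r1, r.r2, r.noe])
            err = np.array(
                [r.r1_err or 0.0, r.r2_err or 0.0, r.noe_err or 0.0]
            )
            # floor the weights: degenerate (noise-free) error estimates
            # otherwise produce pathological conditioning
            err = np.maximum(err, np.maximum(1e-4, 1e-6 * np.abs(obs)))
            datasets.append((r.field_mhz, obs, err))
        n_data = 3 * len(datasets)
        residuals = _residual_builder(
            datasets, tensor, nh_vectors[rid], rnh, csa, field_ref
        )
        use_aicc = all(n_data - k - 1 > 0 for k in (1, 2, 3))

        fits: dict[int, tuple[np.ndarray, float, float]] = {}
        for model, names in MODELFREE_MODELS.items():
            k = len(names)
            if k > n_data:
                continue
            best_x, best_chi2 = None, np.inf
            for x0 in _X0[model]:
                sol = least_squares(
                    residuals, x0, bounds=_BOUNDS[model], args=(model,),
                    xtol=1e-15, ftol=1e-15, gtol=1e-15,
                )
                chi2 = float(np.sum(sol.fun**2))
                if chi2 < best_chi2:
                    best_x, best_chi2 = sol.x, chi2
            ic = best_chi2 + 2.0 * k
            if use_aicc:
                ic += 2.0 * k * (k + 1) / (n_data - k - 1)
            fits[model] = (best_x, best_chi2, ic)
        best_model = min(fits, key=lambda m: (fits[m][2], m))
        x, chi2, _ = fits[best_model]
        s2, tau_e, rex, s2f = _unpack(best_model, x)
        params = ModelFreeParams(
            rid, best_model, min(s2, 1.0), tau_e, rex, s2f, chi2=chi2
        )
        if s2 >= 1.0 - 1e-6:
            params.flags.append("boundary")
        if chi2 > chi2_reject:
            params.flags.append("rejected")

        if n_mc > 0:
            draws = {"s2": [], "tau_e": [], "rex": []}
            for _ in range(n_mc):
                noisy = []
                for field_mhz, obs, err in datasets:
                    noisy.append((field_mhz, obs + rng.normal(0, err), err))
                res_mc = _residual_builder(
                    noisy, tensor, nh_vectors[rid], rnh, csa, field_ref
                )
                sol = least_squares(
                    res_mc, x, bounds=_BOUNDS[best_model], args=(best_model,),
                    xtol=1e-10, ftol=1e-10,
                )
                s2m, tem, rxm, _ = _unpack(best_model, sol.x)
                draws["s2"].append(s2m)
                draws["tau_e"].append(tem)
                draws["rex"].append(rxm)
            params.s2_err = float(np.std(draws["s2"]))
            params.tau_e_err = float(np.std(draws["tau_e"]))
            params.rex_err = float(np.std(draws["rex"]))
        results.append(params)
    return results
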