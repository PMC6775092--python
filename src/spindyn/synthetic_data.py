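"""Seeded synthetic datasets with the statistical structure of each stage.

Every generator is bit-deterministic under (seed, parameters) and emulates
the acquisition scheme of the corresponding experiment: 11-point inversion
recovery (80-1200 ms) and 10-point spin lock (10-100 ms) delay grids with
3 duplicates each, two-field constant-time CPMG schedules (17 points,
T = 48 ms, 41.7-2000 Hz at 600 MHz; 14 points, T = 40 ms, 50-1000 Hz at
800 MHz) with a 2% error floor and duplicates at the lowest/median/highest
frequency, the seven-point H/D exchange time course (0.3-17.9 h), and
ideal-geometry backbone fragments built to a prescribed torsion script.

Default ground-truth regimes follow the system under study: an oblate
axially symmetric diffusion tensor with eigenvalues 1.39e7 and 1.30e7 /s
(tau_iso = 12.3 ns), two-state exchange with kex = 847/s and pB = 1.63%,
and protection factors spanning 1e2 to 3e4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from spindyn.cpmg_dispersion import (
    ERROR_FLOOR,
    CPMGSchedule,
    DispersionProfile,
    simulate_bm,
)
from spindyn.diffusion_modelfree import DiffusionTensor, predict_rates
from spindyn.io_tables import IntensityDecaySeries, ResidueID, StructureEnsemble

# delay grids (s); 11 inversion-recovery and 10 spin-lock delays
IR_DELAYS = np.linspace(0.08, 1.2, 11)
SPINLOCK_DELAYS = np.linspace(0.010, 0.100, 10)
#: which delays are acquired twice (first, middle, last of each grid)
DUPLICATE_PICKS = (0, None, -1)   # None -> middle index

# H/D exchange HSQC start times after reconstitution in D2O (hours)
HDX_HOURS = np.array([0.3, 1.6, 2.8, 5.4, 7.9, 12.9, 17.9])

TENSOR_DEFAULT = DiffusionTensor.axial(d_par=1.30e7, d_perp=1.39e7)

KEX_DEFAULT = 847.0
PB_DEFAULT = 0.0163
CPMG_FIELDS = (600.0, 800.0)


def _even_log_blocks(n_min: int, n_max: int, count: int) -> np.ndarray:
    """Distinct even block counts, approximately log-spaced."""
    targets = np.geomspace(n_min, n_max, count)
    picks: list[int] = []
    prev = 0
    for t in targets:
        n = max(prev + 2, int(2 * round(t / 2.0)))
        picks.append(n)
        prev = n
    # if the greedy walk overshot the ceiling, re-pack the tail downwards
    picks[-1] = min(picks[-1], n_max)
    for i in range(len(picks) - 2, -1, -1):
        picks[i] = min(picks[i], picks[i + 1] - 2)
    return np.array(picks, dtype=int)


def cpmg_schedule_600() -> CPMGSchedule:
    """17-point schedule, T = 48 ms, 41.7 Hz to 2000 Hz (snapped valid)."""
    t = 0.048
    blocks = _even_log_blocks(2, 96, 17)
    nu = blocks / t
    return CPMGSchedule(600.0, t, nu,
                        duplicates=(nu[0], nu[len(nu) // 2], nu[-1]))


def cpmg_schedule_800() -> CPMGSchedule:
    """14-point schedule, T = 40 ms, 50 Hz to 1000 Hz."""
    t = 0.040
    blocks = _even_log_blocks(2, 40, 14)
    nu = blocks / t
    return CPMGSchedule(800.0, t, nu,
                        duplicates=(nu[0], nu[len(nu) // 2], nu[-1]))


def _dup_indices(n: int) -> list[int]:
    return [i if i is not None else n // 2 for i in DUPLICATE_PICKS]


@dataclass
class RelaxationTruth:
    """Per-residue model-free truth plus the shared diffusion tensor."""

    tensor: DiffusionTensor
    params: dict[ResidueID, tuple[float, float, float]]   # (S2, tau_e, Rex)
    nh_vectors: dict[ResidueID, np.ndarray]
    field_mhz: float = 800.0


@dataclass
class ExchangeTruth:
    """Global two-state exchange truth with per-residue dw and R2,0."""

    kex: float
    pb: float
    dw_ppm: dict[ResidueID, float]
    r20: dict[tuple[int, float], float]   # (residue number, field) -> /s


@dataclass
class HDXTruth:
    """Per-residue protection factor and intrinsic exchange rate (/h)."""

    pf: dict[ResidueID, float]
    k_int: dict[ResidueID, float]


@dataclass
class GroundTruth:
    """Complete seeded truth for an end-to-end synthetic dataset."""

    seed: int
    relaxation: RelaxationTruth
    exchange: ExchangeTruth
    hdx: HDXTruth
    torsion_script: list[tuple[float, float]] = dc_field(default_factory=list)


def default_relaxation_truth(
    seed: int,
    n_residues: int = 40,
    tensor: DiffusionTensor = TENSOR_DEFAULT,
    field_mhz: float = 800.0,
) -> RelaxationTruth:
    """Rigid-core-dominated truth: most residues S2 ~ 0.85-0.95, a mobile
    tail with low S2 (and hence low NOE), and a few residues with Rex."""
    rng = np.random.default_rng(seed)
    params: dict[ResidueID, tuple[float, float, float]] = {}
    nh: dict[ResidueID, np.ndarray] = {}
    for i in range(n_residues):
        rid = ResidueID(20 + i, "A")
        if i < n_residues - 8:
            s2 = float(rng.uniform(0.82, 0.95))
            tau_e = float(rng.uniform(10e-12, 50e-12))
            rex = 0.0
        elif i < n_residues - 4:
            s2 = float(rng.uniform(0.82, 0.92))
            tau_e = float(rng.uniform(20e-12, 80e-12))
            rex = float(rng.uniform(3.0, 8.0))
        else:  # mobile tail
            s2 = float(rng.uniform(0.3, 0.5))
            tau_e = float(rng.uniform(0.5e-9, 1.5e-9))
            rex = 0.0
        params[rid] = (s2, tau_e, rex)
        v = rng.normal(size=3)
        nh[rid] = v / np.linalg.norm(v)
    return RelaxationTruth(tensor, params, nh, field_mhz)


def default_exchange_truth(
    seed: int,
    n_residues: int = 57,
    kex: float = KEX_DEFAULT,
    pb: float = PB_DEFAULT,
    dw_range: tuple[float, float] = (0.5, 6.0),
    r20_range: tuple[float, float] = (8.0, 20.0),
    fields: tuple[float, ...] = CPMG_FIELDS,
) -> ExchangeTruth:
    """Two-state truth at the study regime: 57 dispersing residues with
    |dw| uniform on 0.5-6 ppm and field-specific R2,0 uniform on 8-20/s."""
    rng = np.random.default_rng(seed)
    dw: dict[ResidueID, float] = {}
    r20: dict[tuple[int, float], float] = {}
    for i in range(n_residues):
        rid = ResidueID(20 + i, "A")
        dw[rid] = float(rng.uniform(*dw_range))
        for f in fields:
            r20[(rid.number, f)] = float(rng.uniform(*r20_range))
    return ExchangeTruth(kex, pb, dw, r20)


def default_hdx_truth(seed: int, n_per_stratum: int = 4) -> HDXTruth:
    """Protection factors spanning the observable strata.

    Low-PF residues (PF ~ 10) paired with fast intrinsic rates exchange
    away before the first HSQC (too fast); mid-PF residues (1e2-1e4) decay
    measurably over the series; very high PF (3e4) gives no significant
    decay (lower bound).
    """
    rng = np.random.default_rng(seed)
    pf: dict[ResidueID, float] = {}
    k_int: dict[ResidueID, float] = {}
    num = 20
    for _ in range(n_per_stratum):          # too fast
        rid = ResidueID(num, "A"); num += 1
        pf[rid] = float(rng.uniform(5, 20))
        k_int[rid] = float(rng.uniform(500, 2000))
    for _ in range(n_per_stratum):          # quantifiable, moderate
        rid = ResidueID(num, "A"); num += 1
        pf[rid] = float(rng.uniform(2e2, 2e3))
        k_int[rid] = float(rng.uniform(50, 500))
    for _ in range(n_per_stratum):          # quantifiable, high
        rid = ResidueID(num, "A"); num += 1
        pf[rid] = float(rng.uniform(2e3, 1e4))
        k_int[rid] = float(rng.uniform(500, 2000))
    for _ in range(n_per_stratum):          # lower bound only
        rid = ResidueID(num, "A"); num += 1
        pf[rid] = 3e4
        k_int[rid] = float(rng.uniform(20, 80))
    return HDXTruth(pf, k_int)


def default_ground_truth(seed: int) -> GroundTruth:
    """Seeded end-to-end truth covering all pipeline stages."""
    return GroundTruth(
        seed=seed,
        relaxation=default_relaxation_truth(seed),
        exchange=default_exchange_truth(seed + 1),
        hdx=default_hdx_truth(seed + 2),
        torsion_script=[(-75.0, 120.0)] * 5,
    )


# ---------------------------------------------------------------------------
# generators

def gen_relaxation_dataset(
    truth: RelaxationTruth,
    noise_pct: float = 2.0,
    seed: int = 0,
    i_eq: float = 100.0,
):
    """Inversion-recovery and spin-lock series plus NOE pairs.

    Rates are forward-predicted from the truth; decays are sampled on the
    11-point/10-point grids with the three duplicate delays, and i.i.d.
    Gaussian noise of ``noise_pct`` percent of the equilibrium intensity is
    added.  Spin-lock decays are generated on resonance (R1rho = R2).
    Returns (ir_series, sl_series, noe_pairs, true_rates).
    """
    if noise_pct < 0:
        raise ValueError("noise_pct must be >= 0")
    rng = np.random.default_rng(seed)
    sd = noise_pct / 100.0 * i_eq
    ir_out: list[IntensityDecaySeries] = []
    sl_out: list[IntensityDecaySeries] = []
    noe_pairs: dict[ResidueID, tuple[float, float, float]] = {}
    true_rates: dict[ResidueID, dict[str, float]] = {}

    ir_t = np.concatenate([IR_DELAYS, IR_DELAYS[_dup_indices(IR_DELAYS.size)]])
    sl_t = np.concatenate(
        [SPINLOCK_DELAYS, SPINLOCK_DELAYS[_dup_indices(SPINLOCK_DELAYS.size)]]
    )
    for rid in sorted(truth.params):
        s2, tau_e, rex = truth.params[rid]
        rates = predict_rates(
            truth.tensor, truth.nh_vectors[rid], truth.field_mhz,
            s2=s2, tau_e=tau_e, rex=rex,
        )
        true_rates[rid] = rates
        ir_i = i_eq - 2.0 * i_eq * np.exp(-rates["R1"] * ir_t)
        ir_i = ir_i + rng.normal(0.0, sd, ir_i.shape) if sd > 0 else ir_i
        sigmas = np.full_like(ir_t, sd) if sd > 0 else None
        ir_out.append(IntensityDecaySeries(rid, ir_t, ir_i, sigmas))
        sl_i = i_eq * np.exp(-rates["R2"] * sl_t)
        sl_i = sl_i + rng.normal(0.0, sd, sl_i.shape) if sd > 0 else sl_i
        sigmas = np.full_like(sl_t, sd) if sd > 0 else None
        sl_out.append(IntensityDecaySeries(rid, sl_t, sl_i, sigmas))
        i_ref = i_eq + (rng.normal(0.0, sd) if sd > 0 else 0.0)
        i_sat = rates["NOE"] * i_eq + (rng.normal(0.0, sd) if sd > 0 else 0.0)
        noe_pairs[rid] = (i_sat, i_ref, sd)
    return ir_out, sl_out, noe_pairs, true_rates


def gen_dispersion_dataset(
    truth: ExchangeTruth,
    seed: int = 0,
    schedules: tuple[CPMGSchedule, ...] | None = None,
    noise_floor: float = ERROR_FLOOR,
) -> list[DispersionProfile]:
    """Two-field R2,eff profiles from the two-state truth.

    Profiles are simulated by Bloch-McConnell propagation, perturbed with
    Gaussian noise at the relative ``noise_floor``, and the schedule's
    duplicate frequencies are appended as second observations so the
    duplicate-based error estimator applies downstream.
    """
    if schedules is None:
        schedules = (cpmg_schedule_600(), cpmg_schedule_800())
    rng = np.random.default_rng(seed)
    profiles: list[DispersionProfile] = []
    for rid in sorted(truth.dw_ppm):
        for sched in schedules:
            key = (rid.number, sched.field_mhz)
            if key not in truth.r20:
                continue
            clean = simulate_bm(
                truth.kex, truth.pb, truth.dw_ppm[rid], truth.r20[key], sched
            )
            dup_idx = [int(np.argmin(np.abs(sched.nu_hz - d)))
                       for d in sched.duplicates]
            nu = np.concatenate([sched.nu_hz, sched.nu_hz[dup_idx]])
            vals = np.concatenate([clean, clean[dup_idx]])
            if noise_floor > 0:
                vals = vals + rng.normal(0.0, noise_floor * np.abs(vals))
            profiles.append(DispersionProfile(rid, sched, nu, vals))
    return profiles


def gen_hdx_dataset(
    truth: HDXTruth,
    seed: int = 0,
    timepoints: np.ndarray = HDX_HOURS,
    noise_pct: float = 2.0,
    i0: float = 100.0,
) -> list[IntensityDecaySeries]:
    """H/D decay series on the seven-point time course.

    k_ex = k_int/PF per residue; intensities decay from ``i0`` with
    seeded Gaussian noise of ``noise_pct`` percent of ``i0``.
    """
    rng = np.random.default_rng(seed)
    sd = noise_pct / 100.0 * i0
    out: list[IntensityDecaySeries] = []
    for rid in sorted(truth.pf):
        k_ex = truth.k_int[rid] / truth.pf[rid]
        vals = i0 * np.exp(-k_ex * timepoints)
        if sd > 0:
            vals = vals + rng.normal(0.0, sd, vals.shape)
        sig = np.full_like(timepoints, sd) if sd > 0 else None
        out.append(IntensityDecaySeries(rid, timepoints, vals, sig))
    return out


# ---------------------------------------------------------------------------
# ideal-geometry backbone builder

# standard backbone bond lengths (A) and angles (deg)
_B_N_CA = 1.458
_B_CA_C = 1.525
_B_C_N = 1.329
_B_C_O = 1.231
_A_C_N_CA = 121.7
_A_N_CA_C = 111.2
_A_CA_C_N = 116.2
_A_CA_C_O = 120.5
_OMEGA = 180.0


def _place(a, b, c, r, theta_deg, chi_deg):
    """Position atom D given A-B-C, bond r (C-D), angle B-C-D, torsion
    A-B-C-D (natural extension reference frame)."""
    theta = math.radians(theta_deg)
    chi = math.radians(chi_deg + 180.0)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-r * math.cos(theta), r * math.sin(theta) * math.cos(chi),
         r * math.sin(theta) * math.sin(chi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def gen_backbone_fragment(
    torsion_script: list[tuple[float, float]],
    sequence: str | None = None,
    first_residue: int = 1,
) -> StructureEnsemble:
    """Build an ideal-geometry backbone chain realizing a torsion script.

    ``torsion_script`` lists (Phi, Psi) in degrees per residue; the first
    residue's Phi and the peptide-plane omega (fixed at 180 deg) are the
    only torsions not taken from the script.  Atoms N, CA, C, O are built
    per residue with standard bond lengths and angles; the realized
    torsions match the script to well under 0.1 degree.
    """
    n_res = len(torsion_script)
    if n_res < 1:
        raise ValueError("empty torsion script")
    seq = sequence or "A" * n_res
    if len(seq) != n_res:
        raise ValueError("sequence length must match torsion script")

    coords: dict[tuple[int, str], np.ndarray] = {}
    # seed residue frame
    coords[(0, "N")] = np.array([0.0, 0.0, 0.0])
    coords[(0, "CA")] = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(180.0 - _A_N_CA_C)
    coords[(0, "C")] = coords[(0, "CA")] + _B_CA_C * np.array(
        [math.cos(ang), math.sin(ang), 0.0]
    )
    for i in range(1, n_res):
        psi_prev = torsion_script[i - 1][1]
        coords[(i, "N")] = _place(
            coords[(i - 1, "N")], coords[(i - 1, "CA")], coords[(i - 1, "C")],
            _B_C_N, _A_CA_C_N, psi_prev,
        )
        coords[(i, "CA")] = _place(
            coords[(i - 1, "CA")], coords[(i - 1, "C")], coords[(i, "N")],
            _B_N_CA, _A_C_N_CA, _OMEGA,
        )
        coords[(i, "C")] = _place(
            coords[(i - 1, "C")], coords[(i, "N")], coords[(i, "CA")],
            _B_CA_C, _A_N_CA_C, torsion_script[i][0],
        )
    for i in range(n_res):
        coords[(i, "O")] = _place(
            coords[(i, "N")], coords[(i, "CA")], coords[(i, "C")],
            _B_C_O, _A_CA_C_O, torsion_script[i][1] - 180.0,
        )
    atoms = []
    xyz = []
    for i in range(n_res):
        rid = ResidueID(first_residue + i, seq[i])
        for name, element in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
            atoms.append((rid, name, element))
            xyz.append(coords[(i, name)])
    return StructureEnsemble(atoms=atoms, coords=np.array(xyz)[None, :, :])
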