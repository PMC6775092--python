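"""NMR restraint generation rules and ensemble/torsion geometry.

Covers the bookkeeping and geometry conventions of NMR structure
determination: NOE distance-restraint classification by sequence
separation, hydrogen-bond restraint pairs, the Karplus relation between
3J(HN-Ha) and the backbone Phi torsion (with its inverse), backbone Phi/Psi
torsions of a coordinate ensemble, polyproline-II run detection, and
atomic RMSD to the iteratively superposed mean structure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from spindyn.io_tables import ResidueID, StructureEnsemble

logger = logging.getLogger(__name__)

# hydrogen-bond restraint bounds (Angstrom): amide proton -> acceptor and
# amide nitrogen -> acceptor
HBOND_H_BOUNDS = (1.5, 2.3)
HBOND_N_BOUNDS = (2.5, 3.5)

# Karplus coefficients for 3J(HN-Ha)(Phi), Hz (quantitative HNHA calibration)
KARPLUS_DEFAULT = (6.51, -1.76, 1.60)

#: 3J value indicative of rotameric averaging; couplings too close to it
#: are not converted into torsion restraints
J_ROTAMERIC = 7.0
J_GUARD_BAND = 1.0      # Hz, minimum distance from J_ROTAMERIC
PHI_TOLERANCE = 30.0    # degrees, tolerance of Karplus-derived restraints

# canonical polyproline-II torsions (degrees)
PPII_PHI = -75.0
PPII_PSI = 120.0
PPII_WINDOW = 25.0
PPII_MIN_RUN = 3

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class DistanceRestraint:
    """Upper/lower distance bound between two atoms.

    Atom references are (ResidueID, atom name).  ``klass`` is one of
    intraresidual / sequential / medium / long / ambiguous / hbond.
    """

    atom1: tuple[ResidueID, str]
    atom2: tuple[ResidueID, str]
    lower: float
    upper: float
    klass: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.lower < self.upper):
            raise ValueError("need 0 < lower < upper")


@dataclass
class DihedralRestraint:
    """Backbone torsion restraint: center +/- tolerance in degrees."""

    residue: ResidueID
    angle: str                  # "phi" | "psi"
    center: float
    tolerance: float
    source: str = "karplus"

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if not (-180.0 < self.center <= 180.0):
            raise ValueError("center must lie in (-180, 180]")


@dataclass
class TorsionSet:
    """Per-residue Phi/Psi torsions (degrees) per ensemble model.

    ``phi``/``psi`` map residue number -> array over models (NaN where the
    torsion is undefined: chain termini or missing atoms).
    """

    phi: dict[int, np.ndarray]
    psi: dict[int, np.ndarray]
    n_models: int


def classify_noe(i: int, j: int, ambiguous: bool = False) -> str:
    """Sequence-separation class of an NOE between residues i and j.

    intraresidual (i = j), sequential (|i-j| = 1), medium (1 < |i-j| < 5),
    long (|i-j| >= 5).  Ambiguous restraints are classified ``ambiguous``
    regardless of separation.
    """
    if ambiguous:
        return "ambiguous"
    sep = abs(i - j)
    if sep == 0:
        return "intraresidual"
    if sep == 1:
        return "sequential"
    if sep < 5:
        return "medium"
    return "long"


def count_noe_classes(
    restraints: list[DistanceRestraint],
) -> dict[str, int]:
    """Tally restraints per class; total is the sum of all rows."""
    counts = {
        "intraresidual": 0, "sequential": 0, "medium": 0,
        "long": 0, "ambiguous": 0,
    }
    for r in restraints:
        counts[r.klass] = counts.get(r.klass, 0) + 1
    counts["total"] = len(restraints)
    return counts


def hbonds_to_restraints(
    hbonds: list[tuple[ResidueID, tuple[ResidueID, str]]],
) -> list[DistanceRestraint]:
    """Two distance restraints per hydrogen bond.

    Each bond is (donor residue, (acceptor residue, acceptor atom)); the
    donor contributes its backbone amide HN and N.  The amide proton to
    acceptor distance is restrained to 1.5-2.3 A, the amide nitrogen to
    acceptor distance to 2.5-3.5 A.
    """
    out: list[DistanceRestraint] = []
    for donor, acceptor in hbonds:
        acc_res, acc_atom = acceptor
        if not acc_atom:
            raise ValueError(f"hydrogen bond {donor} -> {acc_res}: "
                             "acceptor atom not resolvable")
        out.append(
            DistanceRestraint((donor, "HN"), (acc_res, acc_atom),
                              *HBOND_H_BOUNDS, klass="hbond")
        )
        out.append(
            DistanceRestraint((donor, "N"), (acc_res, acc_atom),
                              *HBOND_N_BOUNDS, klass="hbond")
        )
    return out


def karplus_j(
    phi_deg: float, coefficients: tuple[float, float, float] = KARPLUS_DEFAULT
) -> float:
    """3J(HN-Ha) from the backbone Phi torsion.

    J = A cos^2(Phi - 60) + B cos(Phi - 60) + C with coefficients in Hz.
    """
    a, b, c = coefficients
    x = math.cos(math.radians(phi_deg - 60.0))
    return a * x * x + b * x + c


def _wrap_deg(angle: float) -> float:
    """Wrap an angle into (-180, 180]."""
    a = (angle + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def phi_candidates(
    j_hz: float, coefficients: tuple[float, float, float] = KARPLUS_DEFAULT
) -> list[float]:
    """All Phi solutions in (-180, 180] of the Karplus relation for a J.

    Solves the quadratic in cos(Phi - 60); roots outside [-1, 1] are
    discarded.  An unattainable J yields an empty list.
    """
    a, b, c = coefficients
    disc = b * b - 4.0 * a * (c - j_hz)
    if disc < 0:
        logger.info("J = %.2f Hz outside the attainable Karplus range", j_hz)
        return []
    roots = [(-b + s * math.sqrt(disc)) / (2.0 * a) for s in (+1.0, -1.0)]
    out: set[float] = set()
    for x in roots:
        if -1.0 <= x <= 1.0:
            theta = math.degrees(math.acos(x))
            for sign in (+1.0, -1.0):
                out.add(round(_wrap_deg(60.0 + sign * theta), 9))
    return sorted(out)


def j_to_phi_restraint(
    residue: ResidueID,
    j_hz: float,
    j_err: float,
    coefficients: tuple[float, float, float] = KARPLUS_DEFAULT,
) -> DihedralRestraint | None:
    """Convert a 3J(HN-Ha) coupling into a Phi restraint, or exclude it.

    Couplings within max(1.0 Hz, 2*err) of 7.0 Hz are indicative of
    rotameric averaging and excluded (returns None, with a log entry).
    Otherwise the restraint is centered on the beta-region Karplus solution
    (nearest -120 deg) for J > 7 Hz or the alpha-region solution (nearest
    -60 deg) for J < 7 Hz, with a +/-30 deg tolerance.
    """
    guard = max(J_GUARD_BAND, 2.0 * j_err)
    if abs(j_hz - J_ROTAMERIC) <= guard:
        logger.info("%s: J = %.2f Hz within %.2f Hz of %.1f Hz -> excluded "
                    "(rotameric averaging)", residue, j_hz, guard, J_ROTAMERIC)
        return None
    cands = phi_candidates(j_hz, coefficients)
    if not cands:
        return None
    target = -120.0 if j_hz > J_ROTAMERIC else -60.0
    center = min(cands, key=lambda p: abs(_wrap_deg(p - target)))
    return DihedralRestraint(residue, "phi", _wrap_deg(center), PHI_TOLERANCE)


# ---------------------------------------------------------------------------
# torsions and ensemble geometry

def _dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees for four points."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return math.degrees(math.atan2(y, x))


def backbone_torsions(ensemble: StructureEnsemble) -> TorsionSet:
    """Phi/Psi torsions for every residue and model of an ensemble.

    Phi(i) = C(i-1)-N(i)-CA(i)-C(i); Psi(i) = N(i)-CA(i)-C(i)-N(i+1).
    Chain breaks (non-consecutive numbering) and missing atoms yield NaN.
    """
    idx = ensemble.atom_index()
    residues = sorted({rid.number for rid, _, _ in ensemble.atoms})
    nm = ensemble.n_models
    phi = {r: np.full(nm, np.nan) for r in residues}
    psi = {r: np.full(nm, np.nan) for r in residues}

    def pos(m: int, res: int, name: str):
        i = idx.get((res, name))
        return ensemble.coords[m, i] if i is not None else None

    for m in range(nm):
        for r in residues:
            n_i = pos(m, r, "N")
            ca_i = pos(m, r, "CA")
            c_i = pos(m, r, "C")
            c_prev = pos(m, r - 1, "C") if (r - 1) in phi else None
            n_next = pos(m, r + 1, "N") if (r + 1) in phi else None
            if all(p is not None for p in (c_prev, n_i, ca_i, c_i)):
                phi[r][m] = _dihedral(c_prev, n_i, ca_i, c_i)
            if all(p is not None for p in (n_i, ca_i, c_i, n_next)):
                psi[r][m] = _dihedral(n_i, ca_i, c_i, n_next)
    return TorsionSet(phi=phi, psi=psi, n_models=nm)


def detect_ppii(
    torsions: TorsionSet,
    window: float = PPII_WINDOW,
    min_run: int = PPII_MIN_RUN,
) -> list[tuple[int, int]]:
    """Maximal runs of residues in polyproline-II geometry.

    A residue qualifies when both Phi and Psi lie within ``window`` degrees
    of (-75, +120) in at least half of the ensemble models.  Returns
    (first, last) residue numbers of every maximal run of length >=
    ``min_run``.
    """
    residues = sorted(torsions.phi)
    ok: dict[int, bool] = {}
    for r in residues:
        dphi = np.abs([_wrap_deg(a - PPII_PHI) for a in torsions.phi[r]])
        dpsi = np.abs([_wrap_deg(a - PPII_PSI) for a in torsions.psi[r]])
        good = (~np.isnan(torsions.phi[r]) & ~np.isnan(torsions.psi[r])
                & (dphi <= window) & (dpsi <= window))
        ok[r] = bool(np.sum(good) * 2 >= torsions.n_models)
    runs: list[tuple[int, int]] = []
    start = None
    prev = None
    for r in residues:
        if ok[r] and (start is not None) and (r == prev + 1):
            prev = r
        elif ok[r]:
            if start is not None and prev - start + 1 >= min_run:
                runs.append((start, prev))
            start, prev = r, r
        else:
            if start is not None and prev - start + 1 >= min_run:
                runs.append((start, prev))
            start = None
    if start is not None and prev - start + 1 >= min_run:
        runs.append((start, prev))
    return runs


def _kabsch(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Rotation matrix superposing centered p onto centered q."""
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    return vt.T @ np.diag([1.0, 1.0, d]) @ u.T


def superpose_ensemble(
    coords: np.ndarray, tol: float = 1e-4, max_iter: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Iteratively superpose models on their converged mean.

    Returns (superposed coords, mean).  Iterates superposition onto the
    mean and mean recomputation until the mean moves by less than ``tol``
    Angstrom RMS.
    """
    work = coords - coords.mean(axis=1, keepdims=True)
    mean = work[0].copy()
    for _ in range(max_iter):
        for m in range(work.shape[0]):
            rot = _kabsch(work[m], mean)
            work[m] = work[m] @ rot.T
        new_mean = work.mean(axis=0)
        shift = float(np.sqrt(np.mean((new_mean - mean) ** 2)))
        mean = new_mean
        if shift < tol:
            break
    return work, mean


def ensemble_rmsd(
    ensemble: StructureEnsemble,
    residue_range: tuple[int, int] | None = None,
    atom_set: str = "backbone",
) -> tuple[float, float]:
    """Mean +/- sd of per-model RMSD to the converged average structure.

    ``atom_set`` selects backbone atoms (N, CA, C, O) or all heavy
    (non-hydrogen) atoms; ``residue_range`` is an inclusive (first, last)
    author-numbering interval, or None for all residues.
    """
    if ensemble.n_models < 2:
        raise ValueError("need >= 2 models for an ensemble RMSD")
    cols = []
    for i, (rid, name, element) in enumerate(ensemble.atoms):
        if residue_range is not None and not (
            residue_range[0] <= rid.number <= residue_range[1]
        ):
            continue
        if atom_set == "backbone":
            if name in BACKBONE_ATOMS:
                cols.append(i)
        elif atom_set == "heavy":
            if element.upper() != "H":
                cols.append(i)
        else:
            raise ValueError(f"unknown atom_set {atom_set!r}")
    if not cols:
        raise ValueError("empty atom selection")
    sel = ensemble.coords[:, cols, :]
    sup, mean = superpose_ensemble(sel)
    per_model = np.sqrt(np.mean(np.sum((sup - mean) ** 2, axis=2), axis=1))
    return float(np.mean(per_model)), float(np.std(per_model, ddof=1))


def write_cns_distance_tbl(
    restraints: list[DistanceRestraint], path
) -> None:
    """Write distance restraints in CNS .tbl assign syntax."""
    lines = []
    for r in restraints:
        (r1, a1), (r2, a2) = r.atom1, r.atom2
        d = r.upper
        dminus = r.upper - r.lower
        lines.append(
            f"assign (resid {r1.number:4d} and name {a1:<4s}) "
            f"(resid {r2.number:4d} and name {a2:<4s}) "
            f"{d:6.2f} {dminus:5.2f} {0.0:5.2f} ! {r.klass}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
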