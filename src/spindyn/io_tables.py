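"""Tabular and coordinate I/O.

All experimental observables enter the pipeline as delimited text tables
(residue / time / intensity / optional sigma) and coordinate ensembles enter
as multi-model PDB files.  Author residue numbering is preserved verbatim;
cloning artifacts commonly occupy non-positive positions (e.g. Gly at -1,
Ser at 0), so residue numbers may be <= 0 everywhere in this package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AA1 = set("ACDEFGHIKLMNPQRSTVWYX")

AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1TO3 = {v: k for k, v in AA3TO1.items()}


class TableFormatError(ValueError):
    """Input table does not conform to the expected schema."""


class TableValidationError(ValueError):
    """Input table parses but violates a physical constraint."""


class EnsembleStructureError(ValueError):
    """Coordinate ensemble violates the shared-atom-list contract."""


@dataclass(frozen=True)
class ResidueID:
    """Sequence position in author numbering plus one-letter residue type.

    Identity (equality, hashing, ordering) is by ``number`` alone: the
    amino-acid code is annotation, and different tables for the same
    residue may or may not carry it.
    """

    number: int
    aa: str = "X"

    def __post_init__(self) -> None:
        if self.aa not in AA1:
            raise ValueError(f"unknown amino-acid code {self.aa!r}")

    def __eq__(self, other) -> bool:
        if not isinstance(other, ResidueID):
            return NotImplemented
        return self.number == other.number

    def __lt__(self, other: "ResidueID") -> bool:
        return self.number < other.number

    def __hash__(self) -> int:
        return hash(self.number)

    def __str__(self) -> str:  # e.g. "A20", "G-1"
        return f"{self.aa}{self.number}"


@dataclass
class IntensityDecaySeries:
    """Timed peak intensities for one residue.

    ``times`` are stored sorted ascending with duplicate time points kept as
    independent observations; ``duplicates`` maps each repeated time value to
    its multiplicity.  Units of ``times`` are whatever the experiment used
    (seconds for relaxation delays, hours for H/D exchange) -- the fitted
    rate comes out in the reciprocal unit.
    """

    residue: ResidueID
    times: np.ndarray
    intensities: np.ndarray
    sigmas: np.ndarray | None = None
    duplicates: dict[float, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise TableValidationError(
                f"{self.residue}: {self.times.size} times vs "
                f"{self.intensities.size} intensities"
            )
        if np.any(self.times < 0):
            raise TableValidationError(f"{self.residue}: negative time points")
        order = np.argsort(self.times, kind="stable")
        self.times = self.times[order]
        self.intensities = self.intensities[order]
        if self.sigmas is not None:
            self.sigmas = np.asarray(self.sigmas, dtype=float)[order]
            if np.any(self.sigmas <= 0):
                raise TableValidationError(f"{self.residue}: sigmas must be > 0")
        uniq, counts = np.unique(self.times, return_counts=True)
        self.duplicates = {float(t): int(c) for t, c in zip(uniq, counts) if c > 1}

    @property
    def n_distinct_times(self) -> int:
        return int(np.unique(self.times).size)


@dataclass
class StructureEnsemble:
    """Multi-model coordinate set with a shared atom list.

    ``atoms`` is a list of (ResidueID, atom name, element); ``coords`` has
    shape (n_models, n_atoms, 3) in Angstrom.
    """

    atoms: list[tuple[ResidueID, str, str]]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise EnsembleStructureError("coords must have shape (models, atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise EnsembleStructureError(
                f"{len(self.atoms)} atoms but coords for {self.coords.shape[1]}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise EnsembleStructureError("non-finite coordinates")

    @property
    def n_models(self) -> int:
        return int(self.coords.shape[0])

    def atom_index(self) -> dict[tuple[int, str], int]:
        """Map (residue number, atom name) -> column index."""
        return {(rid.number, name): i for i, (rid, name, _) in enumerate(self.atoms)}

    def residues(self) -> list[ResidueID]:
        seen: dict[int, ResidueID] = {}
        for rid, _, _ in self.atoms:
            seen.setdefault(rid.number, rid)
        return [seen[k] for k in sorted(seen)]


DEFAULT_SCHEMA = {
    "residue": "residue",
    "aa": "aa",
    "time": "time",
    "intensity": "intensity",
    "sigma": "sigma",
}


def _read_delimited(path: str | Path) -> pd.DataFrame:
    # sep=None lets pandas sniff tab vs comma; both are accepted.
    return pd.read_csv(path, sep=None, engine="python", comment="#")


def read_intensity_table(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> list[IntensityDecaySeries]:
    """Read a long-format intensity table into per-residue decay series.

    The table must contain residue, time and intensity columns (names
    resolved through ``schema``); a sigma column and a one-letter amino-acid
    column are optional.  Rows sharing a residue and time are kept as
    duplicate observations, never averaged.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = _read_delimited(path)
    if df.empty:
        logger.warning("intensity table %s is empty", path)
        return []
    for key in ("residue", "time", "intensity"):
        if schema[key] not in df.columns:
            raise TableFormatError(
                f"{path}: missing required column {schema[key]!r} "
                f"(have {list(df.columns)})"
            )
    if (df[schema["time"]] < 0).any():
        raise TableValidationError(f"{path}: negative time values")
    has_sigma = schema["sigma"] in df.columns
    has_aa = schema["aa"] in df.columns
    out: list[IntensityDecaySeries] = []
    for num, grp in df.groupby(schema["residue"], sort=True):
        aa = str(grp[schema["aa"]].iloc[0]) if has_aa else "X"
        rid = ResidueID(int(num), aa)
        sig = grp[schema["sigma"]].to_numpy(float) if has_sigma else None
        out.append(
            IntensityDecaySeries(
                residue=rid,
                times=grp[schema["time"]].to_numpy(float),
                intensities=grp[schema["intensity"]].to_numpy(float),
                sigmas=sig,
            )
        )
    return out


def read_pdb_ensemble(path: str | Path) -> StructureEnsemble:
    """Parse a (multi-)MODEL PDB file into a StructureEnsemble.

    Residue numbers are taken verbatim (non-positive numbers allowed).  All
    models must present the same atoms in the same order; a mismatch raises
    ``EnsembleStructureError`` naming the offending model.  Alternate
    locations are resolved to the highest-occupancy conformer (first
    encountered on ties).
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise EnsembleStructureError(f"{path}: no models")

    def model_atoms(model: gemmi.Model):
        atoms: list[tuple[ResidueID, str, str]] = []
        xyz: list[tuple[float, float, float]] = []
        for chain in model:
            for res in chain:
                aa = AA3TO1.get(res.name.strip().upper(), "X")
                rid = ResidueID(res.seqid.num, aa)
                best: dict[str, gemmi.Atom] = {}
                for atom in res:
                    prev = best.get(atom.name)
                    if prev is None or atom.occ > prev.occ:
                        best[atom.name] = atom
                for name, atom in best.items():
                    atoms.append((rid, name, atom.element.name))
                    xyz.append((atom.pos.x, atom.pos.y, atom.pos.z))
        return atoms, np.array(xyz, dtype=float)

    ref_atoms, ref_xyz = model_atoms(st[0])
    coords = [ref_xyz]
    for i, model in enumerate(st):
        if i == 0:
            continue
        atoms, xyz = model_atoms(model)
        if len(atoms) != len(ref_atoms):
            raise EnsembleStructureError(
                f"{path}: MODEL {i + 1} has {len(atoms)} atoms, "
                f"MODEL 1 has {len(ref_atoms)}"
            )
        if [(r.number, n) for r, n, _ in atoms] != [
            (r.number, n) for r, n, _ in ref_atoms
        ]:
            raise EnsembleStructureError(f"{path}: MODEL {i + 1} atom order differs")
        coords.append(xyz)
    return StructureEnsemble(atoms=ref_atoms, coords=np.stack(coords))


def write_pdb_ensemble(ensemble: StructureEnsemble, path: str | Path) -> None:
    """Write an ensemble as a standard multi-MODEL PDB file."""
    lines: list[str] = []
    for m in range(ensemble.n_models):
        lines.append(f"MODEL     {m + 1:4d}")
        serial = 1
        for (rid, name, element), (x, y, z) in zip(
            ensemble.atoms, ensemble.coords[m]
        ):
            res3 = AA1TO3.get(rid.aa, "UNK")
            nm = name if len(name) == 4 else f" {name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {nm:<4s}{res3:>3s} A{rid.number:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{element:>2s}"
            )
            serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_report(
    records: pd.DataFrame | Sequence[Mapping] | Iterable[Mapping],
    path: str | Path,
    float_format: str = "%.6g",
) -> None:
    """Write a flat result table as deterministic tab-separated text.

    Column order follows the DataFrame (or first record); floats are printed
    at fixed precision so that two runs on identical inputs produce
    byte-identical files suitable for diffing.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(list(records))
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def read_report(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_report`."""
    return pd.read_csv(path, sep="\t")
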