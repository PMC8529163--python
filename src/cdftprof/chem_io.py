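"""Readers, writers and unit handling for the formats the pipeline touches.

Species tables are delimited text (comma or tab, header row, UTF-8) carrying
frontier-orbital and optional total energies for the neutral molecule and its
radical ions.  Volumetric electron densities travel in the de-facto standard
cube format (bohr lengths, z-fastest value ordering).  The canonical energy
unit everywhere downstream is eV; conversion from hartree happens only here,
at the I/O boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HARTREE_TO_EV",
    "SchemaError",
    "ParseError",
    "SpeciesRecord",
    "SpeciesTriplet",
    "DensityGrid",
    "ev_to_hartree",
    "hartree_to_ev",
    "read_species_table",
    "write_species_table",
    "group_triplets",
    "read_cube",
    "write_cube",
]

#: CODATA 2018 hartree -> electronvolt conversion.
HARTREE_TO_EV = 27.211386245988


class SchemaError(ValueError):
    """A table is missing a required column or carries an invalid schema."""


class ParseError(ValueError):
    """A file's contents could not be interpreted (bad number, truncation)."""


def hartree_to_ev(e_hartree: float) -> float:
    return e_hartree * HARTREE_TO_EV


def ev_to_hartree(e_ev: float) -> float:
    return e_ev / HARTREE_TO_EV


@dataclass(frozen=True)
class SpeciesRecord:
    """One molecule in one charge state.

    Energies are in eV.  ``eps_homo``/``eps_lumo`` are the frontier-orbital
    energies; ``e_total`` is the ground-state total energy (optional, needed
    only for ΔSCF and KID checks).  ``source`` is free text recording where
    the numbers came from (level of theory, solvation, ...).
    """

    ligand_id: str
    charge: int
    multiplicity: int = 1
    eps_homo: Optional[float] = None
    eps_lumo: Optional[float] = None
    e_total: Optional[float] = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.multiplicity < 1:
            raise ValueError(
                f"{self.ligand_id}: multiplicity must be >= 1, got {self.multiplicity}"
            )
        for name in ("eps_homo", "eps_lumo", "e_total"):
            v = getattr(self, name)
            if v is not None and not math.isfinite(v):
                raise ValueError(f"{self.ligand_id}: {name} is not finite")
        if self.eps_homo is not None and self.eps_lumo is not None:
            if not self.eps_homo < self.eps_lumo:
                raise ValueError(
                    f"{self.ligand_id}: eps_homo ({self.eps_homo}) must lie below "
                    f"eps_lumo ({self.eps_lumo})"
                )


@dataclass(frozen=True)
class SpeciesTriplet:
    """Neutral molecule plus its vertical radical cation and anion."""

    neutral: SpeciesRecord
    cation: SpeciesRecord
    anion: SpeciesRecord

    def __post_init__(self) -> None:
        ids = {self.neutral.ligand_id, self.cation.ligand_id, self.anion.ligand_id}
        if len(ids) != 1:
            raise ValueError(f"triplet mixes ligands: {sorted(ids)}")
        charges = (self.neutral.charge, self.cation.charge, self.anion.charge)
        if charges != (0, 1, -1):
            raise ValueError(
                f"{self.neutral.ligand_id}: triplet charges must be (0, +1, -1), got {charges}"
            )

    @property
    def ligand_id(self) -> str:
        return self.neutral.ligand_id


@dataclass
class DensityGrid:
    """Scalar field on a regular 3-D lattice (cube-file semantics).

    ``origin`` and the rows of ``axes`` (one voxel step per grid axis) are in
    bohr; ``values`` has shape ``shape`` and is in electrons/bohr^3 for
    densities (Fukui grids are signed and dimensionally the same).
    """

    origin: np.ndarray
    axes: np.ndarray
    values: np.ndarray
    atoms: list[tuple[int, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3-D, got ndim={self.values.ndim}")
        if any(n < 2 for n in self.values.shape):
            raise ValueError(f"every grid dimension must be >= 2, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid values contain non-finite entries")
        if np.linalg.det(self.axes) <= 0:
            raise ValueError("voxel step matrix must have positive determinant")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in bohr^3."""
        return float(np.linalg.det(self.axes))

    def same_geometry(self, other: "DensityGrid", atol: float = 1e-6) -> list[str]:
        """Names of geometric fields on which the two grids differ."""
        bad = []
        if self.shape != other.shape:
            bad.append("shape")
        if not np.allclose(self.origin, other.origin, atol=atol):
            bad.append("origin")
        if not np.allclose(self.axes, other.axes, atol=atol):
            bad.append("axes")
        return bad

    def copy_with(self, values: np.ndarray) -> "DensityGrid":
        return replace(self, values=np.asarray(values, dtype=float), atoms=list(self.atoms))


# ---------------------------------------------------------------------------
# species tables
# ---------------------------------------------------------------------------

_REQUIRED = ("ligand_id", "charge", "eps_homo", "eps_lumo")
_OPTIONAL_NUMERIC = ("e_total",)


def read_species_table(path: str | Path, units: str = "ev") -> list[SpeciesRecord]:
    """Read a delimited species table; energies converted to eV on the way in.

    Parameters
    ----------
    path
        Comma- or tab-delimited file with a header row.  Required columns:
        ``ligand_id, charge, eps_homo, eps_lumo``; recognised optional ones:
        ``multiplicity, e_total, source``.
    units
        ``"ev"`` or ``"hartree"`` — the unit of every energy column in the
        file.  Hartree values are converted with the CODATA 2018 factor.
    """
    if units not in ("ev", "hartree"):
        raise ValueError(f"units must be 'ev' or 'hartree', got {units!r}")
    df = pd.read_csv(path, sep=None, engine="python", encoding="utf-8",
                     skipinitialspace=True)
    for col in _REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")

    factor = HARTREE_TO_EV if units == "hartree" else 1.0
    records: list[SpeciesRecord] = []
    for i, row in df.iterrows():
        rowno = int(i) + 2  # header is line 1
        energies: dict[str, Optional[float]] = {}
        for col in ("eps_homo", "eps_lumo", *_OPTIONAL_NUMERIC):
            if col not in df.columns or pd.isna(row[col]):
                energies[col] = None
                continue
            try:
                energies[col] = float(row[col]) * factor
            except (TypeError, ValueError) as exc:
                raise ParseError(
                    f"{path}: row {rowno}: non-numeric value {row[col]!r} in {col}"
                ) from exc
        try:
            charge = int(row["charge"])
        except (TypeError, ValueError) as exc:
            raise ParseError(
                f"{path}: row {rowno}: non-integer charge {row['charge']!r}"
            ) from exc
        mult = 1
        if "multiplicity" in df.columns and not pd.isna(row["multiplicity"]):
            mult = int(row["multiplicity"])
        source = ""
        if "source" in df.columns and not pd.isna(row["source"]):
            source = str(row["source"])
        records.append(
            SpeciesRecord(
                ligand_id=str(row["ligand_id"]),
                charge=charge,
                multiplicity=mult,
                eps_homo=energies["eps_homo"],
                eps_lumo=energies["eps_lumo"],
                e_total=energies["e_total"],
                source=source,
            )
        )
    return records


def write_species_table(records: Sequence[SpeciesRecord], path: str | Path) -> None:
    """Write records as a comma-delimited table in eV (the canonical unit)."""
    rows = [
        {
            "ligand_id": r.ligand_id,
            "charge": r.charge,
            "multiplicity": r.multiplicity,
            "eps_homo": r.eps_homo,
            "eps_lumo": r.eps_lumo,
            "e_total": r.e_total,
            "source": r.source,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10f")


def group_triplets(records: Sequence[SpeciesRecord]) -> list[SpeciesTriplet]:
    """Assemble (neutral, cation, anion) triplets from a flat record list.

    Ligands lacking any of the three charge states are skipped; a ligand with
    duplicate charge states is an error.
    """
    by_ligand: dict[str, dict[int, SpeciesRecord]] = {}
    for r in records:
        slot = by_ligand.setdefault(r.ligand_id, {})
        if r.charge in slot:
            raise SchemaError(f"{r.ligand_id}: duplicate charge state {r.charge}")
        slot[r.charge] = r
    triplets = []
    for lig in sorted(by_ligand):
        slot = by_ligand[lig]
        if {0, 1, -1} <= set(slot):
            triplets.append(SpeciesTriplet(neutral=slot[0], cation=slot[1], anion=slot[-1]))
    return triplets


# ---------------------------------------------------------------------------
# cube files
# ---------------------------------------------------------------------------

def read_cube(path: str | Path) -> DensityGrid:
    """Parse a standard cube file (bohr units, z-fastest value ordering)."""
    with open(path, "r", encoding="utf-8") as fh:
        tokens_after_header: list[str] = []
        fh.readline()  # two comment lines
        fh.readline()
        natoms_line = fh.readline().split()
        if len(natoms_line) < 4:
            raise ParseError(f"{path}: malformed atom-count/origin line")
        natoms = int(natoms_line[0])
        if natoms < 0:
            raise ParseError(f"{path}: negative atom counts (angstrom dialect) unsupported")
        origin = np.array([float(x) for x in natoms_line[1:4]])
        shape = []
        axes = []
        for _ in range(3):
            parts = fh.readline().split()
            if len(parts) < 4:
                raise ParseError(f"{path}: malformed voxel line")
            n = int(parts[0])
            if n <= 0:
                raise ParseError(f"{path}: non-positive voxel count {n}")
            shape.append(n)
            axes.append([float(x) for x in parts[1:4]])
        atoms: list[tuple[int, np.ndarray]] = []
        for _ in range(natoms):
            parts = fh.readline().split()
            if len(parts) < 5:
                raise ParseError(f"{path}: malformed atom line")
            atoms.append((int(parts[0]), np.array([float(x) for x in parts[2:5]])))
        for line in fh:
            tokens_after_header.extend(line.split())

    expected = shape[0] * shape[1] * shape[2]
    if len(tokens_after_header) != expected:
        raise ParseError(
            f"{path}: expected {expected} values, found {len(tokens_after_header)}"
        )
    try:
        values = np.array([float(t) for t in tokens_after_header])
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric entry in value block") from exc
    return DensityGrid(
        origin=origin,
        axes=np.array(axes),
        values=values.reshape(shape),  # z varies fastest in file order
        atoms=atoms,
    )


def write_cube(grid: DensityGrid, path: str | Path, comment: str = "cdftprof grid") -> None:
    """Write a grid in cube format (<= 6 values per line, %13.6E)."""
    if grid.voxel_volume <= 0:
        raise ValueError("refusing to write grid with non-positive voxel volume")
    nx, ny, nz = grid.shape
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{comment}\n")
        fh.write("scalar field, bohr, z-fastest\n")
        fh.write(
            f"{len(grid.atoms):5d}{grid.origin[0]:12.6f}{grid.origin[1]:12.6f}"
            f"{grid.origin[2]:12.6f}\n"
        )
        for n, ax in zip((nx, ny, nz), grid.axes):
            fh.write(f"{n:5d}{ax[0]:12.6f}{ax[1]:12.6f}{ax[2]:12.6f}\n")
        for z, pos in grid.atoms:
            fh.write(f"{z:5d}{float(z):12.6f}{pos[0]:12.6f}{pos[1]:12.6f}{pos[2]:12.6f}\n")
        flat = grid.values.reshape(-1)  # C order: z fastest
        for start in range(0, flat.size, 6):
            chunk = flat[start:start + 6]
            # width 14 keeps a separator in front of negative values
            fh.write("".join(f"{v:14.6E}" for v in chunk) + "\n")
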