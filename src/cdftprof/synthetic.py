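"""Seeded synthetic generators for every input the pipeline consumes.

Each generator constructs data whose properties are known by construction,
so downstream stages have an exact oracle:

* species triplets whose total energies satisfy E(N-1) = E(N) + I and
  E(N+1) = E(N) - A with eps_HOMO = -I, eps_LUMO = -A, making the KID
  deviations exactly zero (a controllable perturbation injects known error);
* atom-centered isotropic-Gaussian electron densities, each normalized to an
  assigned electron count, with the N±1 species redistributing exactly one
  electron, so Fukui-function integrals are known analytically;
* ADMET tables drawn from uniform ranges that straddle each rule threshold,
  so both verdict branches occur;
* noisy four-parameter-logistic dose-response curves with known IC50 and
  Hill slope.

Everything is a pure function of its arguments and the seed; re-running with
the same seed is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .assay import DoseResponse, four_pl
from .chem_io import DensityGrid, SpeciesRecord, SpeciesTriplet
from .pharma import ADMET_BOOLEAN

__all__ = [
    "PAPER_LIGAND_IA",
    "GaussianAtom",
    "DensityTripletSpec",
    "gen_species",
    "gen_density_triplet",
    "gen_admet_table",
    "gen_dose_response",
]

#: Vertical (I, A) pairs, in eV, implied by the published descriptor panel of
#: the five Acorus calamus phytoligands (I = chi + eta/2, A = chi - eta/2).
PAPER_LIGAND_IA: dict[str, tuple[float, float]] = {
    "S-Adenosylhomocysteine": (6.02405, 1.75535),
    "Carbenicillin": (6.68370, 1.05990),
    "Apiin": (6.42815, 1.80545),
    "Rutine": (6.19380, 2.07540),
    "Chloramphenicol Monoglucoronide": (7.32745, 3.08875),
}


def gen_species(
    ligands: Optional[dict[str, tuple[float, float]]] = None,
    seed: int = 0,
    cation_shift_ev: float = 0.0,
    anion_shift_ev: float = 0.0,
) -> list[SpeciesTriplet]:
    """Generate KID-consistent species triplets for the given (I, A) map.

    With both shifts at zero the triplets satisfy the Koopmans/ΔSCF identity
    exactly: ``kid_check`` returns j_i = j_a = 0.  A nonzero
    ``cation_shift_ev`` adds that amount to E(N-1) (so j_i equals the shift),
    and ``anion_shift_ev`` likewise perturbs E(N+1).
    """
    if ligands is None:
        ligands = PAPER_LIGAND_IA
    rng = np.random.default_rng(seed)
    triplets = []
    for lig in sorted(ligands):
        I, A = ligands[lig]
        if not I > A:
            raise ValueError(f"{lig}: require I > A, got I={I}, A={A}")
        e_n = -100.0 - 50.0 * rng.random()  # arbitrary reference total energy, eV
        src = f"synthetic seed={seed}"
        neutral = SpeciesRecord(ligand_id=lig, charge=0, multiplicity=1,
                                eps_homo=-I, eps_lumo=-A, e_total=e_n, source=src)
        cation = SpeciesRecord(ligand_id=lig, charge=1, multiplicity=2,
                               e_total=e_n + I + cation_shift_ev, source=src)
        anion = SpeciesRecord(ligand_id=lig, charge=-1, multiplicity=2,
                              e_total=e_n - A + anion_shift_ev, source=src)
        triplets.append(SpeciesTriplet(neutral=neutral, cation=cation, anion=anion))
    return triplets


@dataclass(frozen=True)
class GaussianAtom:
    """One density center: position (bohr), width sigma (bohr), electron count."""

    center: tuple[float, float, float]
    sigma: float
    electrons: float


@dataclass(frozen=True)
class DensityTripletSpec:
    """Geometry and electron bookkeeping for a synthetic density triplet.

    ``anion_delta[k]`` electrons are added to atom k in the N+1 species
    (must sum to 1); ``cation_delta[k]`` are removed in the N-1 species
    (must sum to 1).
    """

    atoms: tuple[GaussianAtom, ...]
    anion_delta: tuple[float, ...]
    cation_delta: tuple[float, ...]
    shape: tuple[int, int, int] = (32, 32, 32)
    box_length: float = 16.0  # bohr, cubic box starting at the origin
    min_padding_sigmas: float = 5.0

    def __post_init__(self) -> None:
        if len(self.anion_delta) != len(self.atoms) or len(self.cation_delta) != len(self.atoms):
            raise ValueError("delta vectors must have one entry per atom")
        if abs(sum(self.anion_delta) - 1.0) > 1e-12:
            raise ValueError("anion_delta must sum to exactly 1 electron")
        if abs(sum(self.cation_delta) - 1.0) > 1e-12:
            raise ValueError("cation_delta must sum to exactly 1 electron")


def _gaussian_sum(points: tuple[np.ndarray, np.ndarray, np.ndarray],
                  atoms: Sequence[GaussianAtom],
                  electrons: Sequence[float]) -> np.ndarray:
    x, y, z = points
    rho = np.zeros(np.broadcast_shapes(x.shape, y.shape, z.shape))
    for atom, q in zip(atoms, electrons):
        if q == 0.0:
            continue
        cx, cy, cz = atom.center
        r2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
        norm = q / ((2.0 * np.pi * atom.sigma**2) ** 1.5)
        rho += norm * np.exp(-r2 / (2.0 * atom.sigma**2))
    return rho


def gen_density_triplet(spec: DensityTripletSpec) -> tuple[DensityGrid, DensityGrid, DensityGrid]:
    """Neutral, cation and anion densities on identical grids.

    Each species is a sum of isotropic Gaussians normalized to its assigned
    electron count.  Refuses to build grids whose box leaves any center less
    than ``min_padding_sigmas`` sigmas from a wall, reporting the padding
    required.
    """
    L = spec.box_length
    for i, atom in enumerate(spec.atoms):
        need = spec.min_padding_sigmas * atom.sigma
        slack = min(min(c, L - c) for c in atom.center)
        if slack < need:
            raise ValueError(
                f"atom {i}: center {atom.center} is {slack:.3f} bohr from the nearest "
                f"wall but needs >= {need:.3f} bohr ({spec.min_padding_sigmas:g} sigma) "
                "of padding; enlarge the box or recentre"
            )
    nx, ny, nz = spec.shape
    xs = np.linspace(0.0, L, nx)
    ys = np.linspace(0.0, L, ny)
    zs = np.linspace(0.0, L, nz)
    grid_pts = np.meshgrid(xs, ys, zs, indexing="ij")
    steps = (L / (nx - 1), L / (ny - 1), L / (nz - 1))
    axes = np.diag(steps)

    q_neutral = [a.electrons for a in spec.atoms]
    q_cation = [a.electrons - d for a, d in zip(spec.atoms, spec.cation_delta)]
    q_anion = [a.electrons + d for a, d in zip(spec.atoms, spec.anion_delta)]
    atoms_meta = [(6, np.asarray(a.center, float)) for a in spec.atoms]

    def build(qs: list[float]) -> DensityGrid:
        return DensityGrid(origin=np.zeros(3), axes=axes,
                           values=_gaussian_sum(grid_pts, spec.atoms, qs),
                           atoms=list(atoms_meta))

    return build(q_neutral), build(q_cation), build(q_anion)


#: Uniform sampling ranges straddling each default rule threshold.
ADMET_RANGES: dict[str, tuple[float, float]] = {
    "caco2": (0.5, 1.3),
    "intestinal_absorption": (0.0, 60.0),
    "skin_logkp": (-3.5, -1.5),
    "vdss": (-2.0, 1.0),
    "fraction_unbound": (0.0, 1.0),
    "bbb_logbb": (-1.5, 0.2),
    "cns_logps": (-6.0, -2.0),
    "total_clearance": (-0.5, 1.0),
    "max_tolerated_dose": (0.0, 2.0),
    "orat_ld50": (1.0, 3.0),
    "orct": (2.0, 6.0),
    "tpyriformis": (-1.5, 0.5),
}


def gen_admet_table(n: int = 50, seed: int = 0,
                    ranges: Optional[dict[str, tuple[float, float]]] = None) -> pd.DataFrame:
    """Synthetic ADMET table with the published column schema.

    Numeric properties are uniform over ranges straddling the default rule
    thresholds; booleans are fair Bernoulli draws written as Yes/No.  The
    frame round-trips through ``pharma.read_admet_table``.
    """
    if ranges is None:
        ranges = ADMET_RANGES
    rng = np.random.default_rng(seed)
    data: dict[str, list] = {"ligand_id": [f"synth-{i + 1:03d}" for i in range(n)]}
    for prop, (lo, hi) in ranges.items():
        data[prop] = list(np.round(rng.uniform(lo, hi, size=n), 4))
    for prop in ADMET_BOOLEAN:
        data[prop] = ["Yes" if b else "No" for b in rng.random(n) < 0.5]
    return pd.DataFrame(data)


def gen_dose_response(
    ic50: float = 22.39,
    hill: float = 1.0,
    top: float = 100.0,
    bottom: float = 0.0,
    doses: Optional[Sequence[float]] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    replicate_id: Optional[str] = None,
) -> DoseResponse:
    """A 4PL dose-response curve with additive Gaussian noise.

    Default parameters emulate the green-synthesized hydroxyapatite
    anti-acetylcholinesterase assay (IC50 near 22.39 µg/mL, full 0-100%
    inhibition window); default doses are eight log-spaced concentrations
    spanning ~3 decades around the IC50.
    """
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if doses is None:
        doses = np.geomspace(ic50 / 30.0, ic50 * 30.0, 8)
    x = np.asarray(list(doses), dtype=float)
    y = four_pl(x, bottom, top, ic50, hill)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=x.size)
    return DoseResponse(concentrations=tuple(float(v) for v in x),
                        inhibition_pct=tuple(float(v) for v in y),
                        replicate_id=replicate_id)
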