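"""Global conceptual-DFT reactivity descriptors.

From a vertical ionization energy I and electron affinity A (either the
Koopmans-type frontier-orbital proxies I = -eps_HOMO, A = -eps_LUMO, or the
ΔSCF total-energy differences) this module computes the standard global
reactivity panel:

    electronegativity        chi   = (I + A) / 2
    chemical hardness        eta   = I - A
    electrophilicity index   omega = chi^2 / (2 eta)
    global softness          S     = 1 / eta
    nucleophilicity          N     = eps_HOMO - eps_HOMO(reference)
    electrodonating power    omega^- = (3I + A)^2 / (16 eta)
    electroaccepting power   omega^+ = (I + 3A)^2 / (16 eta)
    net electrophilicity     Δomega^± = omega^- + omega^+

plus the Domingo strong/moderate/marginal electrophile classification and a
"Koopmans in DFT" (KID) consistency diagnostic, which measures how well the
frontier-orbital energies of a given functional reproduce the ΔSCF I and A.

The nucleophilicity scale is referenced against tetracyanoethylene (TCE),
whose HOMO energy enters as a configurable constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .chem_io import SpeciesRecord, SpeciesTriplet

__all__ = [
    "DEFAULT_TCE_HOMO_EV",
    "DEFAULT_KID_TOL_EV",
    "IonizationData",
    "GlobalDescriptors",
    "KidReport",
    "vertical_ia_koopmans",
    "vertical_ia_delta_scf",
    "global_descriptors",
    "descriptors_to_ia",
    "electrophilicity_class",
    "kid_check",
    "hardness_ranking",
]

#: HOMO energy (eV) of the nucleophilicity reference electrophile.
DEFAULT_TCE_HOMO_EV = -8.7924

#: Default KID pass tolerance (eV) on |J_I| and |J_A|.
DEFAULT_KID_TOL_EV = 0.05


class HardnessError(ValueError):
    """I <= A: the HOMO-LUMO gap is degenerate or inverted."""


@dataclass(frozen=True)
class IonizationData:
    """Vertical ionization energy and electron affinity, in eV."""

    I: float
    A: float
    method: str  # "koopmans" or "delta_scf"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.I) and math.isfinite(self.A)):
            raise ValueError("I and A must be finite")
        if self.I <= self.A:
            raise HardnessError(
                f"I ({self.I:.4f} eV) must exceed A ({self.A:.4f} eV); "
                "hardness would be non-positive"
            )


@dataclass(frozen=True)
class GlobalDescriptors:
    """The eight-descriptor global reactivity panel for one ligand (eV, S in eV^-1)."""

    chi: float
    eta: float
    omega: float
    S: float
    N_nu: float
    omega_minus: float
    omega_plus: float
    net_electrophilicity: float
    ligand_id: str = ""


@dataclass(frozen=True)
class KidReport:
    """KID-protocol consistency deviations for one ligand, in eV.

    ``j_i = |eps_HOMO + E(N-1) - E(N)|`` measures the Koopmans/ΔSCF agreement
    on the ionization side, ``j_a = |eps_LUMO + E(N) - E(N+1)|`` on the
    affinity side, and ``j_hl = sqrt(j_i^2 + j_a^2)`` combines them.
    """

    ligand_id: str
    j_i: float
    j_a: float
    j_hl: float
    passes: bool
    tol_ev: float


def vertical_ia_koopmans(neutral: SpeciesRecord) -> IonizationData:
    """Koopmans-type I = -eps_HOMO, A = -eps_LUMO from the neutral species."""
    if neutral.eps_homo is None or neutral.eps_lumo is None:
        raise ValueError(f"{neutral.ligand_id}: frontier orbital energies required")
    return IonizationData(I=-neutral.eps_homo, A=-neutral.eps_lumo, method="koopmans")


def vertical_ia_delta_scf(triplet: SpeciesTriplet) -> IonizationData:
    """ΔSCF I = E(N-1) - E(N), A = E(N) - E(N+1) from total energies."""
    for name, rec in (("neutral", triplet.neutral), ("cation", triplet.cation),
                      ("anion", triplet.anion)):
        if rec.e_total is None:
            raise ValueError(f"{triplet.ligand_id}: {name} species lacks e_total")
    e_n = triplet.neutral.e_total
    return IonizationData(
        I=triplet.cation.e_total - e_n,  # type: ignore[operator]
        A=e_n - triplet.anion.e_total,   # type: ignore[operator]
        method="delta_scf",
    )


def global_descriptors(
    ia: IonizationData,
    ref_homo_ev: float = DEFAULT_TCE_HOMO_EV,
    ligand_id: str = "",
) -> GlobalDescriptors:
    """Compute the eight-descriptor panel from vertical I and A."""
    I, A = ia.I, ia.A
    eta = I - A
    chi = (I + A) / 2.0
    return GlobalDescriptors(
        chi=chi,
        eta=eta,
        omega=chi * chi / (2.0 * eta),
        S=1.0 / eta,
        N_nu=(-I) - ref_homo_ev,
        omega_minus=(3.0 * I + A) ** 2 / (16.0 * eta),
        omega_plus=(I + 3.0 * A) ** 2 / (16.0 * eta),
        net_electrophilicity=((3.0 * I + A) ** 2 + (I + 3.0 * A) ** 2) / (16.0 * eta),
        ligand_id=ligand_id,
    )


def descriptors_to_ia(gd: GlobalDescriptors) -> IonizationData:
    """Invert the panel: I = chi + eta/2, A = chi - eta/2 (exact)."""
    return IonizationData(I=gd.chi + gd.eta / 2.0, A=gd.chi - gd.eta / 2.0,
                          method="koopmans")


def electrophilicity_class(omega: float) -> str:
    """Domingo electrophilicity class: strong / moderate / marginal.

    Strong for omega > 1.5 eV, moderate for 0.8 < omega <= 1.5 eV, marginal
    below; the boundary values 1.5 and 0.8 fall to the weaker class.
    """
    if not math.isfinite(omega) or omega < 0:
        raise ValueError(f"omega must be finite and non-negative, got {omega}")
    if omega > 1.5:
        return "strong"
    if omega > 0.8:
        return "moderate"
    return "marginal"


def kid_check(triplet: SpeciesTriplet, tol_ev: float = DEFAULT_KID_TOL_EV) -> KidReport:
    """KID-protocol deviations between frontier-orbital and ΔSCF energetics."""
    n = triplet.neutral
    if n.eps_homo is None or n.eps_lumo is None:
        raise ValueError(f"{triplet.ligand_id}: neutral frontier orbital energies required")
    for name, rec in (("neutral", n), ("cation", triplet.cation), ("anion", triplet.anion)):
        if rec.e_total is None:
            raise ValueError(f"{triplet.ligand_id}: {name} species lacks e_total")
    j_i = abs(n.eps_homo + triplet.cation.e_total - n.e_total)   # type: ignore[operator]
    j_a = abs(n.eps_lumo + n.e_total - triplet.anion.e_total)    # type: ignore[operator]
    j_hl = math.hypot(j_i, j_a)
    return KidReport(
        ligand_id=triplet.ligand_id,
        j_i=j_i,
        j_a=j_a,
        j_hl=j_hl,
        passes=(j_i <= tol_ev and j_a <= tol_ev),
        tol_ev=tol_ev,
    )


def hardness_ranking(table: Sequence[GlobalDescriptors]) -> list[GlobalDescriptors]:
    """Ligands by descending hardness (least reactive first); ties alphabetical."""
    if not table:
        raise ValueError("hardness_ranking requires a non-empty table")
    return sorted(table, key=lambda gd: (-gd.eta, gd.ligand_id))
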