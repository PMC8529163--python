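"""Local reactivity descriptors from finite-difference electron densities.

The nucleophilic and electrophilic Fukui functions are voxelwise density
differences between the N-electron molecule and its vertical ions,

    f+(r) = rho_{N+1}(r) - rho_N(r)      (sites prone to nucleophilic attack)
    f-(r) = rho_N(r) - rho_{N-1}(r)      (sites prone to electrophilic attack)

and the dual descriptor Δf(r) = f+(r) - f-(r) separates the two kinds of site
in a single signed field.  Exact normalization (∫f± = 1, ∫Δf = 0) holds in the
continuum; on a finite grid it is recovered up to quadrature error, which the
module measures and reports rather than hides.

Condensed-to-atom variants work on any population analysis' atomic charges:
f_k+ = q_k(N) - q_k(N+1), f_k- = q_k(N-1) - q_k(N).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .chem_io import DensityGrid

__all__ = [
    "QUADRATURE_TOL",
    "GridMismatchError",
    "NormalizationWarning",
    "FukuiGrids",
    "CondensedFukui",
    "DualSignSummary",
    "grid_integral",
    "fukui_from_densities",
    "condensed_fukui",
    "dual_sign_regions",
]

#: Default quadrature tolerance for the f± normalization invariants.
QUADRATURE_TOL = 1e-2


class GridMismatchError(ValueError):
    """The three density grids do not share origin/axes/shape."""


class NormalizationWarning(UserWarning):
    """A Fukui-function integral deviates from its exact continuum value."""


def grid_integral(g: DensityGrid) -> float:
    """Riemann-sum quadrature: sum of values times the voxel volume."""
    return float(g.values.sum() * g.voxel_volume)


@dataclass
class FukuiGrids:
    """f+, f- and dual-descriptor grids plus their measured integrals."""

    f_plus: DensityGrid
    f_minus: DensityGrid
    dual: DensityGrid
    integral_f_plus: float
    integral_f_minus: float
    integral_dual: float


@dataclass
class CondensedFukui:
    """Per-atom condensed Fukui indices and their column sums."""

    f_plus: np.ndarray
    f_minus: np.ndarray
    dual: np.ndarray
    sum_f_plus: float
    sum_f_minus: float
    sum_dual: float


@dataclass
class DualSignSummary:
    """Voxel counts, volumes (bohr^3) and integrated Δf mass by sign region."""

    threshold: float
    n_positive: int
    n_negative: int
    volume_positive: float
    volume_negative: float
    mass_positive: float
    mass_negative: float


def fukui_from_densities(
    rho_n: DensityGrid,
    rho_cation: DensityGrid,
    rho_anion: DensityGrid,
    tol: float = QUADRATURE_TOL,
) -> FukuiGrids:
    """Finite-difference Fukui functions and dual descriptor from N, N±1 densities.

    The three grids must be geometrically identical (origin, axes, shape,
    within 1e-6).  Normalization failures warn with the measured integral —
    truncated real-world cubes legitimately under-integrate — but never abort.
    """
    for name, other in (("cation", rho_cation), ("anion", rho_anion)):
        bad = rho_n.same_geometry(other)
        if bad:
            raise GridMismatchError(
                f"neutral and {name} grids differ in: {', '.join(bad)}"
            )
    f_plus = rho_n.copy_with(rho_anion.values - rho_n.values)
    f_minus = rho_n.copy_with(rho_n.values - rho_cation.values)
    dual = rho_n.copy_with(f_plus.values - f_minus.values)

    ints = {
        "f+": grid_integral(f_plus),
        "f-": grid_integral(f_minus),
    }
    int_dual = grid_integral(dual)
    for name, value in ints.items():
        if abs(value - 1.0) > tol:
            warnings.warn(
                f"∫{name} dr = {value:.6f}, expected 1 ± {tol:g} "
                "(truncated or inconsistent densities?)",
                NormalizationWarning,
                stacklevel=2,
            )
    if abs(int_dual) > 2 * tol:
        warnings.warn(
            f"∫Δf dr = {int_dual:.6f}, expected 0 ± {2 * tol:g}",
            NormalizationWarning,
            stacklevel=2,
        )
    return FukuiGrids(
        f_plus=f_plus,
        f_minus=f_minus,
        dual=dual,
        integral_f_plus=ints["f+"],
        integral_f_minus=ints["f-"],
        integral_dual=int_dual,
    )


def condensed_fukui(
    charges_n: np.ndarray,
    charges_cation: np.ndarray,
    charges_anion: np.ndarray,
    charge_tol: float = 1e-3,
) -> CondensedFukui:
    """Condensed-to-atom Fukui indices from atomic charges of N, N±1 species.

    Works with any population analysis (Mulliken, Hirshfeld, NPA, ...) as long
    as the three charge vectors are consistent: total charges must differ by
    exactly +1 (cation) and -1 (anion) from the neutral, within ``charge_tol``.
    """
    q_n = np.asarray(charges_n, dtype=float)
    q_cat = np.asarray(charges_cation, dtype=float)
    q_an = np.asarray(charges_anion, dtype=float)
    if not (q_n.shape == q_cat.shape == q_an.shape) or q_n.ndim != 1:
        raise ValueError(
            f"charge lists must be 1-D and equal length, got shapes "
            f"{q_n.shape}, {q_cat.shape}, {q_an.shape}"
        )
    d_cat = q_cat.sum() - q_n.sum()
    d_an = q_an.sum() - q_n.sum()
    if abs(d_cat - 1.0) > charge_tol:
        raise ValueError(f"cation total charge must exceed neutral by 1, got Δ={d_cat:.6f}")
    if abs(d_an + 1.0) > charge_tol:
        raise ValueError(f"anion total charge must undercut neutral by 1, got Δ={d_an:.6f}")
    f_plus = q_n - q_an
    f_minus = q_cat - q_n
    dual = f_plus - f_minus
    return CondensedFukui(
        f_plus=f_plus,
        f_minus=f_minus,
        dual=dual,
        sum_f_plus=float(f_plus.sum()),
        sum_f_minus=float(f_minus.sum()),
        sum_dual=float(dual.sum()),
    )


def dual_sign_regions(dual: DensityGrid, threshold: float = 0.0) -> DualSignSummary:
    """Summarise the Δf > +threshold and Δf < -threshold regions of a dual grid."""
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    vol = dual.voxel_volume
    pos = dual.values > threshold
    neg = dual.values < -threshold
    return DualSignSummary(
        threshold=threshold,
        n_positive=int(pos.sum()),
        n_negative=int(neg.sum()),
        volume_positive=float(pos.sum() * vol),
        volume_negative=float(neg.sum() * vol),
        mass_positive=float(dual.values[pos].sum() * vol),
        mass_negative=float(dual.values[neg].sum() * vol),
    )
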