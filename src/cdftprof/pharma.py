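"""Rule-based interpretation of bioactivity, ADMET and docking tables.

Bioactivity scores (Molinspiration-style) partition into active (> 0),
moderately active ([-0.50, 0], inclusive at both ends) and inactive
(< -0.50).  ADMET predictions are interpreted by a data-driven rulebook —
each rule names a property, a comparator and a threshold with verdict text —
so the shipped defaults can be swapped or extended without touching code.
Docking results (binding affinities in kcal/mol, more negative = stronger
predicted binding) get summary analytics: global extremes, best ligand per
protein target, per-ligand means.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

__all__ = [
    "TARGET_CLASSES",
    "BioactivityRecord",
    "AdmetRecord",
    "DockingRecord",
    "Finding",
    "DockingSummary",
    "classify_bioactivity",
    "load_default_rulebook",
    "interpret_admet",
    "docking_summary",
    "read_bioactivity_table",
    "read_admet_table",
    "read_docking_table",
]

#: The six Molinspiration target classes, in canonical order.
TARGET_CLASSES = (
    "gpcr_ligand",
    "ion_channel_modulator",
    "nuclear_receptor_ligand",
    "kinase_inhibitor",
    "protease_inhibitor",
    "enzyme_inhibitor",
)

ADMET_NUMERIC = (
    "caco2", "intestinal_absorption", "skin_logkp", "vdss", "fraction_unbound",
    "bbb_logbb", "cns_logps", "total_clearance", "max_tolerated_dose",
    "orat_ld50", "orct", "tpyriformis",
)
ADMET_BOOLEAN = (
    "pgp_substrate", "pgp1_inhibitor", "pgp2_inhibitor",
    "cyp2d6_substrate", "cyp3a4_substrate", "cyp1a2_inhibitor",
    "cyp2c19_inhibitor", "cyp2c9_inhibitor", "cyp2d6_inhibitor",
    "cyp3a4_inhibitor", "oct2_substrate", "ames", "herg1", "herg2",
    "hepatotoxicity", "skin_sensitisation",
)


@dataclass(frozen=True)
class BioactivityRecord:
    ligand_id: str
    scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in TARGET_CLASSES if c not in self.scores]
        if missing:
            raise ValueError(f"{self.ligand_id}: missing target classes {missing}")
        for k, v in self.scores.items():
            if not math.isfinite(v):
                raise ValueError(f"{self.ligand_id}: non-finite score for {k}")


@dataclass(frozen=True)
class AdmetRecord:
    """One ligand's predicted pharmacokinetic panel (pkCSM-style schema)."""

    ligand_id: str
    numeric: dict[str, float] = field(default_factory=dict)
    flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ia = self.numeric.get("intestinal_absorption")
        if ia is not None and not 0.0 <= ia <= 100.0:
            raise ValueError(
                f"{self.ligand_id}: intestinal_absorption must be in [0, 100], got {ia}"
            )
        for k, v in self.flags.items():
            if not isinstance(v, bool):
                raise ValueError(f"{self.ligand_id}: flag {k} must be boolean, got {v!r}")


@dataclass(frozen=True)
class DockingRecord:
    """One protein-ligand complex from a virtual-screening run."""

    protein_id: str
    ligand_id: str
    affinity: float  # kcal/mol, negative = favorable
    n_hbonds: int
    residues: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not math.isfinite(self.affinity):
            raise ValueError(f"{self.protein_id}/{self.ligand_id}: non-finite affinity")
        if self.n_hbonds < 0:
            raise ValueError(f"{self.protein_id}/{self.ligand_id}: negative H-bond count")


@dataclass(frozen=True)
class Finding:
    """One rule applied to one ADMET property."""

    property: str
    value: object
    rule: str
    verdict: str
    note: str = ""


def classify_bioactivity(score: float) -> str:
    """Partition a bioactivity score: active / moderately_active / inactive.

    Active above 0, moderately active on [-0.50, 0] (both boundaries
    inclusive), inactive below -0.50.  Total on the finite reals.
    """
    if not math.isfinite(score):
        raise ValueError(f"score must be finite, got {score}")
    if score > 0.0:
        return "active"
    if score >= -0.50:
        return "moderately_active"
    return "inactive"


def load_default_rulebook() -> list[dict]:
    """The shipped ADMET rulebook (JSON list of rule dicts)."""
    text = resources.files("cdftprof.data").joinpath("rulebook.json").read_text("utf-8")
    return json.loads(text)


def _apply_threshold(rule: dict, value: float) -> Finding:
    op, thr = rule["op"], rule["threshold"]
    hit = value > thr if op == ">" else value < thr
    verdict = rule["verdict_true"] if hit else rule["verdict_false"]
    note = ""
    margin = rule.get("near_margin")
    if margin is not None and abs(value - thr) <= margin:
        note = f"within {margin:g} of the {thr:g} threshold"
    return Finding(
        property=rule["property"],
        value=value,
        rule=f"{rule['property']} {op} {thr:g}",
        verdict=verdict,
        note=note,
    )


def _apply_band(rule: dict, value: float) -> Finding:
    upper, lower = rule["upper"], rule["lower"]
    if value > upper:
        verdict = rule["verdict_high"]
    elif value < lower:
        verdict = rule["verdict_low"]
    else:
        verdict = rule["verdict_mid"]
    return Finding(
        property=rule["property"],
        value=value,
        rule=f"{rule['property']} banded at ({lower:g}, {upper:g})",
        verdict=verdict,
    )


def interpret_admet(rec: AdmetRecord, rulebook: Optional[list[dict]] = None) -> list[Finding]:
    """Apply every rulebook rule to one record; one finding per rule.

    Missing properties yield a finding with verdict "not evaluated" rather
    than an exception.  Findings are ordered by property name then rule text,
    so output is deterministic.
    """
    if rulebook is None:
        rulebook = load_default_rulebook()
    findings: list[Finding] = []
    for rule in rulebook:
        prop, kind = rule["property"], rule["kind"]
        if kind == "flag":
            value = rec.flags.get(prop)
        else:
            value = rec.numeric.get(prop)
        if value is None:
            findings.append(Finding(prop, None, kind, "not evaluated",
                                    note="property missing from record"))
            continue
        if kind == "threshold":
            findings.append(_apply_threshold(rule, float(value)))
        elif kind == "band":
            findings.append(_apply_band(rule, float(value)))
        elif kind == "flag":
            verdict = rule["verdict_true"] if value else rule["verdict_false"]
            findings.append(Finding(prop, bool(value), "boolean flag", verdict))
        elif kind == "report":
            findings.append(Finding(prop, float(value), "reported without verdict",
                                    rule.get("note", "no stated cutoff")))
        else:
            raise ValueError(f"unknown rule kind {kind!r}")
    findings.sort(key=lambda f: (f.property, f.rule))
    return findings


@dataclass
class DockingSummary:
    n_complexes: int
    best: DockingRecord            # global minimum (most negative) affinity
    weakest: DockingRecord         # global maximum affinity
    best_per_protein: dict[str, DockingRecord]
    mean_affinity_per_ligand: dict[str, float]
    hbond_range: tuple[int, int]


def docking_summary(records: Sequence[DockingRecord]) -> DockingSummary:
    """Summary analytics over a docking-result table.

    Best ligand per protein = most negative affinity; ties broken by more
    hydrogen bonds, then lexicographic ligand name.
    """
    if not records:
        raise ValueError("docking_summary requires at least one record")

    def rank_key(r: DockingRecord) -> tuple:
        return (r.affinity, -r.n_hbonds, r.ligand_id)

    best = min(records, key=rank_key)
    weakest = max(records, key=lambda r: (r.affinity, r.n_hbonds, r.ligand_id))
    per_protein: dict[str, DockingRecord] = {}
    for r in records:
        cur = per_protein.get(r.protein_id)
        if cur is None or rank_key(r) < rank_key(cur):
            per_protein[r.protein_id] = r
    means: dict[str, float] = {}
    for lig in sorted({r.ligand_id for r in records}):
        vals = [r.affinity for r in records if r.ligand_id == lig]
        means[lig] = sum(vals) / len(vals)
    hbonds = [r.n_hbonds for r in records]
    return DockingSummary(
        n_complexes=len(records),
        best=best,
        weakest=weakest,
        best_per_protein=dict(sorted(per_protein.items())),
        mean_affinity_per_ligand=means,
        hbond_range=(min(hbonds), max(hbonds)),
    )


# ---------------------------------------------------------------------------
# table readers
# ---------------------------------------------------------------------------

def read_bioactivity_table(path: str | Path) -> list[BioactivityRecord]:
    """Read a wide bioactivity table: ligand_id + one column per target class."""
    df = pd.read_csv(path, sep=None, engine="python", encoding="utf-8")
    if "ligand_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'ligand_id'")
    return [
        BioactivityRecord(
            ligand_id=str(row["ligand_id"]),
            scores={c: float(row[c]) for c in TARGET_CLASSES if c in df.columns},
        )
        for _, row in df.iterrows()
    ]


_TRUTHY = {"yes", "true", "1"}
_FALSY = {"no", "false", "0"}


def _as_bool(raw: object, where: str) -> bool:
    s = str(raw).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValueError(f"{where}: boolean cell must be Yes/No, got {raw!r}")


def read_admet_table(path: str | Path) -> list[AdmetRecord]:
    """Read a wide ADMET table: ligand_id + numeric and Yes/No columns."""
    df = pd.read_csv(path, sep=None, engine="python", encoding="utf-8")
    if "ligand_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'ligand_id'")
    out = []
    for _, row in df.iterrows():
        lig = str(row["ligand_id"])
        numeric = {c: float(row[c]) for c in ADMET_NUMERIC if c in df.columns and pd.notna(row[c])}
        flags = {c: _as_bool(row[c], f"{lig}/{c}") for c in ADMET_BOOLEAN
                 if c in df.columns and pd.notna(row[c])}
        out.append(AdmetRecord(ligand_id=lig, numeric=numeric, flags=flags))
    return out


def read_docking_table(path: str | Path) -> list[DockingRecord]:
    """Read a docking table: protein_id, ligand_id, affinity, n_hbonds, residues.

    The residues column is ';'-separated residue labels and may be empty.
    """
    df = pd.read_csv(path, sep=None, engine="python", encoding="utf-8")
    required = {"protein_id", "ligand_id", "affinity", "n_hbonds"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        residues: tuple[str, ...] = ()
        if "residues" in df.columns and pd.notna(row["residues"]):
            residues = tuple(s.strip() for s in str(row["residues"]).split(";") if s.strip())
        out.append(
            DockingRecord(
                protein_id=str(row["protein_id"]),
                ligand_id=str(row["ligand_id"]),
                affinity=float(row["affinity"]),
                n_hbonds=int(row["n_hbonds"]),
                residues=residues,
            )
        )
    return out
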