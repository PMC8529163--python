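"""Pipeline orchestration: chain global CDFT → classification → pharma rules
into one deterministic report, renderable as JSON or markdown.

Stages whose inputs are absent are marked "skipped", never fabricated.  The
report serializes losslessly to JSON (timestamps live in a provenance block
that round-trip comparison excludes).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Optional

from . import __version__
from .cdft_global import (DEFAULT_KID_TOL_EV, DEFAULT_TCE_HOMO_EV,
                          electrophilicity_class, global_descriptors, kid_check,
                          vertical_ia_koopmans)
from .chem_io import group_triplets, read_species_table
from .pharma import (classify_bioactivity, docking_summary, interpret_admet,
                     load_default_rulebook, read_admet_table,
                     read_bioactivity_table, read_docking_table)

logger = logging.getLogger("cdftprof")

__all__ = ["PipelineConfig", "ProfileReport", "run_profile", "render_report"]


@dataclass
class PipelineConfig:
    """Inputs and knobs for one profiling run; only species_path is mandatory."""

    species_path: str
    units: str = "ev"
    tce_homo_ev: float = DEFAULT_TCE_HOMO_EV
    kid_tol_ev: float = DEFAULT_KID_TOL_EV
    bioactivity_path: Optional[str] = None
    admet_path: Optional[str] = None
    docking_path: Optional[str] = None
    rulebook_path: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kid_tol_ev <= 0:
            raise ValueError("kid_tol_ev must be positive")

    @classmethod
    def from_json(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = json.load(fh)
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


@dataclass
class ProfileReport:
    """Aggregated pipeline output; every section is plain JSON-able data."""

    descriptors: list[dict] = field(default_factory=list)
    kid_reports: list[dict] = field(default_factory=list)
    bioactivity: list[dict] = field(default_factory=list)
    admet: list[dict] = field(default_factory=list)
    docking: Optional[dict] = None
    skipped: list[str] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ProfileReport":
        return cls(**d)

    def content_hash(self) -> str:
        """Hash of everything except the provenance block (timestamps)."""
        body = self.to_dict()
        body.pop("provenance")
        return hashlib.sha256(
            json.dumps(body, sort_keys=True).encode("utf-8")
        ).hexdigest()


def _descriptor_stage(config: PipelineConfig, report: ProfileReport) -> None:
    records = read_species_table(config.species_path, units=config.units)
    logger.info("species stage: %d records read from %s", len(records), config.species_path)
    neutrals = [r for r in records if r.charge == 0]
    for rec in neutrals:
        if rec.eps_homo is None or rec.eps_lumo is None:
            report.errors.append(f"{rec.ligand_id}: neutral lacks frontier orbital energies")
            continue
        ia = vertical_ia_koopmans(rec)
        gd = global_descriptors(ia, ref_homo_ev=config.tce_homo_ev, ligand_id=rec.ligand_id)
        report.descriptors.append({
            "ligand_id": gd.ligand_id,
            "chi": gd.chi, "eta": gd.eta, "omega": gd.omega, "S": gd.S,
            "N": gd.N_nu, "omega_minus": gd.omega_minus, "omega_plus": gd.omega_plus,
            "net_electrophilicity": gd.net_electrophilicity,
            "electrophilicity_class": electrophilicity_class(gd.omega),
        })
    for triplet in group_triplets(records):
        if any(r.e_total is None for r in (triplet.neutral, triplet.cation, triplet.anion)):
            continue
        kid = kid_check(triplet, tol_ev=config.kid_tol_ev)
        report.kid_reports.append({
            "ligand_id": kid.ligand_id, "j_i": kid.j_i, "j_a": kid.j_a,
            "j_hl": kid.j_hl, "passes": kid.passes, "tol_ev": kid.tol_ev,
        })
    logger.info("descriptor stage: %d panels, %d KID reports",
                len(report.descriptors), len(report.kid_reports))


def run_profile(config: PipelineConfig) -> ProfileReport:
    """Run every stage the config provides inputs for; skip the rest."""
    report = ProfileReport()
    _descriptor_stage(config, report)

    if config.bioactivity_path:
        for rec in read_bioactivity_table(config.bioactivity_path):
            report.bioactivity.append({
                "ligand_id": rec.ligand_id,
                "classes": {k: classify_bioactivity(v) for k, v in sorted(rec.scores.items())},
                "scores": dict(sorted(rec.scores.items())),
            })
    else:
        report.skipped.append("bioactivity")

    if config.admet_path:
        rulebook = None
        if config.rulebook_path:
            with open(config.rulebook_path, "r", encoding="utf-8") as fh:
                rulebook = json.load(fh)
        else:
            rulebook = load_default_rulebook()
        for rec in read_admet_table(config.admet_path):
            findings = interpret_admet(rec, rulebook)
            report.admet.append({
                "ligand_id": rec.ligand_id,
                "findings": [dataclasses.asdict(f) for f in findings],
            })
    else:
        report.skipped.append("admet")

    if config.docking_path:
        summ = docking_summary(read_docking_table(config.docking_path))

        def rec_dict(r):  # JSON-native types only, so reports round-trip
            d = dataclasses.asdict(r)
            d["residues"] = list(d["residues"])
            return d

        report.docking = {
            "n_complexes": summ.n_complexes,
            "best": rec_dict(summ.best),
            "weakest": rec_dict(summ.weakest),
            "best_per_protein": {p: rec_dict(r)
                                 for p, r in summ.best_per_protein.items()},
            "mean_affinity_per_ligand": summ.mean_affinity_per_ligand,
            "hbond_range": list(summ.hbond_range),
        }
    else:
        report.skipped.append("docking")

    report.provenance = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "generated_at": datetime.now(timezone.utc).isoformat(),
    }
    report.provenance["config_hash"] = hashlib.sha256(
        json.dumps(report.provenance["config"], sort_keys=True).encode()).hexdigest()
    return report


_DESCRIPTOR_COLS = ("chi", "eta", "omega", "S", "N", "omega_minus",
                    "omega_plus", "net_electrophilicity")


def _markdown(report: ProfileReport) -> str:
    lines = ["# Reactivity and pharmacokinetics profile", ""]
    lines.append("## Global Reactivity Descriptors")
    if report.descriptors:
        lines.append("| ligand_id | " + " | ".join(_DESCRIPTOR_COLS) + " | class |")
        lines.append("|" + "---|" * (len(_DESCRIPTOR_COLS) + 2))
        for row in report.descriptors:
            cells = " | ".join(f"{row[c]:.4f}" for c in _DESCRIPTOR_COLS)
            lines.append(f"| {row['ligand_id']} | {cells} | {row['electrophilicity_class']} |")
    else:
        lines.append("| skipped |")
    lines.append("")
    if report.kid_reports:
        lines.append("## KID consistency")
        lines.append("| ligand_id | J_I | J_A | J_HL | passes |")
        lines.append("|---|---|---|---|---|")
        for k in report.kid_reports:
            lines.append(f"| {k['ligand_id']} | {k['j_i']:.6f} | {k['j_a']:.6f} "
                         f"| {k['j_hl']:.6f} | {k['passes']} |")
        lines.append("")
    lines.append("## Bioactivity")
    if report.bioactivity:
        classes = sorted(report.bioactivity[0]["classes"])
        lines.append("| ligand_id | " + " | ".join(classes) + " |")
        lines.append("|" + "---|" * (len(classes) + 1))
        for row in report.bioactivity:
            cells = " | ".join(
                f"{row['scores'][c]:+.2f} ({row['classes'][c]})" for c in classes)
            lines.append(f"| {row['ligand_id']} | {cells} |")
    else:
        lines.append("| skipped |")
    lines.append("")
    lines.append("## ADMET findings")
    if report.admet:
        for row in report.admet:
            lines.append(f"### {row['ligand_id']}")
            for f in row["findings"]:
                note = f" ({f['note']})" if f["note"] else ""
                lines.append(f"- {f['property']} = {f['value']}: {f['verdict']}{note}")
            lines.append("")
    else:
        lines.append("| skipped |")
        lines.append("")
    lines.append("## Docking summary")
    if report.docking:
        d = report.docking
        lines.append(f"- complexes: {d['n_complexes']}")
        lines.append(f"- strongest binding: {d['best']['ligand_id']} vs "
                     f"{d['best']['protein_id']} at {d['best']['affinity']} kcal/mol")
        lines.append(f"- weakest binding: {d['weakest']['ligand_id']} vs "
                     f"{d['weakest']['protein_id']} at {d['weakest']['affinity']} kcal/mol")
        lines.append(f"- hydrogen bonds per complex: {d['hbond_range'][0]}-{d['hbond_range'][1]}")
        for prot, rec in d["best_per_protein"].items():
            lines.append(f"- best for {prot}: {rec['ligand_id']} ({rec['affinity']} kcal/mol)")
    else:
        lines.append("| skipped |")
    lines.append("")
    if report.skipped:
        lines.append(f"Skipped stages: {', '.join(report.skipped)}")
        lines.append("")
    return "\n".join(lines)


def render_report(report: ProfileReport, format: str = "json") -> str:
    """Serialize a report as ``json`` or ``markdown``."""
    if format == "json":
        return json.dumps(report.to_dict(), indent=2, sort_keys=True)
    if format == "markdown":
        return _markdown(report)
    raise ValueError(f"unknown format {format!r}; supported: json, markdown")
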