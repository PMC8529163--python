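"""Loaders for the transcribed published tables shipped with the package."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .pharma import (AdmetRecord, BioactivityRecord, DockingRecord,
                     read_admet_table, read_bioactivity_table, read_docking_table)

__all__ = [
    "fixture_path",
    "load_descriptor_reference",
    "load_docking_records",
    "load_bioactivity_records",
    "load_admet_records",
]

_FILES = {
    "docking": "table1_docking.csv",
    "bioactivity": "table2_bioactivity.csv",
    "admet": "table3_admet.csv",
    "descriptors": "table4_descriptors.csv",
    "rulebook": "rulebook.json",
}


def fixture_path(name: str) -> Path:
    """Filesystem path of a shipped fixture: docking, bioactivity, admet,
    descriptors, or rulebook."""
    if name not in _FILES:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(_FILES)}")
    return Path(str(resources.files("cdftprof.data").joinpath(_FILES[name])))


def load_descriptor_reference() -> pd.DataFrame:
    """Published global-descriptor panel (chi, eta, ... per ligand), in eV."""
    return pd.read_csv(fixture_path("descriptors"))


def load_docking_records() -> list[DockingRecord]:
    """The 25 published protein-ligand docking results."""
    return read_docking_table(fixture_path("docking"))


def load_bioactivity_records() -> list[BioactivityRecord]:
    """Published Molinspiration bioactivity scores for the five ligands."""
    return read_bioactivity_table(fixture_path("bioactivity"))


def load_admet_records() -> list[AdmetRecord]:
    """Published pkCSM ADMET panel for the five ligands."""
    return read_admet_table(fixture_path("admet"))
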