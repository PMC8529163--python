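import pytest

from cdftprof.datasets import (load_admet_records, load_bioactivity_records,
                               load_descriptor_reference, load_docking_records)
from cdftprof.synthetic import DensityTripletSpec, GaussianAtom


@pytest.fixture(scope="session")
def descriptor_reference():
    """Published eight-descriptor panel for the five phytoligands."""
    return load_descriptor_reference()


@pytest.fixture(scope="session")
def docking_records():
    return load_docking_records()


@pytest.fixture(scope="session")
def bioactivity_records():
    return load_bioactivity_records()


@pytest.fixture(scope="session")
def admet_records():
    return load_admet_records()


def two_blob_spec(n=32, sigma=0.55, anion_delta=(0.0, 1.0), cation_delta=(1.0, 0.0)):
    """Two Gaussian atoms (6 e- and 4 e-) in a 16-bohr box, N±1 moving one electron."""
    return DensityTripletSpec(
        atoms=(GaussianAtom((6.0, 8.0, 8.0), sigma, 6.0),
               GaussianAtom((10.0, 8.0, 8.0), sigma, 4.0)),
        anion_delta=anion_delta,
        cation_delta=cation_delta,
        shape=(n, n, n),
        box_length=16.0,
    )
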