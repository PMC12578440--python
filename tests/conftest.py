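import numpy as np
import pytest

from rimscreen.synthetic_data import (
    ComplexSpec,
    FrapSpec,
    ImageSpec,
    StructureSpec,
    generate_complex,
    generate_division_image,
    generate_frap_trace,
    generate_pair_structures,
)


@pytest.fixture(scope="session")
def simple_pair():
    """Two-chain model with two planted contacts (one exactly at 4.0 A)
    and a mixed-confidence interface."""
    spec = StructureSpec(
        subunit_a="Spn2",
        subunit_b="Sec15",
        n_res_a=20,
        n_res_b=20,
        planted_contacts=[(3, 5, 3.5), (10, 12, 4.0)],
        plddt_a={3: 70.0, 10: 30.0},
        plddt_b={5: 70.0, 12: 70.0},
        seed=11,
    )
    return generate_pair_structures(spec)


@pytest.fixture(scope="session")
def octamer():
    """Eight-chain complex (2x four subunits) with four buried residues."""
    spec = ComplexSpec(
        subunit_copies={"Spn1": 2, "Spn2": 2, "Spn3": 2, "Spn4": 2},
        residues_per_subunit=10,
        buried=[("A", 3), ("C", 5), ("E", 2), ("G", 7)],
        seed=5,
    )
    return generate_complex(spec)


@pytest.fixture
def clean_trace():
    """Noiseless, decay-free FRAP trace at the fast acquisition setting."""
    return generate_frap_trace(FrapSpec(m1=80.0, m3=0.1, noise_sigma=0.0, seed=0))


@pytest.fixture
def rim_image():
    return generate_division_image(ImageSpec(geometry="rim", seed=0))
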