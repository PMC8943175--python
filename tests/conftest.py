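import numpy as np
import pytest

import chromofold as cf


@pytest.fixture(scope="session")
def two_compartment():
    """One deterministic synthetic chromosome: reference structure,
    compartments, contact matrix and the three peak tracks."""
    spec = cf.SyntheticSpec(seed=0)
    pos, comp = cf.make_reference_structure(spec)
    hic = cf.contacts_from_structure(pos, spec.contact_radius)
    factor, active, repressive = cf.make_marked_tracks(comp, spec)
    return {
        "spec": spec,
        "positions": pos,
        "compartments": comp,
        "hic": hic,
        "factor": factor,
        "active": active,
        "repressive": repressive,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
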