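import numpy as np
import pytest

import tumorsim as ts
from tumorsim.cohort import _regimen_tc


@pytest.fixture(scope="session")
def small_phantom():
    """12 mm ellipsoid phantom at 2 mm voxels (12³ lattice)."""
    spec = ts.PhantomSpec(diameter_mm=12, seed=2, voxel_side_mm=2.0,
                          margin_voxels=3)
    return ts.generate_phantom(spec)


@pytest.fixture()
def tc_case(small_phantom):
    """TNBC case on the anthracycline-free TC regimen, unit sensitivity."""
    lat, pmap, rho = small_phantom
    reg = _regimen_tc(False)
    return ts.CaseRecord(
        "tc-case", 52.0, "Other", "T2", "N0", 0.0, 0.0, False, 3,
        "Invasive Ductal Carcinoma", "TNBC",
        sensitivity={d: 1.0 for d in reg.drugs()},
        lattice=lat, perfusion=pmap, density=rho.copy(), regimen=reg)


@pytest.fixture(scope="session")
def fast_sim_config():
    return ts.SimConfig(mechanics_mode="bookkeeping",
                        include_secondary_species=False)
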