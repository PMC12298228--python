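import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helpers

from losartan_pkpd import (
    DoseRegimen,
    default_parameters,
    genotype_parameters,
)


@pytest.fixture(scope="session")
def dose50() -> DoseRegimen:
    return DoseRegimen(dose_mg=50.0)


@pytest.fixture(scope="session")
def base_params():
    """Package default parameter set (genotype-neutral)."""
    return default_parameters()


@pytest.fixture(scope="session")
def gg_params():
    """Wild-type CYP2C9 with the high-activity ABCB1 haplotype."""
    return genotype_parameters("CYP2C9*1/CYP2C9*1", "GG/CC")


@pytest.fixture(scope="session")
def fast_solver() -> dict:
    """Relaxed tolerances for tests where speed matters more than precision."""
    return {"rtol": 1e-6, "atol": 1e-8}
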