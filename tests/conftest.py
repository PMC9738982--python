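import numpy as np
import pytest
from hypothesis import settings

import speccult as sc

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from speccult.models import GaussianComponent, SpeciesModel, SubFunction

#: Coarse synthetic grid (nm) used throughout the suite; the instrument grid
#: (0.22 nm step) is 10x denser but adds nothing to the checked properties.
GRID = (330.0, 860.0, 2.0)


@pytest.fixture(scope="session")
def cem_model() -> SpeciesModel:
    """Calibrated CEM T-lymphoblast model (minimization parameters)."""
    return sc.load_builtin_model("cem_table2")


@pytest.fixture(scope="session")
def ca_model() -> SpeciesModel:
    """Calibrated Candida albicans model (log-linear sub-functions)."""
    return sc.load_builtin_model("ca_table3")


@pytest.fixture(scope="session")
def cem_approx_model() -> SpeciesModel:
    """CEM model at the approximated (iterated-fitting) parameters."""
    return SpeciesModel(
        "CEM-approx",
        (
            GaussianComponent(
                SubFunction("beer_lambert_amplitude", (7.45e-7,)),
                SubFunction("constant", (496.9,)),
                SubFunction("power", (2.14, 0.41)),
            ),
            GaussianComponent(
                SubFunction("constant", (23.11,)),
                SubFunction("constant", (976.9,)),
                SubFunction("constant", (253.9,)),
            ),
        ),
        (1e5, 1e6),
    )


@pytest.fixture(scope="session")
def lam() -> np.ndarray:
    lo, hi, step = GRID
    return np.arange(lo, hi + step / 2, step)
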