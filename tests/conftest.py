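import numpy as np
import pandas as pd
import pytest

from gmapsolve import parse_glycan
from gmapsolve.response_model import build_model_matrix, normalize_per_lectin
from gmapsolve.synthetic import (SimulationSpec, default_enzymes,
                                 default_lectins, default_panel,
                                 generate_library)

#: disialylated biantennary N-glycan, both arms Neu5Ac a2-6 / Gal b1-4
BIANTENNARY = ("Neu5Aca2-6Galb1-4GlcNAcb1-2Mana1-3"
               "(Neu5Aca2-6Galb1-4GlcNAcb1-2Mana1-6)"
               "Manb1-4GlcNAcb1-4GlcNAc")


@pytest.fixture
def biantennary():
    return parse_glycan(BIANTENNARY, id="bi26")


@pytest.fixture
def enzymes():
    return default_enzymes()


@pytest.fixture
def lectins():
    return default_lectins(extended=True)


@pytest.fixture
def basic_panel():
    return default_panel(extended=False)


@pytest.fixture
def extended_panel():
    return default_panel(extended=True)


@pytest.fixture(scope="session")
def small_library():
    spec = SimulationSpec(library_size=20, seed=7)
    return generate_library(spec)


@pytest.fixture(scope="session")
def small_matrix(small_library):
    panel = default_panel(extended=True)
    return normalize_per_lectin(build_model_matrix(small_library, panel))
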