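import numpy as np
import pytest

from xbsolv.itc import BindingParams, TitrationScheme


@pytest.fixture
def reverse_scheme() -> TitrationScheme:
    """Reverse titration: 287 uM titrant into 28.7 uM cell species, 200 uL
    cell, 0.4 uL first injection then 14 x 2.5 uL, 301 K."""
    return TitrationScheme.reverse_galectin()


@pytest.fixture
def cl_params() -> BindingParams:
    """Chloro-ligand binding parameters (Kd 0.22 uM, dH -56.6 kJ/mol)."""
    return BindingParams(n=1.0, Kd_M=0.22e-6, dH_kJmol=-56.6, Qoff_uJ=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240329)
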