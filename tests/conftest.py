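import numpy as np
import pytest

from ampar_mwc.io import load_builtin_model


@pytest.fixture(scope="session")
def glua3():
    """Recombinant GluA3/GluK2 chimera, full-agonist (quisqualate) fit."""
    return load_builtin_model("glua3_gluk2")


@pytest.fixture(scope="session")
def native():
    """Native cerebellar receptor, glutamate fit; basal state does not bind."""
    return load_builtin_model("native")


@pytest.fixture(scope="session")
def iw():
    return load_builtin_model("iw")


@pytest.fixture(scope="session")
def brw():
    return load_builtin_model("brw")


@pytest.fixture(scope="session")
def all_models(glua3, native, iw, brw):
    return {"glua3_gluk2": glua3, "native": native, "iw": iw, "brw": brw}


@pytest.fixture(scope="session")
def conc_grid():
    return np.logspace(-8, -2, 25)
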