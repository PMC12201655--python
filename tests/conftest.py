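import numpy as np
import pytest

from ribocell import _kernels as K
from ribocell.parameters import default_species, load_params
from ribocell.world import init_world


@pytest.fixture
def params():
    p, _ = load_params()
    return p


@pytest.fixture
def species():
    return default_species()


def make_world(seed=0, **overrides):
    """A world with custom constants and no initial material by default."""
    overrides.setdefault("N", 3)
    overrides.setdefault("T_NPPB", 0)
    overrides.setdefault("T_FB", 0)
    overrides.setdefault("T_GPB", 0)
    p, sp = load_params(overrides)
    return init_world(p, seed, sp)


def quiet_overrides(**extra):
    """Overrides switching every stochastic event off; tests re-enable."""
    out = {name: 0.0 for name in (
        "P_AT", "P_BB", "P_CB", "P_CD", "P_CF", "P_FJM", "P_FLM", "P_FP",
        "P_GD", "P_GF", "P_GFR", "P_GPP", "P_MC", "P_MF", "P_MV", "P_ND",
        "P_NDE", "P_NF", "P_NFR", "P_NP", "P_NPD", "P_NPF", "P_NPFR",
        "P_NPP", "P_NPPP", "P_PD", "P_PDM", "P_PF", "P_PJM", "P_PLM",
        "P_RL", "P_SP", "P_TL")}
    out.update(extra)
    return out


@pytest.fixture
def quiet_world():
    """3x3 world with all event probabilities zero and empty pools."""
    return make_world(**quiet_overrides())


@pytest.fixture(autouse=True)
def _seed_kernel_rng():
    K.seed_kernel_rng(12345)
    yield


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
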