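import numpy as np
import pytest

from tisim.genetics_core import Individual, TraitArchitecture
from tisim.meiosis import GameteModel
from tisim.strategy_bc import LasConfig, SelectionContext
from tisim.synthetic_data import generate_panel, maize_like_preset, micro_preset


@pytest.fixture(scope="session")
def micro_panel():
    """2-chromosome, 12-marker panel within reach of the enumeration oracles."""
    return generate_panel(micro_preset())


@pytest.fixture(scope="session")
def maize_panel():
    """Full-size maize-like panel with a handful of donors."""
    return generate_panel(maize_like_preset(n_donors=6))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_context(panel, seed=0, **las_kwargs):
    """Selection context over a generated panel."""
    donors, rp, gmap, arch = panel
    las = LasConfig(**las_kwargs) if las_kwargs else LasConfig()
    return SelectionContext(
        rp=rp,
        arch=arch,
        model=GameteModel(gmap.rf),
        rng=np.random.default_rng(seed),
        las=las,
    )


def random_individual(rng, P, ident="x"):
    return Individual(ident, rng.integers(0, 2, (P, 2), dtype=np.uint8))


def simple_arch(P, targets, rc_goal=0.5, effects=None):
    if effects is None:
        effects = np.ones(P)
    return TraitArchitecture(target_loci=np.asarray(targets), effects=effects, rc_goal=rc_goal)
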