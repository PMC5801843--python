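import numpy as np
import pytest

from radiate.simulate import SimConfig, make_study_fixture, sim_tree
from radiate.tree import Phylogeny, branching_times, parse_tree


@pytest.fixture(scope="session")
def four_tip_tree():
    return parse_tree("((A:1,B:1):2,(C:2,D:2):1);")


@pytest.fixture(scope="session")
def study_fixture():
    """58-tip two-subclade tree with two-peak OU traits on 41 species."""
    return make_study_fixture(1)


@pytest.fixture(scope="session")
def study_bt(study_fixture):
    tree, _ = study_fixture
    return branching_times(tree)


def scaled_yule(seed: int, n_tips: int = 32, height: float = 15.0) -> Phylogeny:
    """Pure-birth tree rescaled to a fixed crown age (test helper)."""
    cfg = SimConfig(process="yule", lambda0=1.0, n_tips=n_tips)
    t = sim_tree(cfg, np.random.default_rng(seed))
    return Phylogeny(t.parent, t.edge_length * (height / t.root_height), t.labels)
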