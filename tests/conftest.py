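import numpy as np
import pytest

from caudalmorph.outlines import Outline
from caudalmorph.phylo import read_newick
from caudalmorph.synth import make_study_like_dataset, simulate_yule_tree


@pytest.fixture(scope="session")
def three_taxon_tree():
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def yule16():
    return simulate_yule_tree(16, seed=11)


@pytest.fixture(scope="session")
def yule64():
    return simulate_yule_tree(64, seed=23)


@pytest.fixture(scope="session")
def circle_outline():
    t = np.linspace(0, 2 * np.pi, 512, endpoint=False)
    return Outline(np.column_stack([np.cos(t), np.sin(t)]), "circle")


@pytest.fixture(scope="session")
def study_bundle():
    """Default study-like bundle: 51 species, 5 foraging classes."""
    return make_study_like_dataset(51, seed=1)
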