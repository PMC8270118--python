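import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from screenage import SpeciesTree
from screenage.simulate import DEFAULT_FOCAL, DEFAULT_NEWICK


@pytest.fixture(scope="session")
def standard_tree() -> SpeciesTree:
    """The default 12-species tree (6 stages on the root-to-focal path)."""
    return SpeciesTree.from_newick(DEFAULT_NEWICK, DEFAULT_FOCAL)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
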