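import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from rnaphylo.io_formats import SequenceRecord
from rnaphylo.phylo_ml.model import make_model
from rnaphylo.synthetic_data import SimulationConfig, make_its2_family


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def jc():
    return make_model("JC")


@pytest.fixture(scope="session")
def small_family():
    """An 8-taxon ITS2-like family shared by structure/alignment tests."""
    return make_its2_family(SimulationConfig(seed=11, n_taxa=8))


@pytest.fixture
def three_records():
    return [
        SequenceRecord(id="a", residues="ACGUACGU", description="first"),
        SequenceRecord(id="b", residues="ACGAACGA"),
        SequenceRecord(id="c", residues="GGGUACGU", description="third one"),
    ]
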