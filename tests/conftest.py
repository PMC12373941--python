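import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes _oracles importable

from invascope.genesets import GeneSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_gene_set():
    return GeneSet("target", tuple(f"G{i:04d}" for i in range(30)))
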