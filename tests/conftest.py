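import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from metnet import build_network, generate_fixture_model


@pytest.fixture
def diamond_model():
    """A + B <=> C (reversible R1), A -> E (R2), E -> B (R3)."""
    return generate_fixture_model("diamond")


@pytest.fixture
def diamond_rc(diamond_model):
    return build_network(diamond_model, "RC")


@pytest.fixture
def random_models():
    """A spread of small random models (2-5 reactions, mixed reversibility)."""
    return [
        generate_fixture_model("random", seed=seed, size=2 + seed % 4)
        for seed in range(40)
    ]
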