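import numpy as np
import pytest

from circmil.instancing import WindowGeometry
from circmil.model import BagNet, ModelConfig
from circmil.seqio import SequenceRecord


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_config():
    """A config small enough for fast forward/backward passes."""
    return ModelConfig(rnn_hidden=6, fcn_hidden=8, feature_dim=5,
                       attention_hidden=4, rnn_layers=2)


@pytest.fixture
def tiny_net(tiny_config):
    return BagNet(tiny_config, seed=7)


@pytest.fixture
def geometry():
    return WindowGeometry(window=12, step=6)


def _random_record(rng, length, rid="r", label=1):
    seq = "".join("ATGC"[c] for c in rng.integers(0, 4, length))
    return SequenceRecord(id=rid, seq=seq, label=label)


@pytest.fixture
def make_record():
    """Factory fixture for random sequence records."""
    return _random_record


@pytest.fixture
def random_records(rng):
    return [_random_record(rng, int(rng.integers(200, 400)), f"r{i}", i % 2)
            for i in range(12)]
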