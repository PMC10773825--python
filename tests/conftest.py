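import numpy as np
import pytest

from metaswin.model import ModelConfig, build_network, count_parameters


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240101)


def _count(mixer, use_se, c, inc, outc):
    cfg = ModelConfig(feature_size=c, in_channels=inc, out_channels=outc,
                      mixer=mixer, use_se=use_se, roi=(96, 96, 96))
    return count_parameters(build_network(cfg))


@pytest.fixture(scope="session")
def reference_grid_counts():
    """Parameter totals for every variant at C=24 and C=48 in both
    channel configurations (built once; reused by checksum and delta
    tests)."""
    counts = {}
    for mixer in ("attention", "pooling"):
        for use_se in (False, True):
            for c in (24, 48):
                counts[(mixer, use_se, c, 1, 14)] = _count(mixer, use_se, c, 1, 14).total
            counts[(mixer, use_se, 48, 4, 3)] = _count(mixer, use_se, 48, 4, 3).total
    return counts


@pytest.fixture(scope="session")
def tiny_pooling_net():
    cfg = ModelConfig(feature_size=12, in_channels=4, out_channels=3,
                      mixer="pooling", roi=(32, 32, 32))
    return build_network(cfg, seed=1)
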