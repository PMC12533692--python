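import numpy as np
import pytest

from statebound.timelines import BlockSchedule, BoundaryTimeline


@pytest.fixture(scope="session")
def schedule() -> BlockSchedule:
    return BlockSchedule.default()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def neural_timeline(marks_per_block: dict, block_samples: int = 1920,
                    rate_hz: float = 64.0) -> BoundaryTimeline:
    """Convenience constructor for neural timelines in tests."""
    return BoundaryTimeline(rate_hz=rate_hz, block_samples=block_samples,
                           blocks=marks_per_block, provenance="neural")
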