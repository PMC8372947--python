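import numpy as np
import pytest

from enscnv.worked_example import build_worked_example


@pytest.fixture()
def worked_example():
    """Rarity calls and annotated genes of the published candidate table."""
    return build_worked_example()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
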