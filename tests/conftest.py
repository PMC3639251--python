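import numpy as np
import pytest

from cardiomap.genome import make_marker_map


@pytest.fixture(scope="session")
def small_map():
    """Five 2-Mb arms at 50 kb spacing: 40 markers per arm, fast crosses."""
    arms = (("X", 2_000_000), ("2L", 2_000_000), ("2R", 2_000_000),
            ("3L", 2_000_000), ("3R", 2_000_000))
    return make_marker_map(arms, spacing=50_000)


@pytest.fixture(scope="session")
def default_map():
    """The full default D. melanogaster map (~12k markers at 10 kb)."""
    return make_marker_map()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
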