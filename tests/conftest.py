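import numpy as np
import pytest

from retrokit.simulate import SimParams


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def sim_params():
    return SimParams(seed=0)


def spans_match(found, truth_span, tsd_len, slack=3):
    """Planted-element span matcher.

    The 3' boundary of an element is ambiguous against an adenine-rich TSD
    (the detected poly(A) tail may legitimately absorb leading adenines of
    the right TSD copy), so the end may extend up to the TSD length.
    """
    (fs, fe), (ts, te) = found, truth_span
    return abs(fs - ts) <= slack and te - slack <= fe <= te + tsd_len
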