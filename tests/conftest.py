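import numpy as np
import pytest

from retemplate import parse_dot_bracket, random_nested_structure


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_structures():
    """A deterministic batch of random nested structures of varied length."""
    rng = np.random.default_rng(777)
    out = []
    for k in range(60):
        length = int(rng.integers(10, 121))
        out.append(random_nested_structure(length, rng))
    return out


@pytest.fixture
def sam_like():
    """A multi-element structure: outer stem enclosing two hairpins."""
    return parse_dot_bracket("((..((...))..((...))..))")
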