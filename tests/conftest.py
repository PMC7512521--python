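import numpy as np
import pytest

from logbounds import (
    champernowne_digits,
    encode,
    from_codes,
    logistic_string,
    pi_digits,
    uniform_string,
)


@pytest.fixture(scope="session")
def assorted_strings():
    """A mixed bag of strings for invariant suites: random, structured,
    chaotic, and tiny hand-built cases over several alphabet sizes."""
    rng = np.random.default_rng(20181206)
    out = [
        encode("banana", alphabet="abn"),
        encode("abcd"),
        encode("aabb", alphabet="ab"),
        encode("aaaa", alphabet="ab"),
        uniform_string(2, 500, 1),
        uniform_string(4, 2000, 2),
        uniform_string(10, 1500, 3),
        uniform_string(26, 800, 4),
        logistic_string(0.1, 4.0, 600, 10),
        champernowne_digits(1200),
        pi_digits(1000),
        from_codes(rng.integers(0, 3, 50), 5),  # declared m > observed
    ]
    return out
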