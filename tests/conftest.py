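import numpy as np
import pytest

from cyclospi import (
    CyclicCode,
    fold_crt,
    m_sequence_code,
    qr_code,
    twin_prime_code,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def code3():
    """Order-3 S-matrix code [1, 1, 0] used in hand-computed examples."""
    return CyclicCode(order=3, bits=np.array([1, 1, 0], dtype=np.uint8), method="custom")


@pytest.fixture(scope="session")
def qr7():
    return qr_code(7)


@pytest.fixture(scope="session")
def qr19():
    return qr_code(19)


@pytest.fixture(scope="session")
def tp15():
    return twin_prime_code(3, 5)


@pytest.fixture(scope="session")
def layout15(tp15):
    return fold_crt(tp15, 3, 5)


@pytest.fixture(scope="session")
def tp10403():
    return twin_prime_code(101, 103)


@pytest.fixture(scope="session")
def layout10403(tp10403):
    return fold_crt(tp10403, 101, 103)


@pytest.fixture(scope="session")
def small_codes(qr7, qr19, tp15):
    """Every construction family at dense-oracle scale (N <= 31)."""
    return [
        qr_code(3),
        qr7,
        qr_code(11),
        qr19,
        qr_code(23),
        qr_code(31),
        tp15,
        m_sequence_code(3, (3, 1)),
        m_sequence_code(4, (4, 1)),
        m_sequence_code(5, (5, 2)),
    ]
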