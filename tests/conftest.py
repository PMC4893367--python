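import numpy as np
import pytest

from grmcalib import ItemBank, generate_bank


@pytest.fixture(scope="session")
def quasi_bank() -> ItemBank:
    """A 40-item quasi-trait bank matching the default summary targets."""
    return generate_bank(seed=7)


@pytest.fixture(scope="session")
def small_bank() -> ItemBank:
    """Hand-picked 5-item bank for cheap estimation tests."""
    return ItemBank(
        a=np.array([1.2, 1.8, 2.2, 1.5, 2.6]),
        b=np.array(
            [
                [-1.5, -0.5, 0.5, 1.5],
                [-0.8, 0.0, 0.9, 1.8],
                [-0.2, 0.6, 1.3, 2.1],
                [-1.0, -0.1, 0.8, 1.6],
                [0.1, 0.9, 1.7, 2.5],
            ]
        ),
        label="small",
    )
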