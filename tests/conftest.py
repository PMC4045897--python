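"""Shared fixtures: small hand-checkable capture histories."""

import numpy as np
import pytest

from closedcmr import CaptureData, capture_frequencies


@pytest.fixture
def toy() -> CaptureData:
    """5 individuals x 3 occasions; row sums 3,2,2,1,1."""
    return CaptureData(
        individuals=["A", "B", "C", "D", "E"],
        occasions=["1", "2", "3"],
        matrix=np.array([
            [1, 1, 1],
            [1, 1, 0],
            [0, 1, 1],
            [1, 0, 0],
            [0, 0, 1],
        ]),
    )


@pytest.fixture
def toy_freq(toy):
    return capture_frequencies(toy)


@pytest.fixture
def three_periods() -> CaptureData:
    """Three primary periods: X only in P1, Y in P1+P3, W in all, Z born P3."""
    return CaptureData(
        individuals=["X", "Y", "W", "Z"],
        occasions=["a1", "a2", "b1", "b2", "c1", "c2"],
        matrix=np.array([
            [1, 0, 0, 0, 0, 0],
            [1, 1, 0, 0, 1, 0],
            [0, 1, 1, 0, 0, 1],
            [0, 0, 0, 0, 1, 1],
        ]),
        primary_of={"a1": "P1", "a2": "P1", "b1": "P2", "b2": "P2",
                    "c1": "P3", "c2": "P3"},
        birth_period={"Z": "P3"},
    )


@pytest.fixture
def all_caught() -> CaptureData:
    """Every animal caught on every occasion."""
    return CaptureData(
        individuals=[f"i{k}" for k in range(10)],
        occasions=["1", "2", "3"],
        matrix=np.ones((10, 3), dtype=int),
    )
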