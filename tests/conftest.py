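"""Shared fixtures: deterministic code tables, sharp PWMs, small bundles."""

import numpy as np
import pytest

from pprchip.code import CodeTable, PWMatrix, build_pwm
from pprchip.proteins import SpecificityPair


@pytest.fixture
def sharp_code_table():
    """A deterministic pair→base table: each pair maps to one base."""
    return CodeTable(
        entries={
            ("T", "D"): np.array([0.0, 0.0, 1.0, 0.0]),  # G
            ("T", "N"): np.array([1.0, 0.0, 0.0, 0.0]),  # A
            ("N", "D"): np.array([0.0, 0.0, 0.0, 1.0]),  # U
            ("N", "S"): np.array([0.0, 1.0, 0.0, 0.0]),  # C
        },
        source_label="sharp-fixture",
    )


@pytest.fixture
def pairs_ugac():
    """Four pairs spelling UGAC under the sharp fixture table."""
    return [
        SpecificityPair("P1", "N", "D"),
        SpecificityPair("P2", "T", "D"),
        SpecificityPair("P3", "T", "N"),
        SpecificityPair("P4", "N", "S"),
    ]


@pytest.fixture
def sharp_pwm(sharp_code_table, pairs_ugac):
    """A 4-position deterministic PWM with consensus UGAC."""
    return build_pwm(pairs_ugac, sharp_code_table)


@pytest.fixture
def random_pwm_factory():
    """Seeded random PWMs for distribution tests."""
    def make(length: int, seed: int, concentration: float = 1.0) -> PWMatrix:
        rng = np.random.default_rng(seed)
        return PWMatrix(probs=rng.dirichlet(np.full(4, concentration), size=length))
    return make
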