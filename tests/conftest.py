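import numpy as np
import pandas as pd
import pytest

from rloopkit.config import SimConfig


@pytest.fixture
def small_config():
    """A light configuration for fast generator tests."""
    return SimConfig(
        seed=7, n_plates=2, wells_per_plate=24, n_wt_wells=12,
        hyper_effects={"mutA": 10.0, "mutB": 1.0},
        n_strains_pinning=8, pinning_effects={"strain000": 0.5},
        n_genes=10, genome_length=10_000, n_nuclei=4, nucleus_radius=14,
        image_shape=(128, 128),
    )


@pytest.fixture
def wt_only_measurements():
    """A two-plate wild-type-only table with known values."""
    rows = []
    for plate, values in (("p1", [0.02, 0.04, 0.06]), ("p2", [0.01, 0.02, 0.03])):
        for i, v in enumerate(values):
            rows.append(("wt", plate, i, v, True))
    return pd.DataFrame(
        rows, columns=["strain_id", "plate_id", "replicate", "frac_positive", "is_wt"]
    )


def fisher_two_sided_enumeration(table) -> float:
    """Independent oracle: two-sided Fisher p by exhaustive hypergeometric
    enumeration over all tables with the same margins (sum of probabilities
    <= that of the observed table)."""
    from math import comb

    (a, b), (c, d) = table
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def prob(x):
        return comb(row1, x) * comb(row2, col1 - x) / comb(n, col1)

    p_obs = prob(a)
    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))
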