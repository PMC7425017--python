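"""Shared fixtures: the eight-fragment toy locus and small synthetic worlds."""

import numpy as np
import pandas as pd
import pytest

from sifcall.fragments import FragmentMap
from sifcall.simulate import simulate_fragment_map

# Eight restriction fragments F1..F8 with lengths L1..L8 (bp).  Scaled to
# tens of kb so that pairwise distances support a distance profile.
TOY_LENGTHS = [10_000, 20_000, 15_000, 25_000, 30_000, 18_000, 22_000, 13_000]

# Interactions of the toy locus: (frag_i, frag_j, score), 0-based indices.
# F1-F8: 4, F2-F7: 4, F3-F5: 5, F4-F6: 3.
TOY_INTERACTIONS = [(0, 7, 4), (1, 6, 4), (2, 4, 5), (3, 5, 3)]


@pytest.fixture(scope="session")
def toy_map() -> FragmentMap:
    return simulate_fragment_map(8, lengths=TOY_LENGTHS, chrom="chrT")


@pytest.fixture(scope="session")
def toy_records(toy_map) -> pd.DataFrame:
    return pd.DataFrame(
        [("chrT", i, "chrT", j, s) for i, j, s in TOY_INTERACTIONS],
        columns=["chrom1", "idx1", "chrom2", "idx2", "score"],
    )


@pytest.fixture(scope="session")
def toy_pairs(toy_map) -> pd.DataFrame:
    """Read pairs realizing the toy USF scores, deterministic positions."""
    rng = np.random.default_rng(42)
    rows = []
    k = 0
    for i, j, score in TOY_INTERACTIONS:
        fi = toy_map.fragment("chrT", i)
        fj = toy_map.fragment("chrT", j)
        for _ in range(score):
            rows.append((
                f"r{k}", "chrT", int(rng.integers(fi.start, fi.end)),
                "chrT", int(rng.integers(fj.start, fj.end)), "+", "-",
            ))
            k += 1
    return pd.DataFrame(
        rows, columns=["read_id", "chrom1", "pos1", "chrom2", "pos2",
                       "strand1", "strand2"])


@pytest.fixture(scope="session")
def uniform_map() -> FragmentMap:
    """100 fragments of exactly 1 kb, for midpoint-distance arithmetic."""
    return simulate_fragment_map(100, lengths=[1000] * 100, chrom="chrU")
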