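import numpy as np
import pandas as pd
import pytest

from atacreg.peaks import CountsMatrix, GenomicInterval
from atacreg.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort: 5,000 peaks, 15 vs 15, 10% opening / 5% closing."""
    return simulate_cohort(SimConfig(seed=3))


@pytest.fixture(scope="session")
def small_cohort():
    """A scaled cohort for fast unit tests."""
    return simulate_cohort(SimConfig(n_peaks=800, n_genes=300, seed=7))


@pytest.fixture
def toy_filter_fixture():
    """Five peaks exercising each consensus filter rule exactly once.

    A survives; B fails read support (max 10 <= 20); C exceeds the 500 cpm
    ceiling; D overlaps the blacklist; E sits on chrX.
    """
    peaks = [
        GenomicInterval("chr1", 100, 500, name="A"),
        GenomicInterval("chr1", 1000, 1400, name="B"),
        GenomicInterval("chr1", 2000, 2400, name="C"),
        GenomicInterval("chr1", 3000, 3400, name="D"),
        GenomicInterval("chrX", 100, 500, name="E"),
    ]
    lib = np.array([1e6, 1e6])
    values = np.array(
        [
            [25, 20],  # A: max 25 reads -> 25 cpm
            [10, 8],  # B: max 10 reads, fails support
            [600, 50],  # C: 600 cpm > 500
            [30, 25],  # D: fine on counts, blacklisted
            [30, 25],  # E: fine on counts, non-autosomal
        ]
    )
    counts = CountsMatrix(
        ["A", "B", "C", "D", "E"], ["s1", "s2"], values, lib_sizes=lib
    )
    blacklist = [GenomicInterval("chr1", 3300, 3600)]
    return peaks, counts, blacklist


@pytest.fixture
def balanced_sheet():
    rows = []
    for i, (g, s) in enumerate(
        [("control", "F"), ("control", "M")] * 3 + [("centenarian", "F"), ("centenarian", "M")] * 3
    ):
        rows.append({"sample_id": f"s{i:02d}", "group": g, "sex": s})
    return pd.DataFrame(rows)
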