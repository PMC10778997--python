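import numpy as np
import pytest

from ernadens.io_formats import GenomicInterval, IntervalSet
from ernadens.synthetic_data import SynthConfig

#: the printed worked-example inputs for the Australian ovarian-cancer donor
DO46325_GENOME = {"C>A": 1342, "C>G": 1178, "C>T": 1770, "T>A": 912, "T>C": 1160, "T>G": 503}
DO46325_REGION = {"C>A": 7, "C>G": 10, "C>T": 12, "T>A": 0, "T>C": 2, "T>G": 5}
DO46325_REGION_BASES = 14_522_866


@pytest.fixture
def rng():
    return np.random.default_rng(20240534)


@pytest.fixture
def small_intervals():
    return IntervalSet(
        [
            GenomicInterval("1", 100, 300, name="a"),
            GenomicInterval("1", 500, 900, name="b"),
            GenomicInterval("2", 50, 60, name="c"),
        ],
        source_label="toy",
    )


@pytest.fixture
def sim_base_config():
    """Small but well-powered simulation geometry shared by the statistical tests."""
    return SynthConfig(
        chrom_length=120_000,
        n_ernas=12,
        edge_margin=20_000,
        min_spacing=5_000,
        n_donors=10,
        donor_total_median=700.0,
        donor_total_sigma=0.3,
    )


def random_interval_set(rng, max_intervals=50, chrom_span=10_000, chroms=("1", "2")):
    n = int(rng.integers(1, max_intervals + 1))
    ivs = []
    for _ in range(n):
        c = str(rng.choice(list(chroms)))
        start = int(rng.integers(0, chrom_span - 2))
        end = int(rng.integers(start + 1, min(start + 400, chrom_span)))
        ivs.append(GenomicInterval(c, start, end))
    return IntervalSet(ivs, source_label=f"rand{rng.integers(1e6)}")
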