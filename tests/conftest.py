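import numpy as np
import pytest

from hicbg import BinTable, ContactMap, ModelParameters


@pytest.fixture
def toy_bins() -> BinTable:
    """Three 10 kb bins on one chromosome plus two on another."""
    return BinTable(
        chrom=np.array(["chr1", "chr1", "chr1", "chr2", "chr2"], dtype=object),
        start=np.array([0, 10_000, 20_000, 0, 10_000]),
        end=np.array([10_000, 20_000, 30_000, 10_000, 20_000]),
        bin_id=np.array([1, 2, 3, 4, 5]),
    )


@pytest.fixture
def toy_map(toy_bins) -> ContactMap:
    return ContactMap(
        bins=toy_bins,
        i=np.array([1, 1, 2, 1]),
        j=np.array([2, 3, 3, 4]),
        count=np.array([5, 2, 7, 3]),
        bin_size=10_000,
    )


@pytest.fixture
def simple_params() -> ModelParameters:
    return ModelParameters(
        b=0.8, b_m=-1.0, v_base=0.05,
        a0=11.0, a1=-0.9, a2=0.0, a3=0.0,
        f_c=0.3, r=4.0, k=10.0, base_e=0.5,
    )


@pytest.fixture(scope="session")
def background_sim():
    """Small simulated background map shared across training tests."""
    from hicbg import simulate_background

    return simulate_background(n_bins=120, bin_size=10_000, seed=42)
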