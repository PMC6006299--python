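import numpy as np
import pytest

from xomap import AlleleDepthMatrix, MarkerSet, SimConfig, simulate_marker_set
import pandas as pd


@pytest.fixture
def small_cfg() -> SimConfig:
    """Two 2-Mbp chromosomes; CO density matching the default genome-wide rate."""
    return SimConfig(
        chrom_lengths={"chr1": 2_000_000, "chr2": 2_000_000},
        co_per_meiosis_lambda=0.4,
        seed=7,
    )


@pytest.fixture
def small_markers(small_cfg) -> MarkerSet:
    return simulate_marker_set(small_cfg)


def make_depth_matrix(ref_rows, alt_rows, positions=None, chrom="chr1") -> AlleleDepthMatrix:
    """Hand-built depth matrix: one row per individual, one column per marker."""
    ref = np.asarray(ref_rows, dtype=np.int32)
    alt = np.asarray(alt_rows, dtype=np.int32)
    n_ind, m = ref.shape
    if positions is None:
        positions = np.arange(m) * 1000 + 100
    table = pd.DataFrame(
        {"chrom": chrom, "pos": positions, "ref": "A", "alt": "G"}
    )
    return AlleleDepthMatrix(
        individuals=[f"i{k}" for k in range(n_ind)],
        ref=ref,
        alt=alt,
        markers=MarkerSet(table),
    )
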