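import numpy as np
import pandas as pd
import pytest

from hapmethyl.synthetic import SimConfig


@pytest.fixture
def small_cfg():
    """Fast methylome config: 2 chromosomes, dense CpGs, a few planted regions."""
    return SimConfig(seed=11, n_chromosomes=2, n_cpgs_per_chrom=1500,
                     chrom_length_bp=100_000, mean_coverage_per_haplotype=30,
                     n_planted_tumor_admrs=6, n_planted_imprinted_regions=2,
                     n_planted_random_asm=2, panel_size=10,
                     panel_partial_fraction_at_imprinted=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=100_000, max_len=2_000):
    start = rng.integers(0, max_pos, size=n)
    length = rng.integers(1, max_len, size=n)
    return pd.DataFrame({
        "chrom": rng.choice(chroms, size=n),
        "start": start,
        "end": start + length,
    })
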