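import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cisspread import SimParams

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def small_params():
    """A fast 5 Mb toy chromosome."""
    return SimParams(
        chrom_length=5_000_000,
        n_genes=30,
        integration_pos=500_000,
        centromere_pos=2_500_000,
        silencing_halflife=1_000_000,
        chip_window_size=50_000,
        seed=7,
    )


def random_variant_table(rng, n_sites, *, zero_fraction=0.1, tie_boost=True,
                         chrom="chrT", start_pos=1):
    """Random allelic count table exercising zeros, ties and extremes."""
    pos = start_pos + np.arange(n_sites)
    counts = rng.integers(0, 60, size=(n_sites, 4))
    zero_mask = rng.random(n_sites) < zero_fraction
    which = rng.integers(0, 2, size=n_sites)
    counts[zero_mask & (which == 0), 0:2] = 0
    counts[zero_mask & (which == 1), 2:4] = 0
    if tie_boost:
        ties = rng.random(n_sites) < 0.15
        counts[ties, 3] = counts[ties, 2]
    return pd.DataFrame({
        "chrom": chrom, "pos": pos,
        "allele_a_id": "A", "allele_b_id": "G",
        "ctrl_a": counts[:, 0], "ctrl_b": counts[:, 1],
        "exp_a": counts[:, 2], "exp_b": counts[:, 3],
    })
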