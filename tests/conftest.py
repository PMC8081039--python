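import numpy as np
import pandas as pd
import pytest

from nemaquant import synthio


@pytest.fixture(scope="session")
def worm_image_210():
    """A moderately curved synthetic worm near the L1 length scale."""
    return synthio.gen_worm_image(210.0, amplitude_um=20.0, seed=11)


@pytest.fixture(scope="session")
def small_counts():
    """A small two-group count matrix with 10% spiked DE genes."""
    return synthio.gen_counts(n_genes=400, n_per_group=4, frac_de=0.1, seed=5)


@pytest.fixture()
def toy_lipid_table():
    return synthio.gen_lipid_table(
        n_lipids=30, n_samples_per_group=5, missing_prob=0.1,
        effect_multipliers={"LPC_000": 3.0, "LPE_001": 2.0}, seed=2,
    )
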