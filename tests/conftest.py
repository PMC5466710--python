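"""Shared fixtures: a small forged reference and random-sequence helpers.

Everything is generated programmatically and seeded; no fixture files.
"""

import numpy as np
import pytest

from nanosurvey import ForgeConfig, build_reference


def random_seq(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def small_config():
    return ForgeConfig(
        seed=11,
        chrom_lengths=(90_000, 80_000, 70_000),
        te_length=2_000,
        rdna_unit_length=800,
        rdna_copies=5,
        tandem_arrays=(("CUP1", 1_000, 7), ("ENA1", 1_200, 4)),
        n_genes=6,
        gene_length=900,
    )


@pytest.fixture(scope="session")
def small_ref(small_config):
    return build_reference(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20_260_926)
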