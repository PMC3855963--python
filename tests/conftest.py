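from __future__ import annotations

import numpy as np
import pytest

import ismvar as iv


@pytest.fixture(scope="session")
def planted_dataset() -> iv.SyntheticDataset:
    """Strong-effect planted dataset shared by recovery/evaluation tests."""
    return iv.generate_planted_dataset(
        length=300, planted_frequency_index=143,
        n_mut=20, n_snp=20, effect_size=3.0, seed=42,
    )


@pytest.fixture(scope="session")
def planted_fit(planted_dataset) -> iv.GeneFit:
    return iv.fit_gene(planted_dataset.wild_type, planted_dataset.variants,
                       gene_id="SYNTH")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20130948)


@pytest.fixture()
def random_series(rng):
    """A bundle of random EIIP-like series of mixed parity and length."""
    lengths = list(rng.integers(2, 501, size=20))
    return [rng.uniform(0.0, 0.13, size=int(n)) for n in lengths]
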