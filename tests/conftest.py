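import numpy as np
import pytest

from metasense import MetaDataset, Study


@pytest.fixture
def homogeneous_dataset() -> MetaDataset:
    """Twelve identical effects: Q = 0, tau2 = 0, every mean equal."""
    return MetaDataset(
        tuple(Study(f"h{i}", 0.25, 150) for i in range(12)), label="homogeneous"
    )


@pytest.fixture
def mixed_dataset() -> MetaDataset:
    """Ten heterogeneous studies, one extreme value (s8, r=.55, small n).

    Matches the fixture frozen into the external-oracle cross-checks.
    """
    r = [0.10, 0.15, 0.22, 0.05, 0.18, 0.30, 0.12, 0.08, 0.55, 0.20]
    n = [120, 80, 200, 150, 60, 90, 300, 110, 45, 70]
    return MetaDataset(
        tuple(Study(f"s{i}", r[i], n[i]) for i in range(10)), label="mixed"
    )


@pytest.fixture
def planted_outlier_dataset() -> MetaDataset:
    """k=20 homogeneous studies plus one shifted by ~+5 SE (study 'out')."""
    rng = np.random.default_rng(20240917)
    studies = []
    for i in range(19):
        z = rng.normal(0.15, np.sqrt(1.0 / 97))
        studies.append(Study(f"p{i}", float(np.tanh(z)), 100))
    z_out = 0.15 + 5.0 * np.sqrt(1.0 / 97)
    studies.append(Study("out", float(np.tanh(z_out)), 100))
    return MetaDataset(tuple(studies), label="planted")
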