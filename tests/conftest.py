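import numpy as np
import pytest

from gliorl.synthetic import SynthSpec, generate_classification_table
from gliorl.table import SampleTable, zscore_normalize


@pytest.fixture
def toy_table() -> SampleTable:
    """3 samples, 2 features, binary labels, singleton groups."""
    return SampleTable.from_arrays(
        np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]),
        ["f0", "f1"],
        labels=[0, 1, 1],
    )


@pytest.fixture
def separable_table() -> SampleTable:
    """Well-separated binary table (effect size 3, 5 of 20 informative)."""
    spec = SynthSpec(
        class_counts=(40, 40), n_features=20, n_informative=5, effect_size=3.0, seed=42
    )
    table, _ = generate_classification_table(spec)
    table, _ = zscore_normalize(table)
    return table


@pytest.fixture
def noise_table() -> SampleTable:
    """Pure-noise binary table (effect size 0): no learnable signal."""
    spec = SynthSpec(
        class_counts=(40, 40), n_features=20, n_informative=5, effect_size=0.0, seed=42
    )
    table, _ = generate_classification_table(spec)
    table, _ = zscore_normalize(table)
    return table
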