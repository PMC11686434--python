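import numpy as np
import pandas as pd
import pytest

from phenocae.model import LatentLayout, NetworkSpec
from phenocae.panel import SpectraPanel


@pytest.fixture
def tiny_layout() -> LatentLayout:
    return LatentLayout(zg=3, ze=2, zp=2, E=2, N=2)


@pytest.fixture
def tiny_spec() -> NetworkSpec:
    return NetworkSpec(input_dim=30, hidden_dims=(16, 8))


@pytest.fixture
def small_panel() -> SpectraPanel:
    """3 genotypes x 2 environments x 2 replicates x 12 wavelengths."""
    rng = np.random.default_rng(7)
    rows = []
    for g in range(3):
        for e in range(2):
            for r in range(2):
                rows.append((f"g{g}", f"e{e}", f"r{r}"))
    meta = pd.DataFrame(rows, columns=["genotype", "environment", "replicate"])
    values = rng.uniform(0.05, 0.95, size=(12, 12))
    traits = pd.DataFrame({"yield": rng.normal(size=12)})
    return SpectraPanel(
        meta=meta, wavelengths=np.arange(400.0, 412.0), values=values, traits=traits
    )
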