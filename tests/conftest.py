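import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_map():
    """3-anchor toy map on chr3: 1 bp -> 0 cM, 1,000,001 -> 1 cM, 2,000,001 -> 2 cM."""
    from coseg.genmap import load_genetic_map

    return load_genetic_map(
        pd.DataFrame(
            {
                "chrom": ["chr3"] * 3,
                "bp": [1, 1_000_001, 2_000_001],
                "cM": [0.0, 1.0, 2.0],
            }
        )
    )


@pytest.fixture
def sib_pedigree():
    from coseg.synthetic import nuclear_pedigree

    return nuclear_pedigree(2, affected=("child1", "child2"))
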