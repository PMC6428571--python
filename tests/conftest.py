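import pandas as pd
import pytest

from helpers import make_freq_table


@pytest.fixture
def toy_scores_input():
    """Three SNPs, two populations, with hand-computable scores."""
    betas = pd.Series([0.1, -0.2, 0.05], index=["s1", "s2", "s3"], name="beta")
    freqs = make_freq_table(
        [[0.5, 0.1], [0.2, 0.4], [0.9, 0.9]], populations=["north", "south"]
    )
    return betas, freqs
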