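import pandas as pd
import pytest

from rarepc.synthetic import make_bin_table


@pytest.fixture(scope="session")
def bins5000() -> pd.DataFrame:
    """Standard 5,000-bin hg19-proportioned genome grid."""
    return make_bin_table(5000, seed=1)


@pytest.fixture(scope="session")
def bins500() -> pd.DataFrame:
    """Coarse grid for cheap tests."""
    return make_bin_table(500, seed=1)
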