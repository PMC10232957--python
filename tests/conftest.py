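import pandas as pd
import pytest

from agt_screen import load_reference_panel, score_panel


@pytest.fixture(scope="session")
def panel() -> pd.DataFrame:
    """Packaged 119-genotype reference panel of pooled trait means."""
    return load_reference_panel()


@pytest.fixture(scope="session")
def scored(panel) -> pd.DataFrame:
    return score_panel(panel)
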