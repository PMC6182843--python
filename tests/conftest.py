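import pytest

from refstab.cq import collapse_technical_reps, complete_case
from refstab.simulate import default_panel, simulate_cq


@pytest.fixture(scope="session")
def panel():
    """Synthetic 7-gene panel (seed 0): collapsed complete matrix + truth."""
    m, truth = simulate_cq(default_panel(seed=0))
    collapsed, _ = complete_case(collapse_technical_reps(m))
    return collapsed, truth


@pytest.fixture(scope="session")
def panel_matrix(panel):
    return panel[0]
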