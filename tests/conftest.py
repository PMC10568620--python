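import pytest

import tkiswitch as tk


@pytest.fixture(scope="session")
def table():
    """The bundled published rate table (regimens A, B, C)."""
    return tk.default_parameter_table()


@pytest.fixture(scope="session")
def standard():
    """Standard initial tumor: 1e9 cells, X0=Y0=1e4, Z0=10, W the rest."""
    return tk.standard_initial_state()
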