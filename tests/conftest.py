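import pytest

from chemoval import bbd_table, fit_quadratic
from chemoval.synth import make_component_library


@pytest.fixture(scope="session")
def design():
    """The bundled 17-run chromatographic Box-Behnken study."""
    return bbd_table()


@pytest.fixture(scope="session")
def models(design):
    """Fitted quadratic surfaces for both responses of the bundled study."""
    return {name: fit_quadratic(design, name) for name in ("Rs", "Rt")}


@pytest.fixture(scope="session")
def library():
    """Default two-component synthetic spectral library (unit absorptivity)."""
    return make_component_library()
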