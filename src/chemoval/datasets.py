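"""Bundled example data: the 17-run Box-Behnken chromatographic study."""

from __future__ import annotations

from importlib import resources

from .doe import DesignTable, FactorSpec
from .io import read_design_csv

#: the three chromatographic factors of the bundled study
BBD_FACTORS = (
    FactorSpec("temperature_C", 25.0, 30.0, 35.0, units="degC"),
    FactorSpec("acn_pct", 60.0, 65.0, 70.0, units="%"),
    FactorSpec("pH", 3.0, 5.0, 7.0),
)


def bbd_table() -> DesignTable:
    """The bundled 17-run Box-Behnken design (column temperature, %ACN, pH)
    with measured resolution ``Rs`` and retention time ``Rt`` (min)."""
    with resources.as_file(
            resources.files("chemoval.data").joinpath("bbd_runs.csv")) as path:
        return read_design_csv(path, BBD_FACTORS)
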