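"""CSV/JSON readers and writers for the package's interchange dialects.

All files are UTF-8 comma-separated text with ``#`` comment headers; numbers
are serialized with 12 significant digits so read(write(x)) round-trips to
the tolerance the analyses care about.  Parse failures name the offending
line.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .capability import CapabilitySeries
from .doe import DesignTable, FactorSpec, QuadraticSurfaceModel
from .spectra import Spectrum
from .stability import StabilitySeries

_FMT = "%.12g"


class ParseError(ValueError):
    """A file did not conform to its documented dialect."""

    def __init__(self, path, line: int | None, message: str):
        self.path, self.line = str(path), line
        where = f"{path}" + (f", line {line}" if line is not None else "")
        super().__init__(f"{where}: {message}")


def write_spectrum_csv(spectrum: Spectrum, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if spectrum.label:
            fh.write(f"# label={spectrum.label}\n")
        if spectrum.concentration is not None:
            fh.write(f"# conc_ug_per_ml={_FMT % spectrum.concentration}\n")
        truth = spectrum.meta.get("truth")
        if truth is not None:
            fh.write(f"# truth={json.dumps(truth)}\n")
        fh.write("wavelength_nm,absorbance\n")
        for lam, ab in zip(spectrum.wavelengths, spectrum.absorbance):
            fh.write(f"{_FMT % lam},{_FMT % ab}\n")


def read_spectrum_csv(path) -> Spectrum:
    path = Path(path)
    label, conc, meta = "", None, {}
    lams, abs_ = [], []
    header_seen = False
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("label="):
                label = body[len("label="):]
            elif body.startswith("conc_ug_per_ml="):
                conc = float(body[len("conc_ug_per_ml="):])
            elif body.startswith("truth="):
                meta["truth"] = json.loads(body[len("truth="):])
            continue
        if not header_seen:
            if line.replace(" ", "") != "wavelength_nm,absorbance":
                raise ParseError(path, lineno,
                                 "expected header 'wavelength_nm,absorbance'")
            header_seen = True
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise ParseError(path, lineno, f"expected 2 columns, got {len(parts)}")
        try:
            lams.append(float(parts[0]))
            abs_.append(float(parts[1]))
        except ValueError:
            raise ParseError(path, lineno, f"non-numeric cell in {line!r}") from None
    if not header_seen:
        raise ParseError(path, None, "missing header row")
    try:
        return Spectrum(np.array(lams), np.array(abs_), label=label,
                        concentration=conc, meta=meta)
    except ValueError as exc:
        raise ParseError(path, None, str(exc)) from None


def write_design_csv(design: DesignTable, path) -> None:
    design.to_frame().to_csv(path, index=False, float_format=_FMT)


def read_design_csv(path, factors) -> DesignTable:
    """Read a design table (actual units) and derive the coded matrix.

    Expected columns: ``std,run,<factor names...>,<response names...>``.
    """
    path = Path(path)
    factors = tuple(factors)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise ParseError(path, None, f"unreadable CSV: {exc}") from None
    required = ["std", "run"] + [f.name for f in factors]
    for col in required:
        if col not in df.columns:
            raise ParseError(path, None, f"missing column {col!r}")
    response_cols = [c for c in df.columns if c not in required]
    for col in required[2:] + response_cols:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise ParseError(path, int(bad[0]) + 2,
                             f"non-numeric or missing value in column {col!r}")
    coded = np.column_stack([
        f.code(df[f.name].to_numpy(dtype=float)) for f in factors])
    responses = {c: df[c].to_numpy(dtype=float) for c in response_cols}
    return DesignTable(factors=factors, coded=coded,
                       std_order=df["std"].to_numpy(dtype=int),
                       run_order=df["run"].to_numpy(dtype=int),
                       responses=responses)


def write_anova_csv(table, path) -> None:
    table.to_frame().to_csv(path, index=False, float_format=_FMT)


def write_model_json(model: QuadraticSurfaceModel, path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2) + "\n",
                          encoding="utf-8")


def read_model_json(path) -> QuadraticSurfaceModel:
    return QuadraticSurfaceModel.from_dict(
        json.loads(Path(path).read_text(encoding="utf-8")))


def read_batches_csv(path, subgroup_size: int = 1, lsl=None, usl=None) -> CapabilitySeries:
    """Read ``batch_id,subgroup,value`` rows, ordered by appearance."""
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise ParseError(path, None, f"unreadable CSV: {exc}") from None
    for col in ("batch_id", "subgroup", "value"):
        if col not in df.columns:
            raise ParseError(path, None, f"missing column {col!r}")
    bad = df.index[pd.to_numeric(df["value"], errors="coerce").isna()]
    if len(bad):
        raise ParseError(path, int(bad[0]) + 2, "non-numeric value cell")
    return CapabilitySeries(values=df["value"].to_numpy(dtype=float),
                            subgroup_size=subgroup_size, lsl=lsl, usl=usl)


def read_stability_csv(path) -> list:
    """Read ``product,analyte,month,assay`` rows into StabilitySeries
    (one per product/analyte pair, in order of first appearance)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise ParseError(path, None, f"unreadable CSV: {exc}") from None
    for col in ("product", "analyte", "month", "assay"):
        if col not in df.columns:
            raise ParseError(path, None, f"missing column {col!r}")
    out = []
    for (product, analyte), grp in df.groupby(["product", "analyte"], sort=False):
        out.append(StabilitySeries(product=str(product), analyte=str(analyte),
                                   months=grp["month"].to_numpy(dtype=float),
                                   assays=grp["assay"].to_numpy(dtype=float)))
    return out


def write_report(payload: dict, path, fmt: str = "json") -> None:
    """Write an analysis report as JSON or a flat markdown table."""
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(payload, indent=2, default=_jsonify) + "\n",
                        encoding="utf-8")
    elif fmt == "markdown":
        lines = ["| key | value |", "| --- | --- |"]
        for key, value in payload.items():
            lines.append(f"| {key} | {_mdify(value)} |")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown report format {fmt!r}")


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "to_dict"):
        return obj.to_dict()
    raise TypeError(f"cannot serialize {type(obj).__name__}")


def _mdify(value):
    if isinstance(value, float):
        return _FMT % value
    return str(value)
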