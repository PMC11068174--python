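"""CSV schemas for the series containers.

Spectra: ``time_min,a_1680,...`` (one column per channel, named from the
wavelength grid). Reference: ``time_min,analyte,value,device``.
Concentrations: ``time_min,glucose_mgdl,bhb_mM,lactate_mM,ethanol_mM`` plus
one ``<compound>_mM`` column per scheduled confounder. Round-trips are
lossless to full float precision (written with repr-level digits).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .forward import ReferenceSeries, SpectraSeries
from .visits import ConcentrationSeries

__all__ = [
    "SchemaError",
    "write_spectra", "read_spectra",
    "write_reference", "read_reference",
    "write_concentrations", "read_concentrations",
]

_FLOAT_FMT = "%.17g"


class SchemaError(ValueError):
    """A CSV does not match the documented schema."""


def _require_columns(df: pd.DataFrame, required: list[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _check_monotone_time(df: pd.DataFrame, path: Path) -> None:
    t = df["time_min"].to_numpy(float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        # +2: one for the header line, one for 0- vs 1-based indexing
        raise SchemaError(f"{path}: time_min not strictly increasing at line {bad[0] + 2}")


def write_spectra(spectra: SpectraSeries, path: str | Path) -> None:
    spectra.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_spectra(path: str | Path) -> SpectraSeries:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["time_min"], path)
    chan_cols = [c for c in df.columns if c.startswith("a_")]
    if not chan_cols:
        raise SchemaError(f"{path}: no absorbance channel columns (a_<nm>)")
    try:
        wl = np.array([float(c[2:]) for c in chan_cols])
    except ValueError as err:
        raise SchemaError(f"{path}: malformed channel column name: {err}") from err
    order = np.argsort(wl)
    if df[chan_cols].isna().any().any():
        raise SchemaError(f"{path}: missing absorbance values")
    _check_monotone_time(df, path)
    return SpectraSeries(
        time_min=df["time_min"].to_numpy(float),
        absorbance=df[chan_cols].to_numpy(float)[:, order],
        wavelengths_nm=wl[order],
    )


def write_reference(reference: ReferenceSeries, path: str | Path) -> None:
    reference.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_reference(path: str | Path) -> ReferenceSeries:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["time_min", "analyte", "value", "device"], path)
    _check_monotone_time(df, path)
    analytes = df["analyte"].unique()
    devices = df["device"].unique()
    if len(analytes) != 1 or len(devices) != 1:
        raise SchemaError(f"{path}: expected a single analyte/device per file")
    return ReferenceSeries(
        time_min=df["time_min"].to_numpy(float),
        values=df["value"].to_numpy(float),
        analyte=str(analytes[0]),
        device=str(devices[0]),
    )


def write_concentrations(series: ConcentrationSeries, path: str | Path) -> None:
    series.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_concentrations(path: str | Path) -> ConcentrationSeries:
    path = Path(path)
    df = pd.read_csv(path)
    base = ["time_min", "glucose_mgdl", "bhb_mM", "lactate_mM", "ethanol_mM"]
    _require_columns(df, base, path)
    _check_monotone_time(df, path)
    confounders = {
        c[:-3]: df[c].to_numpy(float)
        for c in df.columns if c.endswith("_mM") and c not in base
    }
    return ConcentrationSeries(
        time_min=df["time_min"].to_numpy(float),
        glucose_mgdl=df["glucose_mgdl"].to_numpy(float),
        bhb_mM=df["bhb_mM"].to_numpy(float),
        lactate_mM=df["lactate_mM"].to_numpy(float),
        ethanol_mM=df["ethanol_mM"].to_numpy(float),
        confounders_mM=confounders,
    )
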