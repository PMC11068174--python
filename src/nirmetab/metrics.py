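"""CGM-style accuracy statistics: MAD, MARD, glycemic-stratum breakdown,
consensus error-grid zone counts and rate-of-change grid summaries."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errorgrids import ErrorGridGeometry, ZONES, load_parkes_t1d, load_rate_grid, \
    parkes_zone, rate_grid_zone

__all__ = [
    "AccuracyReport",
    "mad",
    "mard",
    "stratified_accuracy",
    "rate_pairs",
    "rate_grid_summary",
    "accuracy_report",
    "DEFAULT_STRATUM_EDGES",
]

#: Glycemic stratum edges in mg/dl: hypo 40-70, eu 70-180, hyper >180; pairs
#: with reference below 40 are reported in an extra "<40" stratum.
DEFAULT_STRATUM_EDGES = (40.0, 70.0, 180.0, math.inf)


def mad(reference: np.ndarray, predicted: np.ndarray) -> float:
    """Mean absolute difference, in the analyte's units."""
    ref = np.asarray(reference, float)
    pred = np.asarray(predicted, float)
    if ref.shape != pred.shape or ref.ndim != 1:
        raise ValueError("reference and predicted must be 1-D of equal length")
    if len(ref) == 0:
        raise ValueError("need at least one pair")
    return float(np.mean(np.abs(pred - ref)))


def mard(reference: np.ndarray, predicted: np.ndarray) -> float:
    """Mean absolute relative difference as a percentage of the reference."""
    ref = np.asarray(reference, float)
    pred = np.asarray(predicted, float)
    if ref.shape != pred.shape or ref.ndim != 1:
        raise ValueError("reference and predicted must be 1-D of equal length")
    if len(ref) == 0:
        raise ValueError("need at least one pair")
    if np.any(ref <= 0):
        raise ValueError("all reference values must be > 0 for MARD")
    return float(100.0 * np.mean(np.abs(pred - ref) / ref))


def stratified_accuracy(
    reference: np.ndarray,
    predicted: np.ndarray,
    bounds: tuple[float, ...] = DEFAULT_STRATUM_EDGES,
) -> pd.DataFrame:
    """Per-stratum MAD/MARD with half-open strata [low, high).

    Returns one row per stratum (plus a "<40"-style row for references below
    the first edge when present) with columns stratum, n, mad, mard; empty
    strata get n=0 and null metrics.
    """
    if any(b >= c for b, c in zip(bounds, bounds[1:])):
        raise ValueError("stratum bounds must be strictly increasing")
    ref = np.asarray(reference, float)
    pred = np.asarray(predicted, float)
    rows = []
    below = ref < bounds[0]
    if below.any():
        rows.append({
            "stratum": f"<{bounds[0]:g}",
            "n": int(below.sum()),
            "mad": mad(ref[below], pred[below]),
            "mard": mard(ref[below], pred[below]) if np.all(ref[below] > 0) else None,
        })
    for lo, hi in zip(bounds, bounds[1:]):
        m = (ref >= lo) & (ref < hi)
        label = f">{lo:g}" if math.isinf(hi) else f"{lo:g}-{hi:g}"
        if m.any():
            rows.append({"stratum": label, "n": int(m.sum()),
                         "mad": mad(ref[m], pred[m]), "mard": mard(ref[m], pred[m])})
        else:
            rows.append({"stratum": label, "n": 0, "mad": None, "mard": None})
    return pd.DataFrame(rows)


def rate_pairs(
    times: np.ndarray,
    reference: np.ndarray,
    predicted: np.ndarray,
    window: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Finite-difference rates over consecutive samples, in units per minute.

    Only consecutive gaps within +-50% of ``window`` minutes are used; if no
    gap qualifies, empty arrays are returned with a warning.
    """
    t = np.asarray(times, float)
    if len(t) < 2:
        raise ValueError("need at least 2 time points for rates")
    dt = np.diff(t)
    ok = (dt >= 0.5 * window) & (dt <= 1.5 * window)
    if not ok.any():
        import warnings
        warnings.warn(f"no consecutive gaps within 50% of {window} min; no rates computed")
        return np.empty(0), np.empty(0)
    ref_rate = np.diff(np.asarray(reference, float))[ok] / dt[ok]
    pred_rate = np.diff(np.asarray(predicted, float))[ok] / dt[ok]
    return ref_rate, pred_rate


def rate_grid_summary(
    reference_rates: np.ndarray,
    predicted_rates: np.ndarray,
    geometry: ErrorGridGeometry | None = None,
) -> dict[str, float]:
    """Per-zone fractions on the rate error grid, plus the combined A+B."""
    if len(reference_rates) == 0:
        raise ValueError("need at least one rate pair")
    zones = rate_grid_zone(reference_rates, predicted_rates, geometry)
    n = len(zones)
    out = {z: float(np.sum(zones == z)) / n for z in ZONES}
    out["A+B"] = out["A"] + out["B"]
    return out


@dataclass
class AccuracyReport:
    """Accuracy summary of one analyte's cross-validated predictions."""

    analyte: str
    n: int
    mad: float
    mard: float | None
    n_mard: int
    strata: pd.DataFrame | None = None
    parkes_counts: dict[str, int] | None = None
    parkes_fractions: dict[str, float] | None = None
    rate_zone_fractions: dict[str, float] | None = None

    def to_dict(self) -> dict:
        return {
            "analyte": self.analyte,
            "n": self.n,
            "mad": self.mad,
            "mard_percent": self.mard,
            "n_mard": self.n_mard,
            "strata": None if self.strata is None else self.strata.to_dict("records"),
            "parkes_counts": self.parkes_counts,
            "parkes_fractions": self.parkes_fractions,
            "rate_zone_fractions": self.rate_zone_fractions,
        }


def accuracy_report(
    times: np.ndarray,
    reference: np.ndarray,
    predicted: np.ndarray,
    analyte: str = "glucose",
    stratum_edges: tuple[float, ...] = DEFAULT_STRATUM_EDGES,
    rate_window: float = 5.0,
) -> AccuracyReport:
    """Full accuracy report for one analyte.

    Glucose gets the stratified breakdown, consensus error-grid zone counts
    and the rate-grid summary; other analytes report MAD and MARD only.
    MARD is computed over the pairs with strictly positive reference (the
    ethanol reference is exactly zero before intake), with that pair count
    reported as ``n_mard``.
    """
    ref = np.asarray(reference, float)
    pred = np.asarray(predicted, float)
    pos = ref > 0
    overall_mad = mad(ref, pred)
    overall_mard = mard(ref[pos], pred[pos]) if pos.any() else None

    strata = parkes_counts = parkes_fractions = rate_fracs = None
    if analyte == "glucose":
        strata = stratified_accuracy(ref, pred, stratum_edges)
        geometry = load_parkes_t1d()
        zones = parkes_zone(np.clip(ref, 0, 550), np.clip(pred, 0, 550), geometry)
        parkes_counts = {z: int(np.sum(zones == z)) for z in ZONES}
        parkes_fractions = {z: parkes_counts[z] / len(ref) for z in ZONES}
        rr, pr = rate_pairs(times, ref, pred, window=rate_window)
        if len(rr):
            rate_fracs = rate_grid_summary(rr, pr, load_rate_grid())

    return AccuracyReport(
        analyte=analyte, n=len(ref), mad=overall_mad, mard=overall_mard,
        n_mard=int(pos.sum()), strata=strata, parkes_counts=parkes_counts,
        parkes_fractions=parkes_fractions, rate_zone_fractions=rate_fracs,
    )
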