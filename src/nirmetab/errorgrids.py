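"""Clinical error-grid geometries and zone classification.

The consensus (Parkes) error grid for type 1 diabetes partitions the
reference-vs-measured glucose plane ([0, 550] mg/dl on both axes) into
zones A-E of increasing clinical risk. The zone boundaries are nested
polylines encoded from the published consensus vertex table, shipped as a
versioned CSV so the geometry is inspectable and swappable. A point's zone
is the number of boundaries it strictly crosses away from the identity
line; points exactly on a boundary therefore fall in the lower-risk zone.

The rate grid applies the same zone idea to the (reference rate, predicted
rate) plane in mg/dl/min, with symmetric bands around the identity line.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "ErrorGridGeometry",
    "load_parkes_t1d",
    "load_rate_grid",
    "parkes_zone",
    "rate_grid_zone",
]

ZONES = ("A", "B", "C", "D", "E")
AXIS_MAX = 550.0
_EPS = 1e-9


@dataclass(frozen=True)
class ErrorGridGeometry:
    """Zone boundary geometry of one grid variant.

    For ``parkes_t1d``, ``boundaries`` maps (separator, side) — e.g.
    ``("AB", "upper")`` — to an (x, y) vertex array; for ``rate_grid``,
    ``rate_bands`` maps zone letter to the maximal absolute rate error.
    """

    variant: str
    format_version: int
    boundaries: dict[tuple[str, str], np.ndarray] | None = None
    rate_bands: dict[str, float] | None = None


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("nirmetab.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_parkes_t1d() -> ErrorGridGeometry:
    """Type-1-diabetes consensus error grid from the packaged vertex table."""
    df = _read_packaged("parkes_t1d.csv")
    boundaries: dict[tuple[str, str], np.ndarray] = {}
    for (sep, side), grp in df.groupby(["boundary", "side"]):
        grp = grp.sort_values("order")
        boundaries[(sep, side)] = grp[["x", "y"]].to_numpy(float)
    return ErrorGridGeometry(variant="parkes_t1d",
                             format_version=int(df["format_version"].iloc[0]),
                             boundaries=boundaries)


def load_rate_grid() -> ErrorGridGeometry:
    """Symmetric rate-difference band geometry for the rate error grid."""
    df = _read_packaged("rate_grid.csv")
    bands = dict(zip(df["zone"], df["max_abs_rate_error"].astype(float)))
    return ErrorGridGeometry(variant="rate_grid",
                             format_version=int(df["format_version"].iloc[0]),
                             rate_bands=bands)


def _boundary_y(vertices: np.ndarray, x: np.ndarray, side: str) -> np.ndarray:
    """Boundary height at reference value x, with out-of-range fills chosen
    so that a point beyond the polyline can never count as crossed.

    Vertical segments (repeated x) are nudged by an epsilon so interpolation
    takes the pre-vertical value exactly at the shared x, which implements
    the on-boundary -> lower-risk-zone convention together with the strict
    comparisons in :func:`parkes_zone`.
    """
    xs = vertices[:, 0].astype(float).copy()
    ys = vertices[:, 1].astype(float)
    for i in range(1, len(xs)):
        if xs[i] <= xs[i - 1]:
            xs[i] = xs[i - 1] + _EPS
    if side == "upper":
        # boundaries terminating at the top edge before x=550 cannot be
        # exceeded further right
        right = np.inf if xs[-1] < AXIS_MAX - _EPS else ys[-1]
        return np.interp(x, xs, ys, left=ys[0], right=right)
    # lower boundaries start at x>0: nothing to the left can be below them
    return np.interp(x, xs, ys, left=-np.inf, right=ys[-1])


def parkes_zone(
    reference: np.ndarray | float,
    predicted: np.ndarray | float,
    geometry: ErrorGridGeometry | None = None,
) -> np.ndarray | str:
    """Consensus error grid zone(s) for reference/predicted glucose (mg/dl).

    Vectorized; scalar inputs return a scalar zone letter. Raises on values
    outside [0, 550].
    """
    if geometry is None:
        geometry = load_parkes_t1d()
    if geometry.boundaries is None:
        raise ValueError(f"geometry {geometry.variant!r} has no boundary polylines")
    ref = np.atleast_1d(np.asarray(reference, float))
    pred = np.atleast_1d(np.asarray(predicted, float))
    if ref.shape != pred.shape:
        raise ValueError("reference and predicted must have the same shape")
    for arr, name in ((ref, "reference"), (pred, "predicted")):
        if np.any((arr < 0) | (arr > AXIS_MAX)):
            raise ValueError(f"{name} values must lie within [0, {AXIS_MAX}] mg/dl")

    uppers = np.zeros(ref.shape, int)
    lowers = np.zeros(ref.shape, int)
    for sep in ("AB", "BC", "CD", "DE"):
        if (sep, "upper") in geometry.boundaries:
            yb = _boundary_y(geometry.boundaries[(sep, "upper")], ref, "upper")
            uppers += (pred > yb).astype(int)
        if (sep, "lower") in geometry.boundaries:
            yb = _boundary_y(geometry.boundaries[(sep, "lower")], ref, "lower")
            lowers += (pred < yb).astype(int)
    n_crossed = np.maximum(uppers, lowers)
    zones = np.array(ZONES)[n_crossed]
    if np.isscalar(reference) or np.ndim(reference) == 0:
        return str(zones[0])
    return zones


def rate_grid_zone(
    reference_rate: np.ndarray | float,
    predicted_rate: np.ndarray | float,
    geometry: ErrorGridGeometry | None = None,
) -> np.ndarray | str:
    """Rate error grid zone(s) for rates of change in mg/dl/min."""
    if geometry is None:
        geometry = load_rate_grid()
    if geometry.rate_bands is None:
        raise ValueError(f"geometry {geometry.variant!r} has no rate bands")
    rr = np.atleast_1d(np.asarray(reference_rate, float))
    pr = np.atleast_1d(np.asarray(predicted_rate, float))
    err = np.abs(pr - rr)
    zones = np.full(err.shape, "E", dtype=object)
    for zone in reversed(ZONES):  # assign from worst to best; best wins ties
        if zone in geometry.rate_bands:
            zones[err <= geometry.rate_bands[zone]] = zone
    out = zones.astype(str)
    if np.isscalar(reference_rate) or np.ndim(reference_rate) == 0:
        return str(out[0])
    return out
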