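"""Backward air-mass trajectory scoring: sea time and loading conditions.

Each 5-day backward trajectory (120 hourly points ending above the
sampling site) is classified point by point: "sea" when the nearest
land-mask cell is water, "loading" when the point sits within the mixing
layer (altitude <= boundary-layer height) AND surface wind exceeds
3 m/s (strict).  Event summaries average per-trajectory fractions over
the first 96 h (four days) by default.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Expected columns of a trajectory point table.
TRAJ_COLUMNS = (
    "traj_id",
    "hours_before",
    "lat",
    "lon",
    "altitude",
    "blh",
    "wind",
    "land",
)


def read_trajectories(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRAJ_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"trajectory table missing column(s): {missing}")
    return df


def nearest_grid_annotation(
    points: pd.DataFrame,
    grid_lats: np.ndarray,
    grid_lons: np.ndarray,
    fields: Mapping[str, np.ndarray],
) -> pd.DataFrame:
    """Annotate points with nearest-cell values of gridded model fields.

    The grid is regular in lat/lon; nearness is Euclidean in degrees, and
    an equidistant point takes the lowest-index cell (row-major over
    lat then lon).  Points outside the grid's bounding box raise.
    """
    glat = np.asarray(grid_lats, dtype=float)
    glon = np.asarray(grid_lons, dtype=float)
    lat = points["lat"].to_numpy(dtype=float)
    lon = points["lon"].to_numpy(dtype=float)
    if (
        lat.min() < glat.min() or lat.max() > glat.max()
        or lon.min() < glon.min() or lon.max() > glon.max()
    ):
        raise ValidationError("trajectory point outside field grid bounds")
    # full pairwise distances; argmin returns the first (lowest) index on ties
    d2 = (lat[:, None] - glat[None, :]) ** 2
    i_lat = np.argmin(d2, axis=1)
    d2 = (lon[:, None] - glon[None, :]) ** 2
    i_lon = np.argmin(d2, axis=1)
    out = points.copy()
    for name, values in fields.items():
        arr = np.asarray(values)
        if arr.shape != (glat.size, glon.size):
            raise ValidationError(f"field {name!r} shape does not match grid")
        out[name] = arr[i_lat, i_lon]
    return out


def classify_points(
    trajectory: pd.DataFrame,
    wind_threshold: float = 3.0,
    require_sea_for_loading: bool = False,
) -> pd.DataFrame:
    """Add per-point ``sea``, ``loading``, and ``evaluable`` flags.

    sea = not land; loading = within the mixing layer (altitude <= BLH)
    and surface wind strictly greater than the threshold.  Points missing
    BLH or wind are flagged unevaluable and drop out of denominators.
    """
    df = trajectory.copy()
    df["sea"] = ~df["land"].astype(bool)
    evaluable = ~(df["blh"].isna() | df["wind"].isna())
    in_ml = df["altitude"] <= df["blh"]
    windy = df["wind"] > wind_threshold
    loading = in_ml & windy & evaluable
    if require_sea_for_loading:
        loading &= df["sea"]
    df["loading"] = loading.fillna(False)
    df["evaluable"] = evaluable
    return df


def trajectory_summary(
    trajectory: pd.DataFrame, window_hours: int = 96
) -> tuple[float, float]:
    """(sea_fraction, loading_fraction) over the first ``window_hours`` points."""
    win = trajectory[trajectory["hours_before"] < window_hours]
    win = win[win["evaluable"]] if "evaluable" in win.columns else win
    n = len(win)
    if n == 0:
        raise ValidationError("empty evaluation window")
    return float(win["sea"].sum()) / n, float(win["loading"].sum()) / n


def event_summary(
    trajectories: pd.DataFrame,
    events: Optional[Mapping[str, str]] = None,
    window_hours: int = 96,
    wind_threshold: float = 3.0,
    require_sea_for_loading: bool = False,
) -> pd.DataFrame:
    """Per-event mean sea/loading fractions over classified trajectories.

    ``events`` maps trajectory id to an event label; unmapped trajectories
    form the event "all".  The event value is the unweighted mean of the
    per-trajectory fractions.
    """
    rows = []
    for tj_id, grp in trajectories.groupby("traj_id", sort=True):
        cls = classify_points(
            grp.sort_values("hours_before"),
            wind_threshold=wind_threshold,
            require_sea_for_loading=require_sea_for_loading,
        )
        sea, loading = trajectory_summary(cls, window_hours)
        rows.append(
            {
                "traj_id": tj_id,
                "event": (events or {}).get(tj_id, "all"),
                "sea_fraction": sea,
                "loading_fraction": loading,
            }
        )
    per_tj = pd.DataFrame(rows)
    out = (
        per_tj.groupby("event")
        .agg(
            n_trajectories=("traj_id", "size"),
            sea_fraction=("sea_fraction", "mean"),
            loading_fraction=("loading_fraction", "mean"),
        )
        .reset_index()
    )
    return out
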