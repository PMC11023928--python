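"""Independent detection events and sampling effort.

A camera records a burst of photos whenever an animal triggers it, so raw
photo counts overstate abundance.  Photos of the same species at the same
camera are collapsed into *independent detection events*: a photo joins the
current event while its gap to the previous photo is below a temporal
threshold (10 min by default), and a gap of at least the threshold starts a
new event.  The event's group size is the maximum per-photo individual
count among its members.

Sampling effort is the number of active camera-days: the deployment span,
truncated where the photo stream (status photos every 12 h plus animal
photos) shows the camera died early, minus any recorded downtime.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DetectionEvent", "EffortTable", "build_events", "sensitivity_table", "compute_effort"]

DEFAULT_THRESHOLD_MIN = 10.0
DEFAULT_SENSITIVITY_THRESHOLDS = (10.0, 30.0, 60.0, 1440.0)
STATUS_INTERVAL_H = 12.0

EVENT_COLUMNS = ("camera_id", "species_label", "start_time", "end_time", "group_size", "n_photos")


@dataclass(frozen=True)
class DetectionEvent:
    """One temporally clustered, species-specific observation."""

    camera_id: str
    species_label: str
    start_time: pd.Timestamp
    end_time: pd.Timestamp
    group_size: int
    n_photos: int


@dataclass(frozen=True)
class EffortTable:
    """Active camera-days per camera and summed per concession."""

    camera: pd.DataFrame  # camera_id, concession_id, pair_id, certified, active_days
    concession: pd.DataFrame  # concession_id, pair_id, certified, camera_days


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "camera_id": pd.Series(dtype=object),
            "species_label": pd.Series(dtype=object),
            "start_time": pd.Series(dtype="datetime64[ns]"),
            "end_time": pd.Series(dtype="datetime64[ns]"),
            "group_size": pd.Series(dtype=int),
            "n_photos": pd.Series(dtype=int),
        }
    )


def build_events(
    photos: pd.DataFrame,
    threshold_minutes: float = DEFAULT_THRESHOLD_MIN,
    anchor: str = "last_photo",
) -> pd.DataFrame:
    """Collapse animal photos into independent detection events.

    Parameters
    ----------
    photos
        Validated photo table; status photos are ignored here.
    threshold_minutes
        Independence threshold.  Two consecutive photos of the same species
        at the same camera that are at least this far apart belong to
        separate events (gap >= threshold splits; gap < threshold chains).
    anchor
        ``"last_photo"`` (default) measures each gap from the previous photo
        in the event; ``"event_start"`` measures from the event's first
        photo, which caps event duration at the threshold.
    """
    if threshold_minutes <= 0:
        raise ValueError("threshold_minutes must be positive")
    if anchor not in ("last_photo", "event_start"):
        raise ValueError("anchor must be 'last_photo' or 'event_start'")

    df = photos.loc[~photos["is_status_photo"].astype(bool)].copy()
    if df.empty:
        return _empty_events()
    ndup = df.duplicated(["camera_id", "species_label", "timestamp", "n_individuals"]).sum()
    if ndup:
        warnings.warn(f"collapsing {ndup} duplicate photo rows", stacklevel=2)
        df = df.drop_duplicates(["camera_id", "species_label", "timestamp", "n_individuals"])

    df = df.sort_values(["camera_id", "species_label", "timestamp"], kind="mergesort")
    thr = pd.Timedelta(minutes=threshold_minutes)
    key_change = (
        (df["camera_id"] != df["camera_id"].shift())
        | (df["species_label"] != df["species_label"].shift())
    )

    if anchor == "last_photo":
        gap = df["timestamp"].diff()
        new_event = key_change | (gap >= thr)
        ev_id = new_event.cumsum()
    else:
        ev_id = _event_start_ids(df, key_change.to_numpy(), thr)

    grouped = df.groupby(ev_id, sort=True)
    out = grouped.agg(
        camera_id=("camera_id", "first"),
        species_label=("species_label", "first"),
        start_time=("timestamp", "first"),
        end_time=("timestamp", "last"),
        group_size=("n_individuals", "max"),
        n_photos=("timestamp", "size"),
    ).reset_index(drop=True)
    out["group_size"] = out["group_size"].astype(int)
    out["n_photos"] = out["n_photos"].astype(int)
    return out


def _event_start_ids(df: pd.DataFrame, key_change: np.ndarray, thr: pd.Timedelta) -> np.ndarray:
    ts = df["timestamp"].to_numpy()
    ids = np.empty(len(df), dtype=np.int64)
    eid = 0
    anchor_t = None
    for i in range(len(df)):
        if key_change[i] or (ts[i] - anchor_t) >= thr:
            eid += 1
            anchor_t = ts[i]
        ids[i] = eid
    return ids


def sensitivity_table(
    photos: pd.DataFrame,
    traits: pd.DataFrame,
    thresholds=DEFAULT_SENSITIVITY_THRESHOLDS,
    anchor: str = "last_photo",
) -> pd.DataFrame:
    """Event counts per independence threshold and body-mass class.

    Returns a tidy table (threshold_minutes, body_mass_class, n_events,
    proportion) where ``proportion`` is the class's share of events at that
    threshold — used to check that the choice of threshold does not distort
    the community composition.
    """
    thresholds = tuple(thresholds)
    if not thresholds:
        raise ValueError("thresholds must be non-empty")
    class_of = dict(zip(traits["species_label"], traits["body_mass_class"]))
    rows = []
    for thr in thresholds:
        ev = build_events(photos, threshold_minutes=thr, anchor=anchor)
        if ev.empty:
            continue
        cls = ev["species_label"].map(class_of)
        counts = cls.value_counts()
        total = int(counts.sum())
        for label, n in counts.items():
            rows.append((thr, label, int(n), n / total))
    return pd.DataFrame(
        rows, columns=["threshold_minutes", "body_mass_class", "n_events", "proportion"]
    )


def compute_effort(
    deployments: pd.DataFrame,
    photos: pd.DataFrame,
    status_interval_h: float = STATUS_INTERVAL_H,
) -> EffortTable:
    """Active camera-days per camera, aggregated per concession.

    The active window of a camera ends at ``min(scheduled end, last photo
    + status interval)`` — a camera whose photo stream (status or animal)
    stops early is assumed dead one status interval after its last photo —
    and recorded ``downtime_days`` are then subtracted.  Effort is reported
    in fractional days and never negative.
    """
    unknown = set(photos["camera_id"].unique()) - set(deployments["camera_id"])
    if unknown:
        raise ValueError(f"photos reference cameras with no deployment record: {sorted(unknown)}")

    last = photos.groupby("camera_id")["timestamp"].max()
    dep = deployments.set_index("camera_id")
    grace = pd.Timedelta(hours=status_interval_h)

    window_end = dep["end"].copy()
    has_photos = dep.index.isin(last.index)
    window_end.loc[has_photos] = np.minimum(
        dep.loc[has_photos, "end"], last.reindex(dep.index[has_photos]) + grace
    )
    if (~has_photos).any():
        warnings.warn(
            f"{(~has_photos).sum()} deployed cameras have no photos at all; "
            "their effort is 0",
            stacklevel=2,
        )
        window_end.loc[~has_photos] = dep.loc[~has_photos, "start"]

    active = (window_end - dep["start"]).dt.total_seconds() / 86400.0 - dep["downtime_days"]
    active = active.clip(lower=0.0)
    nzero = int((active <= 0).sum())
    if nzero:
        warnings.warn(f"{nzero} cameras have zero active days", stacklevel=2)

    camera = pd.DataFrame(
        {
            "camera_id": dep.index,
            "concession_id": dep["concession_id"].to_numpy(),
            "pair_id": dep["pair_id"].to_numpy(),
            "certified": dep["certified"].to_numpy(),
            "active_days": active.to_numpy(),
        }
    ).reset_index(drop=True)
    concession = (
        camera.groupby(["concession_id", "pair_id", "certified"], as_index=False)["active_days"]
        .sum()
        .rename(columns={"active_days": "camera_days"})
    )
    return EffortTable(camera=camera, concession=concession)
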