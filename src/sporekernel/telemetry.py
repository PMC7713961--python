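"""GPS telemetry ingestion, cleaning, and ingestion-window extraction.

A *track* is the time-ordered sequence of GPS fixes from one continuous
deployment (tracking period) of a telemetry unit on one animal.  The kernel
pipeline needs, for every fix that could be a spore-ingestion event, the
straight-line displacement of the animal from that fix over the following
gut-retention window (69 h by default).  This module reads delimited-text
telemetry, applies the fix-quality and warm-up filters, and slices tracks
into those ingestion windows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: mean Earth radius used for great-circle distances, metres
EARTH_RADIUS_M = 6_371_000.0

#: metres per degree of latitude implied by EARTH_RADIUS_M
METERS_PER_DEGREE = math.pi * EARTH_RADIUS_M / 180.0

#: default CSV column names; override any of them via ``column_map``
DEFAULT_COLUMNS: dict[str, str] = {
    "animal_id": "animal_id",
    "period_id": "period_id",
    "timestamp": "timestamp",
    "lat": "lat",
    "lon": "lon",
    "x": "x_m",
    "y": "y_m",
    "quality": "nsat",
}


class TelemetryError(ValueError):
    """Malformed telemetry input (bad columns, unparseable rows)."""


class EmptyTrackError(ValueError):
    """A filtering step left fewer than two usable fixes in a period."""


@dataclass(frozen=True)
class Fix:
    """A single GPS position record."""

    animal_id: str
    period_id: str
    time: pd.Timestamp
    lat: float  # degrees WGS84, or metres northing in projected mode
    lon: float  # degrees WGS84, or metres easting in projected mode
    quality: int | None = None
    crs: str = "geographic"

    def __post_init__(self) -> None:
        if self.crs == "geographic":
            if not (-90.0 <= self.lat <= 90.0):
                raise TelemetryError(f"latitude {self.lat} outside [-90, 90]")
            if not (-180.0 <= self.lon <= 180.0):
                raise TelemetryError(f"longitude {self.lon} outside [-180, 180]")
        if pd.isna(self.time):
            raise TelemetryError("fix timestamp is missing or not finite")


@dataclass
class Track:
    """Time-ordered fixes for one tracking period of one animal.

    Coordinates are stored as parallel arrays; ``crs`` is either
    ``"geographic"`` (lat/lon degrees, great-circle distances) or
    ``"projected"`` (metres, Euclidean distances).  ``start_time`` is the
    start of the deployment — it defaults to the first raw fix and is
    preserved by :func:`clean_track`, which makes the warm-up cut
    idempotent.
    """

    animal_id: str
    period_id: str
    times: np.ndarray  # datetime64[ns], strictly increasing
    lat: np.ndarray  # degrees (geographic) or metres northing (projected)
    lon: np.ndarray  # degrees (geographic) or metres easting (projected)
    crs: str = "geographic"
    start_time: np.datetime64 | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype="datetime64[ns]")
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        if self.times.size < 2:
            raise EmptyTrackError(
                f"track {self.animal_id}/{self.period_id} has "
                f"{self.times.size} fixes; need at least 2"
            )
        if not (self.times.size == self.lat.size == self.lon.size):
            raise TelemetryError("times, lat and lon must have equal length")
        if np.any(np.diff(self.times) <= np.timedelta64(0, "ns")):
            raise TelemetryError(
                f"track {self.animal_id}/{self.period_id}: fix times must be "
                "strictly increasing"
            )
        if self.crs not in ("geographic", "projected"):
            raise TelemetryError(f"unknown crs {self.crs!r}")
        if self.crs == "geographic":
            if np.any(np.abs(self.lat) > 90.0) or np.any(np.abs(self.lon) > 180.0):
                raise TelemetryError("geographic coordinates out of range")
        if self.start_time is None:
            self.start_time = self.times[0]

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def span_hours(self) -> float:
        """Elapsed time between first and last fix, hours."""
        return float((self.times[-1] - self.times[0]) / np.timedelta64(1, "h"))

    def fix(self, i: int) -> Fix:
        return Fix(
            animal_id=self.animal_id,
            period_id=self.period_id,
            time=pd.Timestamp(self.times[i]),
            lat=float(self.lat[i]),
            lon=float(self.lon[i]),
            crs=self.crs,
        )


@dataclass(frozen=True)
class IngestionWindow:
    """Displacements over one hypothetical gut-retention window.

    ``offsets`` are hours since the anchor fix (the hypothetical ingestion
    event); ``distances`` are straight-line metres from the anchor position.
    The first element is always (0, 0).
    """

    animal_id: str
    period_id: str
    anchor_time: np.datetime64
    offsets: np.ndarray  # hours, strictly increasing, offsets[0] == 0
    distances: np.ndarray  # metres, distances[0] == 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "offsets", np.asarray(self.offsets, dtype=float))
        object.__setattr__(self, "distances", np.asarray(self.distances, dtype=float))
        if self.offsets.size == 0 or self.offsets[0] != 0.0 or self.distances[0] != 0.0:
            raise TelemetryError("window must start at (offset 0, distance 0)")
        if np.any(np.diff(self.offsets) <= 0):
            raise TelemetryError("window offsets must be strictly increasing")
        if np.any(self.distances < 0):
            raise TelemetryError("window distances must be nonnegative")

    def __len__(self) -> int:
        return int(self.offsets.size)


# ---------------------------------------------------------------------------
# distances


def haversine_m(
    lat1: float | np.ndarray,
    lon1: float | np.ndarray,
    lat2: float | np.ndarray,
    lon2: float | np.ndarray,
) -> float | np.ndarray:
    """Great-circle distance in metres between WGS84 points (degrees)."""
    phi1, lam1, phi2, lam2 = (np.radians(np.asarray(v, dtype=float))
                              for v in (lat1, lon1, lat2, lon2))
    dphi = phi2 - phi1
    dlam = lam2 - lam1
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_M * np.arcsin(np.minimum(1.0, np.sqrt(a)))
    return float(d) if np.ndim(d) == 0 else d


def geodesic_distance(p1: Fix, p2: Fix) -> float:
    """Distance in metres between two fixes sharing a coordinate convention.

    Great-circle (haversine, R = 6,371 km) for geographic fixes, Euclidean
    for projected-metre fixes.
    """
    if p1.crs != p2.crs:
        raise TelemetryError(f"mixed coordinate conventions: {p1.crs} vs {p2.crs}")
    if p1.crs == "projected":
        return math.hypot(p1.lat - p2.lat, p1.lon - p2.lon)
    return float(haversine_m(p1.lat, p1.lon, p2.lat, p2.lon))


def _distances_from_anchor(track: Track, anchor_index: int) -> np.ndarray:
    """Metres from the anchor fix to every fix at or after it."""
    lat = track.lat[anchor_index:]
    lon = track.lon[anchor_index:]
    if track.crs == "projected":
        return np.hypot(lat - lat[0], lon - lon[0])
    return np.asarray(haversine_m(lat[0], lon[0], lat, lon), dtype=float).reshape(-1)


# ---------------------------------------------------------------------------
# reading and cleaning


def read_tracks(
    path_or_df,
    column_map: Mapping[str, str] | None = None,
    quality_threshold: int = 4,
) -> list[Track]:
    """Read telemetry CSV (or DataFrame) into one Track per tracking period.

    Rows are grouped by (animal_id, period_id) and sorted by time, so the
    result is invariant to row order in the file.  If a quality column is
    configured *and present*, rows with quality below ``quality_threshold``
    (default 4 visible satellites, i.e. non-3D fixes) are dropped and the
    count logged.  Duplicate timestamps within a period keep the first
    occurrence with a warning.  Periods left with fewer than two fixes are
    skipped with a warning.

    Projected-metre input is detected when the mapped x/y columns are present
    and lat/lon are not.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)

    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df)

    required = [cols["animal_id"], cols["period_id"], cols["timestamp"]]
    for c in required:
        if c not in df.columns:
            raise TelemetryError(f"required column {c!r} not found in input")

    projected = cols["x"] in df.columns and cols["lat"] not in df.columns
    if projected:
        coord_cols = (cols["y"], cols["x"])
    else:
        coord_cols = (cols["lat"], cols["lon"])
    for c in coord_cols:
        if c not in df.columns:
            raise TelemetryError(f"coordinate column {c!r} not found in input")

    times = pd.to_datetime(df[cols["timestamp"]], errors="coerce", utc=True, format="mixed")
    bad = times.isna()
    if bad.any():
        line = int(df.index[bad][0]) + 2  # header + 1-based
        raise TelemetryError(
            f"unparseable timestamp {df.loc[df.index[bad][0], cols['timestamp']]!r} "
            f"at line {line}"
        )
    df = df.assign(_time=times.dt.tz_localize(None))

    qcol = cols.get("quality")
    if qcol and qcol in df.columns:
        keep = df[qcol].astype(float) >= quality_threshold
        n_drop = int((~keep).sum())
        if n_drop:
            logger.warning(
                "quality filter (%s >= %d): %d of %d rows dropped",
                qcol, quality_threshold, n_drop, len(df),
            )
        df = df[keep]

    tracks: list[Track] = []
    for (animal, period), g in df.groupby([cols["animal_id"], cols["period_id"]], sort=True):
        g = g.sort_values("_time", kind="mergesort")
        dup = g["_time"].duplicated(keep="first")
        if dup.any():
            logger.warning(
                "track %s/%s: %d duplicate timestamps collapsed to first occurrence",
                animal, period, int(dup.sum()),
            )
            g = g[~dup]
        if len(g) < 2:
            logger.warning(
                "track %s/%s skipped: only %d valid fix(es)", animal, period, len(g)
            )
            continue
        tracks.append(
            Track(
                animal_id=str(animal),
                period_id=str(period),
                times=g["_time"].to_numpy(),
                lat=g[coord_cols[0]].to_numpy(dtype=float),
                lon=g[coord_cols[1]].to_numpy(dtype=float),
                crs="projected" if projected else "geographic",
            )
        )
    return tracks


def clean_track(track: Track, warmup_min: float = 60.0) -> Track:
    """Discard the post-handling warm-up from the start of a track.

    Fixes earlier than ``start_time + warmup_min`` minutes are dropped; a fix
    exactly on the boundary is kept.  The cut is anchored at the track's
    deployment ``start_time``, not its current first fix, so cleaning twice
    equals cleaning once.

    Raises :class:`EmptyTrackError` if fewer than two fixes remain.
    """
    if warmup_min < 0:
        raise ValueError("warmup must be nonnegative")
    cutoff = track.start_time + np.timedelta64(int(round(warmup_min * 60_000)), "ms")
    keep = track.times >= cutoff
    if int(keep.sum()) < 2:
        raise EmptyTrackError(
            f"track {track.animal_id}/{track.period_id}: fewer than 2 fixes "
            f"remain after {warmup_min:g}-min warm-up"
        )
    if keep.all():
        return replace(track)
    return Track(
        animal_id=track.animal_id,
        period_id=track.period_id,
        times=track.times[keep],
        lat=track.lat[keep],
        lon=track.lon[keep],
        crs=track.crs,
        start_time=track.start_time,
    )


# ---------------------------------------------------------------------------
# displacement and windows


def displacement_series(track: Track, anchor_index: int) -> tuple[np.ndarray, np.ndarray]:
    """Hours-since-anchor and metres-from-anchor for every fix at/after it."""
    if not (0 <= anchor_index < len(track)):
        raise IndexError(f"anchor_index {anchor_index} out of range")
    dt = track.times[anchor_index:] - track.times[anchor_index]
    offsets = dt / np.timedelta64(1, "h")
    distances = _distances_from_anchor(track, anchor_index)
    return offsets.astype(float), distances


_TOL_H = 1e-9  # tolerance on hour arithmetic from timestamp conversion


def extract_windows(
    track: Track,
    window_hours: float = 69.0,
    min_span_fraction: float = 1.0,
) -> list[IngestionWindow]:
    """Slice a (cleaned) track into all possible ingestion windows.

    Every fix is a candidate ingestion point; a window is admitted when the
    track extends at least ``min_span_fraction * window_hours`` beyond its
    anchor.  Each admitted window contains every fix with offset in
    [0, window_hours]; later fixes are truncated away.  Returns an empty
    list when the whole track is shorter than the required span.
    """
    if window_hours <= 0:
        raise ValueError("window_hours must be positive")
    if not (0 < min_span_fraction <= 1.0):
        raise ValueError("min_span_fraction must be in (0, 1]")
    required = min_span_fraction * window_hours - _TOL_H
    rel_h = (track.times - track.times[0]) / np.timedelta64(1, "h")
    span = rel_h[-1]
    windows: list[IngestionWindow] = []
    for i in range(len(track)):
        if span - rel_h[i] < required:
            break  # later anchors have even less trailing span
        offsets, distances = displacement_series(track, i)
        inside = offsets <= window_hours + _TOL_H
        windows.append(
            IngestionWindow(
                animal_id=track.animal_id,
                period_id=track.period_id,
                anchor_time=track.times[i],
                offsets=offsets[inside],
                distances=distances[inside],
            )
        )
    return windows


# ---------------------------------------------------------------------------
# dataset summary


def dataset_summary(tracks: Iterable[Track]) -> dict:
    """Descriptive statistics of a telemetry dataset.

    Returns total position count, per-period span statistics (hours), total
    tracking hours (sum of spans) and the mean within-period fix interval in
    minutes.  Apply before or after :func:`clean_track` depending on whether
    the warm-up fixes should count.
    """
    tracks = list(tracks)
    if not tracks:
        raise ValueError("dataset_summary needs at least one track")
    spans = np.array([t.span_hours for t in tracks])
    gaps_min: list[np.ndarray] = [
        np.diff(t.times) / np.timedelta64(1, "m") for t in tracks
    ]
    all_gaps = np.concatenate(gaps_min)
    return {
        "n_positions": int(sum(len(t) for t in tracks)),
        "n_periods": len(tracks),
        "n_animals": len({t.animal_id for t in tracks}),
        "span_hours_min": float(spans.min()),
        "span_hours_max": float(spans.max()),
        "span_hours_mean": float(spans.mean()),
        "span_hours_sd": float(spans.std(ddof=1)) if len(spans) > 1 else 0.0,
        "total_tracking_hours": float(spans.sum()),
        "mean_fix_interval_min": float(all_gaps.mean()),
    }
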