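"""Point collections, coordinate frames, and provider-distance primitives.

Participants (care recipients) and providers are modelled as located points
in a declared coordinate frame: either planar easting/northing in meters or
geographic WGS84 longitude/latitude in degrees.  All distances returned by
this module are in meters; geographic distances are great-circle (haversine)
lengths on a sphere of mean Earth radius 6 371 008.8 m.

For privacy, participant addresses may be snapped to the centroid of their
administrative zone (e.g. the minimum ZIP-code center) before any distance
is computed; snapping is an explicit, optional step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

EARTH_RADIUS_M = 6371008.8


class Frame(str, Enum):
    """Coordinate frame of a point collection."""

    PLANAR = "planar-meters"
    WGS84 = "geographic-wgs84"

    @classmethod
    def parse(cls, value: "str | Frame") -> "Frame":
        if isinstance(value, Frame):
            return value
        try:
            return cls(value)
        except ValueError:
            raise ValidationError(
                f"unknown coordinate frame {value!r}; "
                f"expected one of {[m.value for m in cls]}"
            ) from None


class ValidationError(ValueError):
    """Raised when input data violates a contract of this package."""


class FrameMismatchError(ValidationError):
    """Raised when two collections in one analysis declare different frames."""


class EmptySupplyError(ValidationError):
    """Raised when a provider set is empty and a nearest distance is requested."""


@dataclass(frozen=True)
class PointSet:
    """An ordered collection of identified points in a single frame.

    Parameters
    ----------
    ids
        Unique opaque string identifiers, one per point.
    xy
        ``(n, 2)`` array of coordinates (x = easting/longitude,
        y = northing/latitude).
    frame
        Coordinate frame shared by all points in the collection.
    zone_ids
        Optional per-point administrative-zone labels (used for privacy
        snapping); ``None`` entries mean "no zone recorded".
    attrs
        Optional extra per-point attribute columns, aligned with ``ids``.
    """

    ids: np.ndarray
    xy: np.ndarray
    frame: Frame = Frame.PLANAR
    zone_ids: np.ndarray | None = None
    attrs: pd.DataFrame | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        ids = np.asarray(self.ids, dtype=object)
        xy = np.asarray(self.xy, dtype=float)
        if xy.ndim != 2 or xy.shape[1] != 2:
            raise ValidationError(f"xy must be (n, 2), got shape {xy.shape}")
        if len(ids) != len(xy):
            raise ValidationError("ids and xy must have equal length")
        if len(set(ids)) != len(ids):
            dupes = pd.Series(ids).value_counts()
            dupes = list(dupes[dupes > 1].index[:5])
            raise ValidationError(f"duplicate point ids: {dupes}")
        if not np.all(np.isfinite(xy)):
            bad = ids[~np.isfinite(xy).all(axis=1)]
            raise ValidationError(f"non-finite coordinates for ids {list(bad[:5])}")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "xy", xy)
        object.__setattr__(self, "frame", Frame.parse(self.frame))
        if self.zone_ids is not None:
            zid = np.asarray(self.zone_ids, dtype=object)
            if len(zid) != len(ids):
                raise ValidationError("zone_ids must align with ids")
            object.__setattr__(self, "zone_ids", zid)

    def __len__(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        """Return the collection as a DataFrame with id, x, y[, zone_id] columns."""
        df = pd.DataFrame({"id": self.ids, "x": self.xy[:, 0], "y": self.xy[:, 1]})
        if self.zone_ids is not None:
            df["zone_id"] = self.zone_ids
        if self.attrs is not None:
            for col in self.attrs.columns:
                df[col] = np.asarray(self.attrs[col])
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, frame: "str | Frame" = Frame.PLANAR) -> "PointSet":
        """Build a PointSet from a DataFrame with id, x, y[, zone_id] columns."""
        missing = {"id", "x", "y"} - set(df.columns)
        if missing:
            raise ValidationError(f"missing required columns: {sorted(missing)}")
        zone = df["zone_id"].to_numpy(dtype=object) if "zone_id" in df.columns else None
        extra = [c for c in df.columns if c not in ("id", "x", "y", "zone_id")]
        attrs = df[extra].reset_index(drop=True) if extra else None
        return cls(
            ids=df["id"].astype(str).to_numpy(dtype=object),
            xy=df[["x", "y"]].to_numpy(dtype=float),
            frame=frame,
            zone_ids=zone,
            attrs=attrs,
        )


def _check_frames(*sets: PointSet) -> Frame:
    frames = {s.frame for s in sets}
    if len(frames) > 1:
        raise FrameMismatchError(
            f"collections declare different frames: {sorted(f.value for f in frames)}"
        )
    return next(iter(frames))


def _haversine_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Great-circle distance matrix in meters for lon/lat degree coordinates."""
    lon1, lat1 = np.radians(a[:, 0])[:, None], np.radians(a[:, 1])[:, None]
    lon2, lat2 = np.radians(b[:, 0])[None, :], np.radians(b[:, 1])[None, :]
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def distance_matrix(a: PointSet, b: PointSet) -> np.ndarray:
    """All-pairs distance matrix in meters between two collections."""
    frame = _check_frames(a, b)
    if frame is Frame.PLANAR:
        return cdist(a.xy, b.xy)
    return _haversine_matrix(a.xy, b.xy)


def pairwise_distance(
    a: tuple[float, float],
    b: tuple[float, float],
    frame: "str | Frame" = Frame.PLANAR,
) -> float:
    """Distance in meters between two coordinate pairs in a common frame.

    Planar frames use the Euclidean norm on meter coordinates; the
    geographic frame uses the haversine great-circle distance.
    """
    frame = Frame.parse(frame)
    pa = np.asarray(a, dtype=float).reshape(1, 2)
    pb = np.asarray(b, dtype=float).reshape(1, 2)
    if not (np.all(np.isfinite(pa)) and np.all(np.isfinite(pb))):
        raise ValidationError("coordinates must be finite")
    if frame is Frame.PLANAR:
        return float(np.hypot(*(pa - pb).ravel()))
    return float(_haversine_matrix(pa, pb)[0, 0])


def nearest_provider_distance(
    participants: PointSet, providers: PointSet
) -> pd.DataFrame:
    """Distance from each participant to the nearest provider.

    Returns a DataFrame indexed by participant id with columns ``distance_m``
    and ``provider_id``.  Ties are broken by the lexicographically smallest
    provider id so results are reproducible regardless of input order.

    Raises
    ------
    EmptySupplyError
        If the provider collection is empty.
    """
    if len(providers) == 0:
        raise EmptySupplyError("provider collection is empty; no nearest distance exists")
    order = np.argsort(providers.ids.astype(str), kind="stable")
    d = distance_matrix(participants, PointSet(
        ids=providers.ids[order], xy=providers.xy[order], frame=providers.frame
    ))
    j = np.argmin(d, axis=1)  # first minimum = smallest provider id after sort
    return pd.DataFrame(
        {
            "distance_m": d[np.arange(len(participants)), j],
            "provider_id": providers.ids[order][j],
        },
        index=pd.Index(participants.ids, name="id"),
    )


@dataclass(frozen=True)
class ZoneCentroidMap:
    """Mapping from zone id to the zone's centroid coordinates."""

    centroids: Mapping[str, tuple[float, float]]
    frame: Frame = Frame.PLANAR

    def __post_init__(self) -> None:
        object.__setattr__(self, "frame", Frame.parse(self.frame))
        object.__setattr__(self, "centroids", dict(self.centroids))

    @classmethod
    def from_points(cls, points: PointSet) -> "ZoneCentroidMap":
        """Interpret a point collection (id = zone id) as a centroid map."""
        return cls(
            centroids={str(i): (x, y) for i, (x, y) in zip(points.ids, points.xy)},
            frame=points.frame,
        )

    def __contains__(self, zone_id: str) -> bool:
        return zone_id in self.centroids


def snap_to_zone_centroid(points: PointSet, zones: ZoneCentroidMap) -> PointSet:
    """Replace each point's coordinates with its zone centroid.

    Cardinality, ids and zone labels are preserved; only coordinates change.
    Every point must carry a zone_id that resolves in ``zones``.
    """
    _check_frames(points, PointSet(ids=np.array([], dtype=object),
                                   xy=np.empty((0, 2)), frame=zones.frame))
    if points.zone_ids is None:
        raise ValidationError("points carry no zone_id column; cannot snap")
    missing = [str(i) for i, z in zip(points.ids, points.zone_ids)
               if z is None or str(z) not in zones]
    if missing:
        raise ValidationError(
            f"{len(missing)} point(s) with missing/unresolvable zone_id: {missing[:10]}"
        )
    xy = np.array([zones.centroids[str(z)] for z in points.zone_ids], dtype=float)
    return PointSet(ids=points.ids.copy(), xy=xy, frame=points.frame,
                    zone_ids=points.zone_ids.copy(), attrs=points.attrs)
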