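"""Readers and writers for point tables (CSV, GeoJSON) and zone centroids.

CSV dialect: UTF-8, header required, columns ``id,x,y[,zone_id,...]``.
GeoJSON dialect: a FeatureCollection of Point features; the point id is taken
from the feature ``id`` or, failing that, an ``id`` property.  The declared
coordinate frame is never guessed from the data; callers state it explicitly.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .points import Frame, PointSet, ValidationError, ZoneCentroidMap


def read_points_csv(path: "str | Path", frame: "str | Frame" = Frame.PLANAR) -> PointSet:
    """Read a point collection from a ``id,x,y[,zone_id,...]`` CSV file."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"id": str, "zone_id": str})
    except Exception as exc:  # pandas raises several parser error types
        raise ValidationError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = {"id", "x", "y"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing required columns {sorted(missing)}")
    for col in ("x", "y"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            lines = (df.index[bad] + 2).tolist()[:5]  # +2: header + 1-based
            raise ValidationError(f"{path}: non-numeric {col!r} at line(s) {lines}")
        df[col] = pd.to_numeric(df[col])
    if df[["x", "y"]].isna().any().any():
        lines = (df.index[df[["x", "y"]].isna().any(axis=1)] + 2).tolist()[:5]
        raise ValidationError(f"{path}: missing coordinates at line(s) {lines}")
    return PointSet.from_frame(df, frame=frame)


def write_points_csv(points: PointSet, path: "str | Path") -> None:
    points.to_frame().to_csv(path, index=False)


def read_points_geojson(path: "str | Path", frame: "str | Frame" = Frame.PLANAR) -> PointSet:
    """Read a point collection from a GeoJSON FeatureCollection of Points."""
    path = Path(path)
    try:
        obj = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ValidationError(f"{path}: invalid JSON ({exc})") from exc
    if obj.get("type") != "FeatureCollection":
        raise ValidationError(f"{path}: expected a FeatureCollection")
    rows = []
    for k, feat in enumerate(obj.get("features", [])):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Point":
            raise ValidationError(f"{path}: feature {k} is not a Point")
        props = feat.get("properties") or {}
        pid = feat.get("id", props.get("id"))
        if pid is None:
            raise ValidationError(f"{path}: feature {k} has no id")
        x, y = geom["coordinates"][:2]
        row = {"id": str(pid), "x": x, "y": y}
        if "zone_id" in props and props["zone_id"] is not None:
            row["zone_id"] = str(props["zone_id"])
        rows.append(row)
    return PointSet.from_frame(pd.DataFrame(rows, columns=["id", "x", "y", "zone_id"])
                               if any("zone_id" in r for r in rows)
                               else pd.DataFrame(rows, columns=["id", "x", "y"]),
                               frame=frame)


def write_points_geojson(points: PointSet, path: "str | Path") -> None:
    features = []
    df = points.to_frame()
    for _, row in df.iterrows():
        props = {c: row[c] for c in df.columns if c not in ("id", "x", "y")}
        features.append({
            "type": "Feature",
            "id": row["id"],
            "geometry": {"type": "Point", "coordinates": [row["x"], row["y"]]},
            "properties": props,
        })
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1),
        encoding="utf-8",
    )


def read_zone_centroids_csv(path: "str | Path",
                            frame: "str | Frame" = Frame.PLANAR) -> ZoneCentroidMap:
    """Read a zone-centroid table (columns ``id,x,y``; id = zone id)."""
    return ZoneCentroidMap.from_points(read_points_csv(path, frame=frame))
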