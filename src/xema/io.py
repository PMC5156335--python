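"""File readers and writers.

CSV for twilights, tag SST series, tracks and summaries (ISO-8601 dates,
fixed headers); NetCDF (CF-style lat/lon, scipy backend) for SST
composites; GeoJSON for occupancy contours. Track round trips are
bit-for-bit: coordinates at full precision via repr.
"""
from __future__ import annotations

import csv
import datetime as dt
import json
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .spaceuse import OccupancyContour
from .types import (
    POLAR_DAY,
    POLAR_NIGHT,
    SENTINELS,
    PositionEstimate,
    Source,
    SSTGrid,
    SSTSample,
    Track,
    TwilightRecord,
    norm_lon,
)


class FormatError(ValueError):
    pass


def _parse_date(s: str, line: int) -> dt.date:
    try:
        return dt.date.fromisoformat(s.strip())
    except ValueError as e:
        raise FormatError(f"line {line}: unparseable date {s!r}") from e


def _parse_time_h(s: str, line: int) -> float:
    s = s.strip()
    try:
        parts = s.split(":")
        if not 2 <= len(parts) <= 3:
            raise ValueError
        h, m = int(parts[0]), int(parts[1])
        sec = float(parts[2]) if len(parts) == 3 else 0.0
        if not (0 <= m < 60 and 0 <= sec < 60):
            raise ValueError
        return (h + m / 60.0 + sec / 3600.0) % 24.0
    except ValueError as e:
        raise FormatError(f"line {line}: unparseable time {s!r}") from e


def _format_time_h(hours: float) -> str:
    total = int(round((hours % 24.0) * 3600.0))
    h, rem = divmod(total, 3600)
    m, s = divmod(rem, 60)
    return f"{h % 24:02d}:{m:02d}:{s:02d}"


TWILIGHT_COLUMNS = ["bird_id", "date", "sunrise", "sunset"]


def read_twilights(path) -> list[TwilightRecord]:
    """Read a twilight CSV (bird_id,date,sunrise,sunset).

    Sentinel strings POLAR_DAY/POLAR_NIGHT mark days without twilights.
    Records come back sorted by (bird_id, date); duplicate (bird_id, date)
    pairs are rejected.
    """
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError("empty file without header")
        missing = [c for c in TWILIGHT_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"missing column(s): {', '.join(missing)}")
        seen = set()
        out = []
        for i, row in enumerate(reader, start=2):
            date = _parse_date(row["date"], i)
            key = (row["bird_id"], date)
            if key in seen:
                raise FormatError(f"duplicate record for bird {key[0]!r} on {date.isoformat()}")
            seen.add(key)
            sr_raw, ss_raw = row["sunrise"].strip(), row["sunset"].strip()
            if sr_raw in SENTINELS or ss_raw in SENTINELS:
                if sr_raw != ss_raw:
                    raise FormatError(f"line {i}: inconsistent polar sentinels")
                out.append(TwilightRecord(row["bird_id"], date, None, None, sentinel=sr_raw))
            else:
                out.append(
                    TwilightRecord(
                        row["bird_id"], date, _parse_time_h(sr_raw, i), _parse_time_h(ss_raw, i)
                    )
                )
    out.sort(key=lambda r: (r.bird_id, r.date))
    return out


def write_twilights(records: Sequence[TwilightRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(TWILIGHT_COLUMNS)
        for r in records:
            if r.sentinel is not None:
                w.writerow([r.bird_id, r.date.isoformat(), r.sentinel, r.sentinel])
            else:
                w.writerow(
                    [r.bird_id, r.date.isoformat(), _format_time_h(r.sunrise_h), _format_time_h(r.sunset_h)]
                )


SST_COLUMNS = ["bird_id", "date", "min_sst"]


def read_sst_series(path) -> list[SSTSample]:
    """Read a per-bird daily minimum-SST CSV (blank value = missing)."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError("empty file without header")
        missing = [c for c in SST_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"missing column(s): {', '.join(missing)}")
        out = []
        for i, row in enumerate(reader, start=2):
            date = _parse_date(row["date"], i)
            raw = row["min_sst"].strip()
            val = None if raw == "" else float(raw)
            out.append(SSTSample(row["bird_id"], date, val))
    out.sort(key=lambda r: (r.bird_id, r.date))
    return out


def write_sst_series(samples: Sequence[SSTSample], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(SST_COLUMNS)
        for s in samples:
            w.writerow([s.bird_id, s.date.isoformat(), "" if s.min_sst is None else repr(s.min_sst)])


TRACK_COLUMNS = ["bird_id", "date", "lat", "lon", "source", "flags"]
_FLAG_NAMES = ("equinox_flagged", "polar_flagged", "speed_rejected", "unsmoothed_jump")


def write_track(track: Track, path) -> None:
    """Write a track CSV with a small key=value metadata header."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# bird_id={track.bird_id}\n")
        fh.write(f"# sex={track.sex or ''}\n")
        fh.write(f"# deployment_year={track.deployment_year if track.deployment_year is not None else ''}\n")
        fh.write(f"# colony_lat={track.colony_lat!r}\n")
        fh.write(f"# colony_lon={track.colony_lon!r}\n")
        w = csv.writer(fh)
        w.writerow(TRACK_COLUMNS)
        for p in track.positions:
            w.writerow(
                [p.bird_id, p.date.isoformat(), repr(p.lat), repr(p.lon), p.source.value, ";".join(p.flags())]
            )


def read_track(path) -> Track:
    """Read a track CSV written by :func:`write_track` (round trip exact).

    Longitudes outside [-180, 180) are normalized with a warning;
    out-of-range latitudes and non-increasing dates are errors.
    """
    meta = {}
    rows = []
    with open(path, newline="") as fh:
        header = None
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key.strip()] = value
                continue
            if header is None:
                header = line.split(",")
                missing = [c for c in TRACK_COLUMNS if c not in header]
                if missing:
                    raise FormatError(f"missing column(s): {', '.join(missing)}")
                continue
            if not line:
                continue
            row = dict(zip(header, next(csv.reader([line]))))
            date = _parse_date(row["date"], i)
            lat = float(row["lat"])
            lon = float(row["lon"])
            if np.isfinite(lat) and abs(lat) > 90:
                raise FormatError(f"line {i}: latitude {lat} outside [-90, 90]")
            if np.isfinite(lon) and not (-180.0 <= lon < 180.0):
                warnings.warn(f"line {i}: longitude {lon} normalized to [-180, 180)")
                lon = float(norm_lon(lon))
            flags = {f: False for f in _FLAG_NAMES}
            for f in filter(None, row.get("flags", "").split(";")):
                if f not in flags:
                    raise FormatError(f"line {i}: unknown flag {f!r}")
                flags[f] = True
            rows.append(
                PositionEstimate(row["bird_id"], date, lat, lon, Source(row["source"]), **flags)
            )
    dates = [p.date for p in rows]
    if any(b <= a for a, b in zip(dates, dates[1:])):
        raise FormatError("track dates must be strictly increasing")
    year = meta.get("deployment_year", "")
    return Track(
        bird_id=meta.get("bird_id", rows[0].bird_id if rows else "unknown"),
        sex=meta.get("sex") or None,
        deployment_year=int(year) if year else None,
        colony_lat=float(meta["colony_lat"]),
        colony_lon=float(meta["colony_lon"]),
        positions=rows,
    )


def write_sst_grid(grid: SSTGrid, path) -> None:
    """Write an 8-day composite as CF-style NetCDF-3."""
    ds = xr.Dataset(
        {"sst": (("lat", "lon"), grid.values)},
        coords={"lat": grid.lat_axis, "lon": grid.lon_axis},
        attrs={"period_start": grid.period_start.isoformat(), "period_days": grid.period_days},
    )
    ds["sst"].attrs.update(units="degC", long_name="8-day composite nighttime SST")
    ds["lat"].attrs.update(units="degrees_north")
    ds["lon"].attrs.update(units="degrees_east")
    ds.to_netcdf(path, engine="scipy")


def read_sst_grid(path) -> SSTGrid:
    """Read an SST composite from NetCDF.

    Longitude axes on 0..360 are remapped to [-180, 180); a missing
    ``period_start`` attribute is an error (supply it when writing).
    """
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    if "period_start" not in ds.attrs:
        raise FormatError("grid lacks a period_start attribute; supply period_start when writing")
    period_start = dt.date.fromisoformat(str(ds.attrs["period_start"]))
    period_days = int(ds.attrs.get("period_days", 8))
    var = "sst" if "sst" in ds else list(ds.data_vars)[0]
    lat = np.asarray(ds["lat"].values, dtype=float)
    lon = np.asarray(ds["lon"].values, dtype=float)
    values = np.asarray(ds[var].values, dtype=float)
    if lon.max() >= 180.0:  # 0..360 convention
        lon = np.asarray(norm_lon(lon))
        order = np.argsort(lon)
        lon = lon[order]
        values = values[:, order]
    if lat[0] > lat[-1]:
        lat = lat[::-1]
        values = values[::-1]
    return SSTGrid(period_start, period_days, lat, lon, values)


def contours_to_geojson(contours: Sequence[OccupancyContour], properties: Optional[dict] = None) -> dict:
    """Occupancy contours as a GeoJSON FeatureCollection (WGS84)."""
    feats = []
    for c in contours:
        geom = c.polygon_geographic if c.polygon_geographic is not None else c.polygon_projected
        feats.append(
            {
                "type": "Feature",
                "properties": {
                    "level_percent": c.level,
                    "captured_fraction": round(c.captured_fraction, 6),
                    **(properties or {}),
                },
                "geometry": geom.__geo_interface__,
            }
        )
    return {"type": "FeatureCollection", "features": feats}


def write_geojson(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True)


def write_stage_log(entries: Sequence[dict], path) -> None:
    """Structured stage log as JSON lines (counts per pipeline stage)."""
    with open(path, "w") as fh:
        for e in entries:
            fh.write(json.dumps(e, sort_keys=True) + "\n")


def summaries_to_frame(summaries) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "bird_id": s.bird_id,
                "basin": s.basin.value if s.basin else "",
                "departure": s.departure.isoformat() if s.departure else "",
                "arrival": s.arrival.isoformat() if s.arrival else "",
                "duration_d": s.duration_days if s.duration_days is not None else "",
                "travel_distance_km": round(s.travel_distance_km, 1) if s.travel_distance_km is not None else "",
                "travel_days": s.travel_days if s.travel_days is not None else "",
                "travel_speed_kmd": round(s.travel_speed_kmd, 1) if s.travel_speed_kmd is not None else "",
                "complete": s.complete,
            }
        )
    return pd.DataFrame(rows)
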