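"""Reading and writing fix streams and bird manifests.

CSV dialect: header ``bird_id,datetime,lat,lon,speed_kmh`` with ISO 8601
datetimes (parsed as UTC).  GPX 1.1 tracks use one ``<trk>`` per bird with
``<trkpt lat lon>``, ``<time>`` and an optional ``<extensions><speed>`` in
km/h.  The manifest is a delimited table ``bird_id,release_site,
exposure_site,group`` mapping every bird to its design cell.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree

from .model import Track, infer_group

log = logging.getLogger(__name__)

_GPX_NS = "http://www.topografix.com/GPX/1/1"
_TIME_FMT = "%Y-%m-%dT%H:%M:%SZ"


def read_manifest(path) -> pd.DataFrame:
    """Read the bird assignment table, validating group consistency."""
    df = pd.read_csv(path, dtype=str)
    required = {"bird_id", "release_site", "exposure_site"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    expected = [infer_group(r, e) for r, e in zip(df["release_site"], df["exposure_site"])]
    if "group" in df.columns:
        bad = df.loc[df["group"] != expected, "bird_id"].tolist()
        if bad:
            raise ValueError(f"manifest group labels inconsistent with site columns for {bad}")
    else:
        df["group"] = expected
    return df.set_index("bird_id", verify_integrity=True)


def _build_tracks(frame: pd.DataFrame, manifest: pd.DataFrame) -> list[Track]:
    """Assemble validated per-bird Tracks from a long fix table."""
    valid = (
        frame["lat"].between(-90.0, 90.0)
        & (frame["lon"] > -180.0) & (frame["lon"] <= 180.0)
        & (frame["speed"] >= 0.0)
        & frame[["lat", "lon", "t", "speed"]].notna().all(axis=1)
    )
    n_bad = int((~valid).sum())
    if n_bad:
        log.warning("rejected %d fix rows failing coordinate/speed invariants", n_bad)
    frame = frame[valid]

    tracks = []
    for bird_id, sub in frame.groupby("bird_id", sort=True):
        if bird_id not in manifest.index:
            raise KeyError(f"manifest has no entry for bird {bird_id!r}")
        sub = sub.sort_values("t", kind="stable")
        dup = sub["t"].duplicated(keep="first")
        if dup.any():
            log.info("bird %s: collapsed %d duplicate timestamps (kept first)",
                     bird_id, int(dup.sum()))
            sub = sub[~dup]
        if len(sub) < 2:
            log.warning("bird %s: fewer than 2 valid fixes, dropped", bird_id)
            continue
        row = manifest.loc[bird_id]
        tracks.append(Track(
            str(bird_id),
            sub["lat"].to_numpy(float), sub["lon"].to_numpy(float),
            sub["t"].to_numpy(float), sub["speed"].to_numpy(float),
            release_site=row["release_site"], exposure_site=row["exposure_site"],
            group=row["group"],
        ))
    return tracks


def _read_csv_fixes(path) -> pd.DataFrame:
    raw = pd.read_csv(path)
    if raw.empty:
        return pd.DataFrame(columns=["bird_id", "t", "lat", "lon", "speed"])
    ts = pd.to_datetime(raw["datetime"], utc=True, errors="coerce")
    tsec = pd.Series(np.nan, index=raw.index)
    ok = ts.notna()
    tsec[ok] = ts[ok].astype("int64") / 1e9
    return pd.DataFrame({
        "bird_id": raw["bird_id"].astype(str),
        "t": tsec,
        "lat": pd.to_numeric(raw["lat"], errors="coerce"),
        "lon": pd.to_numeric(raw["lon"], errors="coerce"),
        "speed": pd.to_numeric(raw["speed_kmh"], errors="coerce"),
    })


def _read_gpx_fixes(path) -> pd.DataFrame:
    tree = etree.parse(str(path))
    ns = {"g": _GPX_NS}
    rows = []
    for trk in tree.getroot().findall("g:trk", ns):
        name = trk.findtext("g:name", default="", namespaces=ns)
        for pt in trk.findall(".//g:trkpt", ns):
            t_text = pt.findtext("g:time", default=None, namespaces=ns)
            speed = pt.findtext(".//g:speed", default="nan", namespaces=ns)
            ts = pd.to_datetime(t_text, utc=True, errors="coerce") if t_text else pd.NaT
            rows.append({
                "bird_id": name,
                "t": ts.timestamp() if pd.notna(ts) else np.nan,
                "lat": float(pt.get("lat", "nan")),
                "lon": float(pt.get("lon", "nan")),
                "speed": float(speed),
            })
    return pd.DataFrame(rows, columns=["bird_id", "t", "lat", "lon", "speed"])


def read_tracks(path, format: str = "csv", manifest=None) -> list[Track]:
    """Read per-bird fix streams into validated :class:`Track` objects.

    ``manifest`` may be a path or a DataFrame from :func:`read_manifest`;
    a missing manifest entry for any bird is a hard error naming the bird.
    Rows failing coordinate invariants are rejected with a logged count, and
    duplicate timestamps within a bird are collapsed to the first occurrence.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if manifest is None:
        raise ValueError("a manifest mapping bird_id to sites is required")
    if not isinstance(manifest, pd.DataFrame):
        manifest = read_manifest(manifest)
    if format == "csv":
        frame = _read_csv_fixes(path)
    elif format == "gpx":
        frame = _read_gpx_fixes(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    if frame.empty:
        log.warning("no fixes found in %s", path)
        return []
    return _build_tracks(frame, manifest)


def write_tracks(tracks, path, format: str = "csv") -> None:
    """Write tracks in the CSV or GPX dialect read by :func:`read_tracks`.

    Coordinates are written with 7 decimals (≈1 cm), timestamps at seconds
    resolution, so a write→read round trip reproduces coordinates to 1e-6
    degrees and timestamps exactly.
    """
    path = Path(path)
    if format == "csv":
        parts = []
        for tr in tracks:
            dt = pd.to_datetime(np.round(tr.t).astype("int64"), unit="s", utc=True)
            parts.append(pd.DataFrame({
                "bird_id": tr.bird_id,
                "datetime": dt.strftime(_TIME_FMT),
                "lat": np.round(tr.lat, 7),
                "lon": np.round(tr.lon, 7),
                "speed_kmh": np.round(tr.speed, 3),
            }))
        out = (pd.concat(parts, ignore_index=True) if parts
               else pd.DataFrame(columns=["bird_id", "datetime", "lat", "lon", "speed_kmh"]))
        out.to_csv(path, index=False)
    elif format == "gpx":
        root = etree.Element("gpx", version="1.1", creator="pigeontrack",
                             nsmap={None: _GPX_NS})
        for tr in tracks:
            trk = etree.SubElement(root, "trk")
            etree.SubElement(trk, "name").text = tr.bird_id
            seg = etree.SubElement(trk, "trkseg")
            for la, lo, tt, sp in zip(tr.lat, tr.lon, tr.t, tr.speed):
                pt = etree.SubElement(seg, "trkpt",
                                      lat=f"{la:.7f}", lon=f"{lo:.7f}")
                stamp = pd.Timestamp(round(tt), unit="s", tz="UTC")
                etree.SubElement(pt, "time").text = stamp.strftime(_TIME_FMT)
                ext = etree.SubElement(pt, "extensions")
                etree.SubElement(ext, "speed").text = f"{sp:.3f}"
        etree.ElementTree(root).write(str(path), xml_declaration=True,
                                      encoding="UTF-8", pretty_print=True)
    else:
        raise ValueError(f"unknown format {format!r}")


def write_manifest(tracks, path) -> None:
    pd.DataFrame(
        [{"bird_id": tr.bird_id, "release_site": tr.release_site,
          "exposure_site": tr.exposure_site, "group": tr.group} for tr in tracks]
    ).to_csv(path, index=False)
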