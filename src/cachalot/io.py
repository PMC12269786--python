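"""File formats: WAV audio, ESRI ASCII bathymetry grids, GeoJSON coastlines.

WAV is written as 16-bit PCM and read in any integer or float PCM width.
Bathymetry is exchanged as the ESRI ASCII grid text format (georeferenced in
WGS84 decimal degrees, depths in positive metres, NODATA for land).
Coastlines are GeoJSON LineStrings.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .acoustics import AudioSegment
from .spatial import BathymetryGrid, GeoPoint

__all__ = [
    "read_wav",
    "write_wav",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_coastline_geojson",
    "write_coastline_geojson",
]


def write_wav(path: str | Path, audio: AudioSegment) -> None:
    """Write 16-bit PCM WAV, scaling so the peak sits at 90% of full scale."""
    x = np.atleast_1d(audio.samples)
    peak = float(np.max(np.abs(x))) or 1.0
    scaled = np.round(x / peak * 0.9 * 32767.0).astype(np.int16)
    wavfile.write(str(path), int(audio.sample_rate), scaled)


def read_wav(path: str | Path, channel_id: str | None = None) -> AudioSegment:
    """Read a PCM WAV into normalised float samples in [-1, 1]."""
    rate, data = wavfile.read(str(path))
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    return AudioSegment(data, float(rate), channel_id or Path(path).stem)


def write_ascii_grid(path: str | Path, grid: BathymetryGrid, nodata: float = -9999.0) -> None:
    """Write an ESRI ASCII grid (cell-centre registration, degrees)."""
    nr, nc = grid.shape
    # xllcorner/yllcorner refer to the lower-left cell corner; dlon is the
    # cellsize (the format has a single cell size, so dlat must equal dlon)
    if not np.isclose(grid.dlat, grid.dlon):
        raise ValueError("ESRI ASCII grids require square cells (dlat == dlon)")
    xll = grid.lon0 - grid.dlon / 2.0
    yll = grid.lat0 - (nr - 1) * grid.dlat - grid.dlat / 2.0
    body = np.where(np.isfinite(grid.depths), grid.depths, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {nc}\n")
        fh.write(f"nrows {nr}\n")
        fh.write(f"xllcorner {xll:.10f}\n")
        fh.write(f"yllcorner {yll:.10f}\n")
        fh.write(f"cellsize {grid.dlon:.10f}\n")
        fh.write(f"NODATA_value {nodata}\n")
        for row in body:
            fh.write(" ".join(f"{v:.4f}" for v in row) + "\n")


def read_ascii_grid(path: str | Path) -> BathymetryGrid:
    """Read an ESRI ASCII grid into a :class:`BathymetryGrid` (NaN for NODATA)."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    for required in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if required not in header:
            raise ValueError(f"ASCII grid missing header field {required!r}")
    depths = np.array(rows, dtype=float)
    if depths.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("ASCII grid body does not match declared dimensions")
    nodata = header.get("nodata_value")
    if nodata is not None:
        depths = np.where(np.isclose(depths, nodata), np.nan, depths)
    cell = header["cellsize"]
    lat0 = header["yllcorner"] + (int(header["nrows"]) - 1) * cell + cell / 2.0
    lon0 = header["xllcorner"] + cell / 2.0
    return BathymetryGrid(depths=depths, lat0=lat0, lon0=lon0, dlat=cell, dlon=cell)


def write_coastline_geojson(path: str | Path, coastline: list[GeoPoint]) -> None:
    feature = {
        "type": "Feature",
        "properties": {"name": "coastline"},
        "geometry": {
            "type": "LineString",
            "coordinates": [[p.lon, p.lat] for p in coastline],
        },
    }
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": [feature]}, fh, indent=1)


def read_coastline_geojson(path: str | Path) -> list[GeoPoint]:
    """Read the first LineString found in a GeoJSON file."""
    with open(path) as fh:
        doc = json.load(fh)
    geometries = []
    if doc.get("type") == "FeatureCollection":
        geometries = [f["geometry"] for f in doc.get("features", [])]
    elif doc.get("type") == "Feature":
        geometries = [doc["geometry"]]
    else:
        geometries = [doc]
    for geom in geometries:
        if geom.get("type") == "LineString":
            return [GeoPoint(lat, lon) for lon, lat in geom["coordinates"]]
    raise ValueError(f"no LineString geometry found in {path}")
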