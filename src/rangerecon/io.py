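"""Plain-text raster/vector/point I/O.

Rasters use the ESRI ASCII grid format (one ``<period>_<var>.asc`` file
per layer per period; nodata encodes the validity mask), vectors use
GeoJSON, and point sets use CSV with a ``period,x,y`` header. All formats
are human-readable and diff-friendly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .types import EnvStack, GridSpec, OccurrenceSet

__all__ = [
    "write_ascii_grid", "read_ascii_grid",
    "write_stack", "read_stack",
    "write_occurrences", "read_occurrences",
    "write_geojson", "read_geojson",
]

_NODATA = -9999.0


def write_ascii_grid(path, values: np.ndarray, spec: GridSpec,
                     mask: np.ndarray | None = None) -> None:
    """One layer as an ESRI ASCII grid; masked cells become nodata."""
    values = np.asarray(values, dtype=float)
    out = values.copy()
    if mask is not None:
        out[~mask] = _NODATA
    out[~np.isfinite(out)] = _NODATA
    header = (f"ncols {spec.n_cols}\n"
              f"nrows {spec.n_rows}\n"
              f"xllcorner {spec.origin[0]}\n"
              f"yllcorner {spec.origin[1]}\n"
              f"cellsize {spec.cell_size}\n"
              f"NODATA_value {_NODATA}\n")
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.6g")


def read_ascii_grid(path) -> tuple[np.ndarray, GridSpec, np.ndarray]:
    """Returns (values with NaN at nodata, spec, valid mask)."""
    with open(path) as fh:
        head = {}
        for _ in range(6):
            key, val = fh.readline().split()
            head[key.lower()] = float(val)
        values = np.loadtxt(fh, ndmin=2)
    spec = GridSpec(n_rows=int(head["nrows"]), n_cols=int(head["ncols"]),
                    cell_size=head["cellsize"],
                    origin=(head["xllcorner"], head["yllcorner"]))
    nodata = head.get("nodata_value", _NODATA)
    mask = values != nodata
    values = np.where(mask, values, np.nan)
    return values, spec, mask


def write_stack(directory, stack: EnvStack) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for var, layer in stack.layers.items():
        write_ascii_grid(directory / f"{stack.period}_{var}.asc", layer,
                         stack.spec, stack.mask)


def read_stack(directory, period: str, variables) -> EnvStack:
    directory = Path(directory)
    layers, spec, mask = {}, None, None
    for var in variables:
        vals, sp, m = read_ascii_grid(directory / f"{period}_{var}.asc")
        layers[var] = vals
        spec = sp
        mask = m if mask is None else (mask & m)
    return EnvStack(period=period, layers=layers, spec=spec, mask=mask)


def write_occurrences(path, sets: list[OccurrenceSet]) -> None:
    rows = [{"period": s.period, "x": x, "y": y}
            for s in sets for x, y in s.points]
    pd.DataFrame(rows, columns=["period", "x", "y"]).to_csv(path, index=False)


def read_occurrences(path) -> list[OccurrenceSet]:
    df = pd.read_csv(path)
    return [OccurrenceSet(period=str(p), points=g[["x", "y"]].to_numpy())
            for p, g in df.groupby("period", sort=False)]


def write_geojson(path, geometries, properties: list[dict] | None = None) -> None:
    feats = []
    for i, geom in enumerate(geometries):
        props = properties[i] if properties else {"id": i}
        feats.append({"type": "Feature", "geometry": mapping(geom), "properties": props})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_geojson(path):
    with open(path) as fh:
        data = json.load(fh)
    return [shape(f["geometry"]) for f in data["features"]]
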