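"""File formats: trait CSV, ESRI ASCII climate grids, GeoJSON ranges,
presence-matrix and community-summary CSVs, fossil site CSVs, and the
self-describing fitted-model JSON.

Every CSV written here carries a ``#``-prefixed metadata header (package
version plus a hash of the generating configuration) and is written with a
fixed float format, so identical configs and seeds produce byte-identical
files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as shapely_shape

from ._version import __version__
from .communities import ClimateSurface, CommunityMatrix, TraitTable
from .model import EcometricResults, EcometricSpace
from .paleo import FossilAssemblage

__all__ = [
    "read_trait_table",
    "write_trait_table",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_climate_surface",
    "write_climate_surface",
    "read_ranges_geojson",
    "read_presence_matrix",
    "write_presence_matrix",
    "read_summaries",
    "write_summaries",
    "read_fossil_sites",
    "save_model",
    "load_model",
    "config_hash",
]

FLOAT_FMT = "%.10g"


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _metadata_header(config: dict | None) -> str:
    h = config_hash(config or {})
    return f"# ecometrics v{__version__} config_hash={h}\n"


def _write_csv(df: pd.DataFrame, path, config: dict | None, index: bool) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(_metadata_header(config))
        df.to_csv(fh, float_format=FLOAT_FMT, index=index, lineterminator="\n")


# -- trait tables ---------------------------------------------------------

def read_trait_table(path) -> TraitTable:
    """Read and validate a species trait CSV (columns: species, rbl,
    optional source). Duplicate species or out-of-range trait values are
    rejected with the offending rows named."""
    df = pd.read_csv(path, comment="#")
    return TraitTable(df)


def write_trait_table(traits: TraitTable, path, config: dict | None = None) -> None:
    _write_csv(traits.data, path, config, index=False)


# -- rasters (ESRI ASCII grid) --------------------------------------------

def read_ascii_grid(path) -> tuple[np.ndarray, float, float, float]:
    """Read an ESRI ASCII grid; returns (array[row0=south], cellsize,
    x0_center, y0_center)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
            "yllcenter", "cellsize", "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    data = np.loadtxt(lines[n_header:])
    data = np.atleast_2d(data)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if data.shape != (nrows, ncols):
        raise ValueError(f"grid shape {data.shape} != header ({nrows}, {ncols})")
    cell = header["cellsize"]
    if "xllcenter" in header:
        x0, y0 = header["xllcenter"], header["yllcenter"]
    else:
        x0 = header.get("xllcorner", 0.0) + cell / 2
        y0 = header.get("yllcorner", 0.0) + cell / 2
    return data[::-1], cell, x0, y0  # ASCII grids store north-up; we use south-up


def write_ascii_grid(array: np.ndarray, path, cellsize: float, x0: float = 0.0, y0: float = 0.0) -> None:
    """Write a south-up array as a north-up ESRI ASCII grid with cell-center
    origin (x0, y0)."""
    ny, nx = array.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {nx}\n")
        fh.write(f"nrows {ny}\n")
        fh.write(f"xllcenter {x0:.10g}\n")
        fh.write(f"yllcenter {y0:.10g}\n")
        fh.write(f"cellsize {cellsize:.10g}\n")
        fh.write("NODATA_value -9999\n")
        np.savetxt(fh, array[::-1], fmt=FLOAT_FMT)


def read_climate_surface(mat_path, ap_path) -> ClimateSurface:
    mat, cell, x0, y0 = read_ascii_grid(mat_path)
    ap, cell2, x02, y02 = read_ascii_grid(ap_path)
    if (cell, x0, y0) != (cell2, x02, y02):
        raise ValueError("MAT and AP grids are not aligned")
    return ClimateSurface(mat=mat, ap=ap, cell_size=cell, x0=x0, y0=y0)


def write_climate_surface(surface: ClimateSurface, mat_path, ap_path) -> None:
    write_ascii_grid(surface.mat, mat_path, surface.cell_size, surface.x0, surface.y0)
    write_ascii_grid(surface.ap, ap_path, surface.cell_size, surface.x0, surface.y0)


# -- ranges ---------------------------------------------------------------

def read_ranges_geojson(path) -> dict[str, shapely.Geometry]:
    """Read species range polygons from a GeoJSON FeatureCollection; the
    species name is taken from the ``species`` (or ``name``) property."""
    with open(path) as fh:
        gj = json.load(fh)
    ranges = {}
    for feat in gj.get("features", []):
        props = feat.get("properties") or {}
        name = props.get("species") or props.get("name")
        if name is None:
            raise ValueError("feature lacks a 'species' (or 'name') property")
        ranges[name] = shapely_shape(feat["geometry"])
    return ranges


# -- presence matrices ----------------------------------------------------

def read_presence_matrix(path) -> CommunityMatrix:
    df = pd.read_csv(path, comment="#", index_col="point_id")
    species = [c for c in df.columns if c not in ("x", "y")]
    return CommunityMatrix(
        points=df[["x", "y"]], presence=df[species].astype(bool)
    )


def write_presence_matrix(matrix: CommunityMatrix, path, config: dict | None = None) -> None:
    df = matrix.points.join(matrix.presence.astype(int))
    _write_csv(df, path, config, index=True)


# -- community summaries --------------------------------------------------

def read_summaries(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", index_col="point_id")


def write_summaries(summaries: pd.DataFrame, path, config: dict | None = None) -> None:
    _write_csv(summaries.rename_axis("point_id"), path, config, index=True)


# -- fossil sites ---------------------------------------------------------

def read_fossil_sites(path) -> list[FossilAssemblage]:
    """Read a long-format fossil CSV (one row per species occurrence:
    site, x, y, age_min_kya, age_max_kya, species, rbl, optional habitat)
    into one assemblage per site."""
    df = pd.read_csv(path, comment="#")
    required = {"site", "x", "y", "species", "rbl"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"fossil CSV missing columns: {sorted(missing)}")
    assemblages = []
    for site, g in df.groupby("site", sort=False):
        first = g.iloc[0]
        assemblages.append(
            FossilAssemblage(
                site=str(site),
                x=float(first["x"]),
                y=float(first["y"]),
                species=tuple(g["species"]),
                rbl=tuple(float(v) for v in g["rbl"]),
                age_min_kya=float(first.get("age_min_kya", float("nan"))),
                age_max_kya=float(first.get("age_max_kya", float("nan"))),
                habitat=str(first["habitat"]) if "habitat" in g.columns else "",
            )
        )
    return assemblages


# -- fitted models --------------------------------------------------------

def save_model(results: EcometricResults, path, config: dict | None = None) -> None:
    """Persist a fitted model as self-describing JSON: axis edges, per-bin
    estimates / bandwidths / counts, bandwidth rule, and metadata."""
    payload = {
        "format": "ecometrics-model",
        "version": __version__,
        "config_hash": config_hash(config or {}),
        "env": results.model.env,
        "n_bins": results.space.n_bins,
        "grid_size": results.model.grid_size,
        "bandwidth_rule": results.bandwidth_rule,
        "bandwidth_floor": results.bandwidth_floor,
        "mean_edges": results.space.mean_edges.tolist(),
        "sd_edges": results.space.sd_edges.tolist(),
        "peaks": [[None if np.isnan(v) else v for v in row] for row in results.peaks],
        "bandwidths": [
            [None if np.isnan(v) else v for v in row] for row in results.bandwidths
        ],
        "counts": results.counts.tolist(),
        "r_squared": results.r_squared,
        "r_squared_regression": results.r_squared_regression,
        "nobs": results.model.nobs,
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


class LoadedEcometricModel:
    """A fitted model restored from disk: supports ``predict`` with the
    same clamping / nearest-nonempty-bin rules as a freshly fitted one."""

    def __init__(self, payload: dict):
        self.env = payload["env"]
        self.space = EcometricSpace(
            n_bins=int(payload["n_bins"]),
            mean_edges=np.asarray(payload["mean_edges"], dtype=float),
            sd_edges=np.asarray(payload["sd_edges"], dtype=float),
        )
        self.peaks = np.array(
            [[np.nan if v is None else v for v in row] for row in payload["peaks"]]
        )
        self.counts = np.asarray(payload["counts"], dtype=int)
        self.r_squared = payload["r_squared"]
        self._nonempty = np.argwhere(~np.isnan(self.peaks))

    # mirror of EcometricResults.predict
    predict = EcometricResults.predict
    _nearest_nonempty = EcometricResults._nearest_nonempty

    @property
    def model(self):  # pragma: no cover - interface shim
        return self


def load_model(path) -> LoadedEcometricModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "ecometrics-model":
        raise ValueError(f"{path} is not an ecometrics model file")
    return LoadedEcometricModel(payload)
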