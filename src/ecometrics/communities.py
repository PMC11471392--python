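"""Community assembly: from species ranges and climate layers to filtered
community trait summaries.

The pipeline stage here mirrors standard ecometric data preparation:
sample a regular point grid over the study extent, overlay species range
polygons (or take a precomputed presence matrix), drop points with fewer
than three trait-bearing species, sample the climate layers at each
retained point (precipitation is log-transformed), and compute each
community's trait mean and sample standard deviation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

__all__ = [
    "TraitTable",
    "CommunityMatrix",
    "ClimateSurface",
    "sample_point_grid",
    "overlay_ranges",
    "filter_min_richness",
    "sample_climate",
    "summarize_traits",
]

MIN_RICHNESS = 3


@dataclass(frozen=True)
class ClimateSurface:
    """Gridded mean annual temperature (degC) and annual precipitation (mm)
    layers on a regular cell grid. ``x0``/``y0`` are the coordinates of the
    lower-left cell *center*; arrays are indexed ``[row, col]`` with row 0
    at ``y0`` (south) and col 0 at ``x0`` (west)."""

    mat: np.ndarray
    ap: np.ndarray
    cell_size: float
    x0: float = 0.0
    y0: float = 0.0

    def __post_init__(self):
        if self.mat.shape != self.ap.shape:
            raise ValueError("MAT and AP layers must have identical shape")
        if np.any(self.ap <= 0):
            raise ValueError("AP must be strictly positive everywhere")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mat.shape

    def cell_centers(self) -> pd.DataFrame:
        """All cell centers as a point table (point_id index, x, y)."""
        ny, nx = self.shape
        jj, ii = np.meshgrid(np.arange(nx), np.arange(ny))
        return pd.DataFrame(
            {
                "x": self.x0 + jj.ravel() * self.cell_size,
                "y": self.y0 + ii.ravel() * self.cell_size,
            },
            index=pd.RangeIndex(nx * ny, name="point_id"),
        )


class TraitTable:
    """Species -> trait mapping with provenance flags.

    Wraps a DataFrame with columns ``species`` (unique), ``rbl`` in [0, 1]
    (relative blade length: trigonid blade length / total m1 length) and an
    optional ``source`` flag (literature | measured | photo).
    """

    VALID_SOURCES = ("literature", "measured", "photo")

    def __init__(self, data: pd.DataFrame):
        if "species" not in data.columns or "rbl" not in data.columns:
            raise ValueError("trait table requires 'species' and 'rbl' columns")
        data = data.copy()
        if "source" not in data.columns:
            data["source"] = "literature"
        dup = data["species"][data["species"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate species in trait table: {sorted(set(dup))}")
        rbl = pd.to_numeric(data["rbl"], errors="coerce")
        bad = data.index[rbl.isna() | (rbl < 0) | (rbl > 1)].tolist()
        if bad:
            raise ValueError(f"RBL outside [0, 1] or missing at rows {bad}")
        data["rbl"] = rbl.astype(float)
        self.data = data.reset_index(drop=True)
        self._lookup = dict(zip(self.data["species"], self.data["rbl"]))

    def __len__(self) -> int:
        return len(self.data)

    def __contains__(self, species: str) -> bool:
        return species in self._lookup

    @property
    def species(self) -> list[str]:
        return list(self.data["species"])

    def rbl(self, species) -> np.ndarray:
        return np.array([self._lookup[s] for s in species], dtype=float)


@dataclass
class CommunityMatrix:
    """Point x species presence matrix with point coordinates.

    ``points`` — DataFrame (index point_id) with ``x``, ``y`` columns;
    ``presence`` — boolean DataFrame, same index, one column per species.
    """

    points: pd.DataFrame
    presence: pd.DataFrame

    def __post_init__(self):
        if not self.points.index.equals(self.presence.index):
            raise ValueError("points and presence must share the same point index")
        if not {"x", "y"} <= set(self.points.columns):
            raise ValueError("points must have x and y columns")
        self.presence = self.presence.astype(bool)

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def species(self) -> list[str]:
        return list(self.presence.columns)

    def richness(self, traits: TraitTable | None = None) -> pd.Series:
        """Species count per point; with ``traits`` given, only species that
        have trait values count."""
        pres = self.presence
        if traits is not None:
            keep = [s for s in pres.columns if s in traits]
            pres = pres[keep]
        return pres.sum(axis=1).rename("richness")


def sample_point_grid(extent, spacing: float) -> pd.DataFrame:
    """Regular point grid at the given spacing covering a projected extent.

    ``extent`` is ``(x0, y0, x1, y1)`` in the same (projected, nominally km
    or m) units as ``spacing``. Points are placed at cell centers of a
    ``ceil(width/spacing) x ceil(height/spacing)`` lattice, so a 100x100
    extent at spacing 50 yields 4 points.
    """
    x0, y0, x1, y1 = map(float, extent)
    width, height = x1 - x0, y1 - y0
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if width <= 0 or height <= 0:
        raise ValueError("extent is degenerate")
    ncol = max(1, math.ceil(width / spacing))
    nrow = max(1, math.ceil(height / spacing))
    if spacing > width and spacing > height:
        warnings.warn("spacing exceeds the extent; returning a single point")
    xs = x0 + (np.arange(ncol) + 0.5) * spacing
    ys = y0 + (np.arange(nrow) + 0.5) * spacing
    xx, yy = np.meshgrid(xs, ys)
    return pd.DataFrame(
        {"x": xx.ravel(), "y": yy.ravel()},
        index=pd.RangeIndex(ncol * nrow, name="point_id"),
    )


def overlay_ranges(points: pd.DataFrame, ranges: dict[str, BaseGeometry]) -> CommunityMatrix:
    """Overlay species range polygons on the sampling points.

    Presence is boundary-inclusive point-in-polygon (``shapely.covers``).
    Species with invalid geometry are skipped with a warning rather than
    aborting the overlay.
    """
    pts = shapely.points(points["x"].to_numpy(), points["y"].to_numpy())
    presence = {}
    for species, geom in ranges.items():
        if geom is None or not geom.is_valid:
            warnings.warn(f"invalid range geometry for {species!r}; species skipped")
            continue
        presence[species] = shapely.covers(geom, pts)
    return CommunityMatrix(
        points=points[["x", "y"]].copy(),
        presence=pd.DataFrame(presence, index=points.index, dtype=bool),
    )


def filter_min_richness(
    matrix: CommunityMatrix, traits: TraitTable, min_n: int = MIN_RICHNESS
) -> CommunityMatrix:
    """Keep only points hosting at least ``min_n`` species with trait
    values. Species lacking traits never count toward richness."""
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    richness = matrix.richness(traits)
    keep = richness[richness >= min_n].index
    if len(keep) == 0:
        raise ValueError(
            f"no points retain >= {min_n} trait-bearing species; lower min_n "
            "or supply more trait values"
        )
    return CommunityMatrix(
        points=matrix.points.loc[keep].copy(),
        presence=matrix.presence.loc[keep].copy(),
    )


def sample_climate(points: pd.DataFrame, surface: ClimateSurface) -> pd.DataFrame:
    """Sample MAT and AP at each point by nearest-cell lookup; returns a
    climate table (point_id index; mat, ap, log_ap columns)."""
    ny, nx = surface.shape
    col = np.rint((points["x"].to_numpy() - surface.x0) / surface.cell_size).astype(int)
    row = np.rint((points["y"].to_numpy() - surface.y0) / surface.cell_size).astype(int)
    outside = (col < 0) | (col >= nx) | (row < 0) | (row >= ny)
    if np.any(outside):
        bad = points.index[outside].tolist()
        raise ValueError(f"points outside the climate raster extent: {bad[:20]}")
    mat = surface.mat[row, col]
    ap = surface.ap[row, col]
    return pd.DataFrame(
        {"mat": mat, "ap": ap, "log_ap": np.log(ap)}, index=points.index
    )


def summarize_traits(matrix: CommunityMatrix, traits: TraitTable) -> pd.DataFrame:
    """Per-community trait mean and sample standard deviation (n-1).

    ``matrix`` must already be richness-filtered; any community with fewer
    than two trait-bearing species is a defensive error. Returns a
    DataFrame (point_id index) with x, y, richness, trait_mean, trait_sd.
    """
    keep = [s for s in matrix.presence.columns if s in traits]
    pres = matrix.presence[keep].to_numpy()
    rbl = traits.rbl(keep)
    richness = pres.sum(axis=1)
    if np.any(richness < 2):
        bad = matrix.points.index[richness < 2].tolist()
        raise ValueError(
            f"communities with <2 trait-bearing species (filter first): {bad[:20]}"
        )
    sums = pres @ rbl
    mean = sums / richness
    # sample SD with n-1 denominator
    sq = pres @ (rbl**2)
    var = (sq - richness * mean**2) / (richness - 1)
    sd = np.sqrt(np.clip(var, 0.0, None))
    out = matrix.points[["x", "y"]].copy()
    out["richness"] = richness
    out["trait_mean"] = mean
    out["trait_sd"] = sd
    return out


def build_summaries(
    matrix: CommunityMatrix,
    traits: TraitTable,
    surface: ClimateSurface,
    min_n: int = MIN_RICHNESS,
) -> pd.DataFrame:
    """Full stage: filter, summarize, attach climate. Returns the community
    summary table consumed by :class:`~ecometrics.model.EcometricModel`."""
    filtered = filter_min_richness(matrix, traits, min_n=min_n)
    summ = summarize_traits(filtered, traits)
    clim = sample_climate(filtered.points, surface)
    return summ.join(clim)
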