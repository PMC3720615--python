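"""Equal-area gridding of species range maps.

Builds a square analysis grid (default 100 × 100 km) in a cylindrical
equal-area projection, rasterizes range polygons into a cells × species
presence–absence matrix, and derives per-cell species richness.

A species is marked present in a cell when its projected range polygon
intersects the cell square with positive area — the common convention for
presence–absence gridding of expert range maps; a center-in-polygon rule
is available behind a flag.  Cells that end up with zero total richness
are kept in the tables but flagged, and the statistical stages exclude
them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box, shape, mapping
from shapely.geometry.base import BaseGeometry
from shapely.ops import transform as shp_transform, unary_union
from shapely.strtree import STRtree
from shapely.validation import make_valid

from .projection import CylindricalEqualArea

logger = logging.getLogger(__name__)


class RangeFormatError(ValueError):
    """Raised for malformed range-map files."""


@dataclass
class RangeSet:
    """Mapping species id → range geometry in geographic (lon/lat) degrees."""

    geoms: dict[str, BaseGeometry] = field(default_factory=dict)

    @property
    def species(self) -> list[str]:
        return list(self.geoms)

    def __len__(self) -> int:
        return len(self.geoms)

    def __getitem__(self, sp: str) -> BaseGeometry:
        return self.geoms[sp]

    def __contains__(self, sp: str) -> bool:
        return sp in self.geoms


def read_ranges(path, species_property: str = "species") -> RangeSet:
    """Read a GeoJSON FeatureCollection of species ranges.

    Multiple features sharing a species name are merged into one
    (multi-)polygon.  Invalid geometries are repaired with
    ``shapely.make_valid``; a geometry that cannot be repaired into a
    polygonal shape is rejected with the species named in the error.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise RangeFormatError(f"{path}: not a GeoJSON FeatureCollection")
    per_species: dict[str, list[BaseGeometry]] = {}
    for i, feat in enumerate(doc.get("features", [])):
        props = feat.get("properties") or {}
        if species_property not in props:
            raise RangeFormatError(
                f"{path}: feature {i} lacks the '{species_property}' property"
            )
        sp = str(props[species_property])
        geom = shape(feat["geometry"])
        if not geom.is_valid:
            geom = make_valid(geom)
        geom = _polygonal_part(geom, sp)
        per_species.setdefault(sp, []).append(geom)
    geoms = {sp: unary_union(gs) if len(gs) > 1 else gs[0]
             for sp, gs in per_species.items()}
    return RangeSet(geoms)


def _polygonal_part(geom: BaseGeometry, sp: str) -> BaseGeometry:
    if geom.geom_type in ("Polygon", "MultiPolygon"):
        return geom
    if geom.geom_type == "GeometryCollection":
        polys = [g for g in geom.geoms if g.geom_type in ("Polygon", "MultiPolygon")]
        if polys:
            return unary_union(polys)
    raise RangeFormatError(f"species {sp!r}: geometry is not polygonal after repair")


def write_ranges(ranges: RangeSet, path) -> None:
    """Write a RangeSet as a GeoJSON FeatureCollection (one feature/species)."""
    features = [
        {"type": "Feature", "properties": {"species": sp}, "geometry": mapping(geom)}
        for sp, geom in ranges.geoms.items()
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


@dataclass(frozen=True)
class EqualAreaGrid:
    """Square analysis grid in an equal-area projection.

    Cells are congruent ``cell_km`` × ``cell_km`` squares in projected
    space, indexed row-major from the grid origin, which is snapped to a
    multiple of the cell size so that grids over nested bounding boxes
    (under the same projection) share cell boundaries.
    """

    projection: CylindricalEqualArea
    cell_km: float
    origin_x_m: float
    origin_y_m: float
    nx: int
    ny: int

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @property
    def cell_m(self) -> float:
        return self.cell_km * 1000.0

    def _centers(self) -> tuple[np.ndarray, np.ndarray]:
        ix = np.arange(self.n_cells) % self.nx
        iy = np.arange(self.n_cells) // self.nx
        x = self.origin_x_m + (ix + 0.5) * self.cell_m
        y = self.origin_y_m + (iy + 0.5) * self.cell_m
        return x, y

    @property
    def x_m(self) -> np.ndarray:
        return self._centers()[0]

    @property
    def y_m(self) -> np.ndarray:
        return self._centers()[1]

    @property
    def lon_deg(self) -> np.ndarray:
        return self.projection.inverse(*self._centers())[0]

    @property
    def lat_deg(self) -> np.ndarray:
        return self.projection.inverse(*self._centers())[1]

    def cell_box(self, cell_id: int):
        ix = cell_id % self.nx
        iy = cell_id // self.nx
        x0 = self.origin_x_m + ix * self.cell_m
        y0 = self.origin_y_m + iy * self.cell_m
        return box(x0, y0, x0 + self.cell_m, y0 + self.cell_m)

    def cell_boxes(self) -> list:
        return [self.cell_box(i) for i in range(self.n_cells)]

    def cell_table(self) -> pd.DataFrame:
        x, y = self._centers()
        lon, lat = self.projection.inverse(x, y)
        return pd.DataFrame(
            {"cell_id": np.arange(self.n_cells), "x_m": x, "y_m": y,
             "latitude_deg": lat, "longitude_deg": lon}
        )


def build_grid(
    bbox: tuple[float, float, float, float],
    cell_km: float = 100.0,
    projection: CylindricalEqualArea | None = None,
) -> EqualAreaGrid:
    """Build the equal-area analysis grid covering a geographic bbox.

    ``bbox`` is (lon_min, lon_max, lat_min, lat_max) in degrees.  When no
    projection is given, a cylindrical equal-area projection with standard
    parallel 30° and central meridian at the bbox longitude center is
    constructed.  The grid origin is the projected bbox lower-left corner
    snapped down to a multiple of the cell size, so nested bboxes under a
    shared projection yield aligned (subset) grids.
    """
    lon_min, lon_max, lat_min, lat_max = bbox
    if not (lon_min < lon_max and lat_min < lat_max):
        raise ValueError(f"degenerate bbox {bbox}")
    if cell_km <= 0:
        raise ValueError("cell_km must be positive")
    if projection is None:
        projection = CylindricalEqualArea(central_meridian=0.5 * (lon_min + lon_max))
    x0, y0 = projection.forward(lon_min, lat_min)
    x1, y1 = projection.forward(lon_max, lat_max)
    cell_m = cell_km * 1000.0
    ox = np.floor(x0 / cell_m) * cell_m
    oy = np.floor(y0 / cell_m) * cell_m
    nx = int(np.ceil((x1 - ox) / cell_m))
    ny = int(np.ceil((y1 - oy) / cell_m))
    return EqualAreaGrid(projection=projection, cell_km=cell_km,
                         origin_x_m=float(ox), origin_y_m=float(oy), nx=nx, ny=ny)


@dataclass
class PresenceMatrix:
    """Boolean cells × species occupancy on an equal-area grid."""

    grid: EqualAreaGrid
    species: list[str]
    matrix: np.ndarray  # bool, shape (n_cells, n_species)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=bool)
        if self.matrix.shape != (self.grid.n_cells, len(self.species)):
            raise ValueError(
                f"presence matrix shape {self.matrix.shape} inconsistent with "
                f"{self.grid.n_cells} cells × {len(self.species)} species"
            )

    @property
    def occupied(self) -> np.ndarray:
        """Boolean mask of cells with at least one species present."""
        return self.matrix.any(axis=1)

    def to_triplets(self) -> pd.DataFrame:
        cells, sps = np.nonzero(self.matrix)
        return pd.DataFrame(
            {"cell_id": cells, "species": [self.species[j] for j in sps],
             "present": np.ones(len(cells), dtype=int)}
        )


def rasterize(
    ranges: RangeSet,
    grid: EqualAreaGrid,
    rule: str = "area",
) -> PresenceMatrix:
    """Rasterize range polygons into a presence–absence matrix.

    rule="area" (default): present iff the projected polygon intersects
    the cell square with positive area.  rule="center": present iff the
    cell center falls inside the polygon.  Species whose ranges miss the
    grid entirely produce all-false columns and a logged warning.
    """
    if len(ranges) == 0:
        raise ValueError("empty RangeSet")
    if rule not in ("area", "center"):
        raise ValueError(f"unknown occupancy rule {rule!r}")
    species = ranges.species
    pm = np.zeros((grid.n_cells, len(species)), dtype=bool)
    boxes = grid.cell_boxes()
    tree = STRtree(boxes)
    centers = shapely.points(grid.x_m, grid.y_m)
    fwd = grid.projection.forward
    for j, sp in enumerate(species):
        geom = ranges[sp]
        try:
            proj = shp_transform(lambda lon, lat: fwd(lon, lat), geom)
        except Exception as exc:
            raise RuntimeError(f"projection failed for species {sp!r}: {exc}") from exc
        if rule == "area":
            cand = tree.query(proj, predicate="intersects")
            hits = [c for c in cand if shapely.intersection(proj, boxes[c]).area > 0]
        else:
            hits = np.nonzero(shapely.contains(proj, centers))[0]
        if len(hits) == 0:
            logger.warning("species %r: range does not reach the grid", sp)
        pm[hits, j] = True
    return PresenceMatrix(grid=grid, species=species, matrix=pm)


def richness(pm: PresenceMatrix, species_subset=None) -> np.ndarray:
    """Per-cell count of present species, optionally within a subset."""
    if species_subset is None:
        return pm.matrix.sum(axis=1).astype(int)
    subset = set(species_subset)
    unknown = subset - set(pm.species)
    if unknown:
        raise ValueError(f"unknown species in subset: {sorted(unknown)}")
    cols = [i for i, sp in enumerate(pm.species) if sp in subset]
    if not cols:
        return np.zeros(pm.grid.n_cells, dtype=int)
    return pm.matrix[:, cols].sum(axis=1).astype(int)


def write_grid_outputs(pm: PresenceMatrix, outdir) -> dict[str, Path]:
    """Write the cell table, sparse presence triplets and richness CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cells": outdir / "cells.csv",
        "presence": outdir / "presence.csv",
        "richness": outdir / "richness.csv",
    }
    pm.grid.cell_table().to_csv(paths["cells"], index=False)
    pm.to_triplets().to_csv(paths["presence"], index=False)
    pd.DataFrame(
        {"cell_id": np.arange(pm.grid.n_cells), "richness": richness(pm),
         "occupied": pm.occupied.astype(int)}
    ).to_csv(paths["richness"], index=False)
    return paths
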