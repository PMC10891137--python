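"""Raster and point-grid I/O for categorical land-use/land-cover (LULC) maps.

Rasters are single-band GeoTIFFs: integer class codes for LULC maps, float32
for continuous predictor layers.  Georeferencing is written and read through
the standard GeoTIFF tags (ModelPixelScale, ModelTiepoint, GeoKeyDirectory,
GDAL nodata), so files interoperate with GDAL-based GIS software.

The point-grid CSV dialect mirrors national land-statistics products that
distribute LULC as a regular point lattice: columns ``E`` and ``N`` carry the
easting/northing of each cell centre and one integer class column per
time-step.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "NODATA",
    "Grid",
    "ClassDef",
    "ClassCodebook",
    "LULCMap",
    "PredictorLayer",
    "PredictorStack",
    "GridAlignmentError",
    "points_to_raster",
    "raster_to_points",
    "read_map",
    "write_map",
    "read_layer",
    "write_layer",
    "read_point_grid_csv",
    "write_point_grid_csv",
    "write_palette_csv",
    "swiss_codebook",
    "synthetic_codebook",
]

#: Nodata code for categorical rasters; class codes start at 1.
NODATA = 0

# GeoTIFF / GDAL tag codes
_TAG_PIXELSCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEOKEYDIR = 34735
_TAG_GDAL_NODATA = 42113


class GridAlignmentError(ValueError):
    """Two rasters do not share an identical grid."""


@dataclass(frozen=True)
class Grid:
    """Regular north-up raster grid in a projected coordinate system.

    ``origin_easting``/``origin_northing`` locate the outer corner of the
    top-left cell; row 0 is the northernmost row.  Two grids are *aligned*
    iff every field is equal — rasters are never silently resampled.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    origin_easting: float
    origin_northing: float
    crs_id: str = "EPSG:2056"

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid must have positive dimensions")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(easting, northing) of the centre of cell ``(row, col)``."""
        e = self.origin_easting + (col + 0.5) * self.cell_size
        n = self.origin_northing - (row + 0.5) * self.cell_size
        return (e, n)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays of (easting, northing) cell centres, shape (n_rows, n_cols)."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        e = self.origin_easting + (cols + 0.5) * self.cell_size
        n = self.origin_northing - (rows + 0.5) * self.cell_size
        return np.broadcast_to(e, self.shape).copy(), np.broadcast_to(
            n[:, None], self.shape
        ).copy()

    def aligned_with(self, other: "Grid") -> bool:
        return self == other

    def require_aligned(self, other: "Grid", what: str = "raster") -> None:
        if not self.aligned_with(other):
            raise GridAlignmentError(f"{what} grid {other} is not aligned with {self}")


@dataclass(frozen=True)
class ClassDef:
    """One LULC class: integer raster code, name, and modelling role.

    ``fine_ids`` lists the high-thematic-resolution codes that a *static*
    aggregate class resolves to in the final maps.
    """

    id: int
    name: str
    modelled: bool
    static: bool
    fine_ids: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.modelled == self.static:
            raise ValueError(
                f"class {self.id} must be exactly one of modelled/static"
            )


@dataclass(frozen=True)
class ClassCodebook:
    """Set of LULC classes with modelled/static partition and name aliases."""

    classes: tuple[ClassDef, ...]
    aliases: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.classes]
        if len(set(ids)) != len(ids):
            raise ValueError("class ids must be unique")
        if NODATA in ids:
            raise ValueError(f"class id {NODATA} is reserved for nodata")

    @property
    def ids(self) -> tuple[int, ...]:
        return tuple(c.id for c in self.classes)

    @property
    def modelled_ids(self) -> tuple[int, ...]:
        return tuple(c.id for c in self.classes if c.modelled)

    @property
    def static_ids(self) -> tuple[int, ...]:
        return tuple(c.id for c in self.classes if c.static)

    def __getitem__(self, class_id: int) -> ClassDef:
        for c in self.classes:
            if c.id == class_id:
                return c
        raise KeyError(f"unknown class id {class_id}")

    def __contains__(self, class_id: int) -> bool:
        return any(c.id == class_id for c in self.classes)

    def id_of(self, name: str) -> int:
        name = self.aliases.get(name, name)
        for c in self.classes:
            if c.name == name:
                return c.id
        raise KeyError(f"unknown class name {name!r}")

    def names(self) -> dict[int, str]:
        return {c.id: c.name for c in self.classes}


def swiss_codebook() -> ClassCodebook:
    """The 17-class Swiss land-statistics codebook (14 modelled, 3 static).

    Static aggregates map onto the fine 26-code thematic resolution used in
    the published maps: Transportation resolves to nine fine classes (codes
    15–23), Lakes stays a single class (24), Rivers splits into Rivers and
    Flood protection structures (25–26).
    """
    m = lambda i, n: ClassDef(i, n, modelled=True, static=False)
    classes = (
        m(1, "Industry"),
        m(2, "Building"),
        m(3, "Special urban"),
        m(4, "Urban green"),
        m(5, "Horticulture"),
        m(6, "Arable"),
        m(7, "Grassland"),
        m(8, "Alpine grassland"),
        m(9, "Forest"),
        m(10, "Brush"),
        m(11, "Trees"),
        m(12, "Unproductive vegetation"),
        m(13, "Bare land"),
        m(14, "Glacier"),
        ClassDef(15, "Transportation", modelled=False, static=True,
                 fine_ids=tuple(range(15, 24))),
        ClassDef(16, "Lakes", modelled=False, static=True, fine_ids=(24,)),
        ClassDef(17, "Rivers", modelled=False, static=True, fine_ids=(25, 26)),
    )
    aliases = {"Orchard": "Horticulture", "Bare rock": "Bare land"}
    return ClassCodebook(classes, aliases)


def synthetic_codebook(n_classes: int, static_ids: Iterable[int] = ()) -> ClassCodebook:
    """Codebook for a synthetic landscape: classes 1..n, given ids static."""
    static = set(static_ids)
    classes = tuple(
        ClassDef(i, f"class_{i}", modelled=i not in static, static=i in static)
        for i in range(1, n_classes + 1)
    )
    return ClassCodebook(classes)


@dataclass
class LULCMap:
    """Integer-coded categorical raster with a class codebook and valid mask.

    Invalid (outside study area) cells carry the nodata code.
    """

    grid: Grid
    codes: np.ndarray
    codebook: ClassCodebook
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int32)
        if self.codes.shape != self.grid.shape:
            raise ValueError("codes shape does not match grid")
        if self.valid_mask is None:
            self.valid_mask = self.codes != NODATA
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != self.grid.shape:
            raise ValueError("valid_mask shape does not match grid")
        self.codes = np.where(self.valid_mask, self.codes, NODATA)
        present = np.unique(self.codes[self.valid_mask])
        unknown = [int(v) for v in present if v not in self.codebook]
        if unknown:
            raise ValueError(f"codes not in codebook: {unknown}")

    def counts(self, ids: Sequence[int] | None = None) -> dict[int, int]:
        """Valid-cell count per class id."""
        ids = list(ids if ids is not None else self.codebook.ids)
        vals = self.codes[self.valid_mask]
        return {i: int(np.sum(vals == i)) for i in ids}

    def dynamic_mask(self) -> np.ndarray:
        """Valid cells whose class is modelled (the allocation universe)."""
        dyn = np.isin(self.codes, self.codebook.modelled_ids)
        return dyn & self.valid_mask

    def with_codes(self, codes: np.ndarray) -> "LULCMap":
        return LULCMap(self.grid, codes, self.codebook, self.valid_mask.copy())

    def copy(self) -> "LULCMap":
        return self.with_codes(self.codes.copy())


@dataclass(frozen=True)
class PredictorLayer:
    """One predictor raster layer, tagged continuous or categorical."""

    name: str
    kind: str  # "continuous" | "categorical"
    data: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        arr = np.asarray(
            self.data, dtype=np.float64 if self.kind == "continuous" else np.int32
        )
        object.__setattr__(self, "data", arr)


@dataclass
class PredictorStack:
    """Named predictor layers, all aligned to one grid."""

    grid: Grid
    layers: dict[str, PredictorLayer] = field(default_factory=dict)

    def add(self, layer: PredictorLayer) -> None:
        if layer.data.shape != self.grid.shape:
            raise GridAlignmentError(
                f"layer {layer.name!r} shape {layer.data.shape} != grid {self.grid.shape}"
            )
        self.layers[layer.name] = layer

    def __getitem__(self, name: str) -> PredictorLayer:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    @property
    def continuous_names(self) -> list[str]:
        return [n for n, l in self.layers.items() if l.kind == "continuous"]

    @property
    def categorical_names(self) -> list[str]:
        return [n for n, l in self.layers.items() if l.kind == "categorical"]


# ---------------------------------------------------------------------------
# Point grid <-> raster
# ---------------------------------------------------------------------------

def points_to_raster(
    points: pd.DataFrame,
    cell_size: float,
    codebook: ClassCodebook,
    *,
    easting_col: str = "E",
    northing_col: str = "N",
    class_col: str | None = None,
    crs_id: str = "EPSG:2056",
) -> LULCMap:
    """Rasterise a regular point lattice of class codes.

    Each point's value fills the ``cell_size`` cell centred on it; cells with
    no point are nodata.  Point spacing must be an integer multiple of
    ``cell_size`` (tolerance 1e-6 of a cell); two points in one cell is an
    error.
    """
    if class_col is None:
        extra = [c for c in points.columns if c not in (easting_col, northing_col)]
        if len(extra) != 1:
            raise ValueError("class_col must be given when several class columns exist")
        class_col = extra[0]
    e = np.asarray(points[easting_col], dtype=float)
    n = np.asarray(points[northing_col], dtype=float)
    v = np.asarray(points[class_col], dtype=int)
    if len(e) == 0:
        raise ValueError("empty point table")
    tol = 1e-6 * cell_size
    origin_e = e.min() - cell_size / 2.0
    origin_n = n.max() + cell_size / 2.0
    fc = (e - (origin_e + cell_size / 2.0)) / cell_size
    fr = ((origin_n - cell_size / 2.0) - n) / cell_size
    col = np.rint(fc).astype(int)
    row = np.rint(fr).astype(int)
    if np.any(np.abs(fc - col) * cell_size > tol) or np.any(
        np.abs(fr - row) * cell_size > tol
    ):
        raise ValueError("irregular point spacing: points do not sit on a "
                         f"{cell_size} m lattice")
    n_rows = int(row.max()) + 1
    n_cols = int(col.max()) + 1
    flat = row * n_cols + col
    if len(np.unique(flat)) != len(flat):
        raise ValueError("duplicate points within one cell")
    grid = Grid(n_rows, n_cols, cell_size, origin_e, origin_n, crs_id)
    codes = np.full(grid.shape, NODATA, dtype=np.int32)
    codes[row, col] = v
    return LULCMap(grid, codes, codebook)


def raster_to_points(lulc: LULCMap, class_col: str = "LULC") -> pd.DataFrame:
    """Inverse of :func:`points_to_raster`: one row per valid cell centre."""
    rows, cols = np.nonzero(lulc.valid_mask)
    e = lulc.grid.origin_easting + (cols + 0.5) * lulc.grid.cell_size
    n = lulc.grid.origin_northing - (rows + 0.5) * lulc.grid.cell_size
    return pd.DataFrame(
        {"E": e, "N": n, class_col: lulc.codes[rows, cols]}
    )


# ---------------------------------------------------------------------------
# GeoTIFF I/O
# ---------------------------------------------------------------------------

def _epsg_code(crs_id: str) -> int:
    m = re.fullmatch(r"EPSG:(\d+)", crs_id)
    return int(m.group(1)) if m else 32767  # user-defined


def _geo_extratags(grid: Grid, nodata) -> list:
    keydir = (
        1, 1, 0, 3,
        1024, 0, 1, 1,      # model type: projected
        1025, 0, 1, 1,      # raster pixel is area
        3072, 0, 1, _epsg_code(grid.crs_id),
    )
    return [
        (_TAG_PIXELSCALE, "d", 3, (float(grid.cell_size), float(grid.cell_size), 0.0), False),
        (_TAG_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, float(grid.origin_easting), float(grid.origin_northing), 0.0),
         False),
        (_TAG_GEOKEYDIR, "H", len(keydir), keydir, False),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata), False),
    ]


def _read_grid(page, shape) -> tuple[Grid, str]:
    try:
        sx, sy, _ = page.tags[_TAG_PIXELSCALE].value
        tp = page.tags[_TAG_TIEPOINT].value
        keydir = page.tags[_TAG_GEOKEYDIR].value
    except KeyError as exc:
        raise ValueError("raster lacks georeferencing tags") from exc
    if abs(sx - sy) > 1e-9:
        raise ValueError("non-square cells are not supported")
    epsg = 32767
    for i in range(4, len(keydir), 4):
        if keydir[i] == 3072:
            epsg = keydir[i + 3]
    nodata = page.tags[_TAG_GDAL_NODATA].value if _TAG_GDAL_NODATA in page.tags else None
    grid = Grid(shape[0], shape[1], float(sx), float(tp[3]), float(tp[4]),
                f"EPSG:{epsg}" if epsg != 32767 else "USER")
    return grid, nodata


def write_map(lulc: LULCMap, path: str | Path) -> None:
    """Write a categorical LULC raster as a single-band integer GeoTIFF."""
    tifffile.imwrite(
        str(path),
        lulc.codes.astype(np.int16),
        extratags=_geo_extratags(lulc.grid, NODATA),
    )


def read_map(
    path: str | Path,
    codebook: ClassCodebook,
    expected_grid: Grid | None = None,
) -> LULCMap:
    """Read a categorical GeoTIFF; unknown codes and grid mismatches error."""
    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        codes = page.asarray().astype(np.int32)
        grid, _ = _read_grid(page, codes.shape)
    if expected_grid is not None:
        expected_grid.require_aligned(grid, what=str(path))
    return LULCMap(grid, codes, codebook)


def write_layer(layer: PredictorLayer, grid: Grid, path: str | Path) -> None:
    """Write one predictor layer (float32 continuous / int16 categorical)."""
    if layer.kind == "continuous":
        data = layer.data.astype(np.float32)
        nodata = "nan"
    else:
        data = layer.data.astype(np.int16)
        nodata = str(NODATA)
    tifffile.imwrite(str(path), data, extratags=_geo_extratags(grid, nodata))


def read_layer(path: str | Path, name: str, kind: str,
               expected_grid: Grid | None = None) -> tuple[PredictorLayer, Grid]:
    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        data = page.asarray()
        grid, _ = _read_grid(page, data.shape)
    if expected_grid is not None:
        expected_grid.require_aligned(grid, what=str(path))
    return PredictorLayer(name, kind, data), grid


# ---------------------------------------------------------------------------
# Point-grid CSV (land-statistics dialect)
# ---------------------------------------------------------------------------

def write_point_grid_csv(
    maps: Sequence[LULCMap], labels: Sequence[str], path: str | Path
) -> None:
    """Write a multi-step point-grid CSV: columns E, N, one class col per step."""
    if len(maps) != len(labels):
        raise ValueError("one label per map required")
    base = maps[0]
    for m in maps[1:]:
        base.grid.require_aligned(m.grid)
        if not np.array_equal(base.valid_mask, m.valid_mask):
            raise ValueError("maps have differing valid masks")
    df = raster_to_points(base, class_col=labels[0])
    rows, cols = np.nonzero(base.valid_mask)
    for m, lab in zip(maps[1:], labels[1:]):
        df[lab] = m.codes[rows, cols]
    df.to_csv(path, index=False)


def read_point_grid_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("E", "N"):
        if col not in df.columns:
            raise ValueError(f"point-grid CSV lacks column {col!r}")
    return df


def write_palette_csv(codebook: ClassCodebook, colours: Mapping[int, str],
                      path: str | Path) -> None:
    """Write a plotting palette CSV with columns Description, Colour."""
    rows = [{"Description": c.name, "Colour": colours.get(c.id, "#000000")}
            for c in codebook.classes]
    pd.DataFrame(rows).to_csv(path, index=False)
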