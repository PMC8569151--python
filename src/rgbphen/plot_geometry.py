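"""Raster / fishnet I/O and per-plot zonal extraction of mean digital numbers.

Rasters are single-band DN grids with a 6-term affine geotransform mapping
pixel ``(col, row)`` to world ``(x, y)``.  The transform follows the ESRI
world-file convention: the translation terms refer to the *center* of the
top-left pixel, so pixel centers sit at integer ``(col, row)``.

A pixel belongs to a polygon iff its center lies inside, with the boundary
counting as inside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
from PIL import Image
from shapely.geometry import Polygon

__all__ = [
    "Affine",
    "BandRaster",
    "SceneRaster",
    "PlotPolygon",
    "Fishnet",
    "ZonalResult",
    "ZonalError",
    "read_scene",
    "write_scene",
    "read_fishnet",
    "write_fishnet",
    "zonal_mean_dn",
    "zonal_results_to_frame",
    "average_rows_to_plot",
]


@dataclass(frozen=True)
class Affine:
    """x = a*col + b*row + c ; y = d*col + e*row + f (pixel-center origin)."""

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    def __post_init__(self) -> None:
        if abs(self.a * self.e - self.b * self.d) < 1e-30:
            raise ValueError("affine transform is not invertible")

    def pixel_to_world(self, col, row):
        return (
            self.a * np.asarray(col) + self.b * np.asarray(row) + self.c,
            self.d * np.asarray(col) + self.e * np.asarray(row) + self.f,
        )

    def world_to_pixel(self, x, y):
        det = self.a * self.e - self.b * self.d
        dx = np.asarray(x) - self.c
        dy = np.asarray(y) - self.f
        col = (self.e * dx - self.b * dy) / det
        row = (self.a * dy - self.d * dx) / det
        return col, row

    def translate(self, dx: float, dy: float) -> "Affine":
        return Affine(self.a, self.b, self.c + dx, self.d, self.e, self.f + dy)

    def to_world_file(self) -> str:
        # world-file line order: a, d, b, e, c, f
        return "\n".join(
            f"{v:.12f}" for v in (self.a, self.d, self.b, self.e, self.c, self.f)
        ) + "\n"

    @classmethod
    def from_world_file(cls, text: str) -> "Affine":
        vals = [float(t) for t in text.split()]
        if len(vals) != 6:
            raise ValueError("world file must contain exactly 6 numbers")
        a, d, b, e, c, f = vals
        return cls(a, b, c, d, e, f)

    @classmethod
    def identity(cls) -> "Affine":
        return cls(1.0, 0.0, 0.0, 0.0, 1.0, 0.0)


@dataclass
class BandRaster:
    """One band of digital numbers with its geotransform and bit depth."""

    values: np.ndarray
    bit_depth: int
    transform: Affine

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("raster grid must be 2-D and non-empty")
        if self.bit_depth < 1:
            raise ValueError("bit depth must be >= 1")
        lo, hi = float(self.values.min()), float(self.values.max())
        if lo < 0 or hi > self.dn_max:
            raise ValueError(
                f"DN range [{lo}, {hi}] outside [0, {self.dn_max}] "
                f"for bit depth {self.bit_depth}"
            )

    @property
    def dn_max(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class SceneRaster:
    """Three co-registered DN bands in fixed R, G, B order."""

    red: BandRaster
    green: BandRaster
    blue: BandRaster

    def __post_init__(self) -> None:
        shapes = {self.red.shape, self.green.shape, self.blue.shape}
        if len(shapes) != 1:
            raise ValueError(f"band shapes differ: {sorted(shapes)}")
        transforms = {self.red.transform, self.green.transform, self.blue.transform}
        if len(transforms) != 1:
            raise ValueError("band geotransforms differ")

    @property
    def shape(self) -> tuple[int, int]:
        return self.red.shape

    @property
    def transform(self) -> Affine:
        return self.red.transform

    @property
    def bands(self) -> dict[str, BandRaster]:
        return {"red": self.red, "green": self.green, "blue": self.blue}


@dataclass
class PlotPolygon:
    """One fishnet polygon in world coordinates.

    ``plot_id`` identifies the polygon uniquely; for multi-row plots the
    ``row`` attribute links row polygons that share a parent plot.
    """

    plot_id: str
    genotype: str
    rep: int
    ring: Sequence[tuple[float, float]]
    row: int | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        poly = Polygon(self.ring)
        if not poly.is_valid or poly.is_empty:
            raise ValueError(f"plot {self.plot_id}: ring is not a valid simple polygon")
        if poly.area <= 0:
            raise ValueError(f"plot {self.plot_id}: polygon area must be > 0")
        self._geom = poly

    @property
    def geometry(self) -> Polygon:
        return self._geom


@dataclass
class Fishnet:
    polygons: list[PlotPolygon]

    def __post_init__(self) -> None:
        ids = [p.plot_id for p in self.polygons]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate plot_ids in fishnet: {dupes}")

    def __iter__(self):
        return iter(self.polygons)

    def __len__(self) -> int:
        return len(self.polygons)

    def translate(self, dx: float, dy: float) -> "Fishnet":
        moved = [
            PlotPolygon(
                p.plot_id,
                p.genotype,
                p.rep,
                [(x + dx, y + dy) for x, y in p.ring],
                row=p.row,
                extra=dict(p.extra),
            )
            for p in self.polygons
        ]
        return Fishnet(moved)


@dataclass(frozen=True)
class ZonalResult:
    plot_id: str
    mean_dn_red: float
    mean_dn_green: float
    mean_dn_blue: float
    pixel_count: int


@dataclass(frozen=True)
class ZonalError:
    plot_id: str
    reason: str


# ---------------------------------------------------------------------------
# raster I/O -- plain TIFF/PNG plus an ESRI world file (.tfw/.pgw)


def _world_file_path(path: Path) -> Path:
    suffix = path.suffix.lower()
    mapping = {".tif": ".tfw", ".tiff": ".tfw", ".png": ".pgw"}
    return path.with_suffix(mapping.get(suffix, path.suffix + "w"))


def _read_band_values(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return np.asarray(tifffile.imread(path))
    return np.asarray(Image.open(path))


def _write_band_values(path: Path, values: np.ndarray) -> None:
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, values)
    else:
        Image.fromarray(values).save(path)


def read_scene(paths: Sequence[str | Path], bit_depth: int) -> SceneRaster:
    """Read a scene from three single-band files or one 3-channel file.

    Each file needs a sibling world file; for a 3-channel file the channel
    order is fixed as R, G, B.
    """
    paths = [Path(p) for p in paths]
    for p in paths:
        if not p.exists():
            raise FileNotFoundError(p)
    if len(paths) == 1:
        arr = _read_band_values(paths[0])
        if arr.ndim != 3 or arr.shape[2] < 3:
            raise ValueError("single-file scene must have >= 3 channels")
        transform = Affine.from_world_file(_world_file_path(paths[0]).read_text())
        bands = [arr[:, :, i] for i in range(3)]
        transforms = [transform] * 3
    elif len(paths) == 3:
        bands, transforms = [], []
        for p in paths:
            arr = _read_band_values(p)
            if arr.ndim != 2:
                raise ValueError(f"{p}: expected a single-band raster")
            bands.append(arr)
            transforms.append(Affine.from_world_file(_world_file_path(p).read_text()))
    else:
        raise ValueError("expected one 3-channel path or three single-band paths")
    shapes = {b.shape for b in bands}
    if len(shapes) != 1:
        raise ValueError(f"band shapes differ: {sorted(shapes)}")
    r, g, b = (
        BandRaster(v, bit_depth, t) for v, t in zip(bands, transforms)
    )
    return SceneRaster(r, g, b)


def write_scene(scene: SceneRaster, paths: Sequence[str | Path]) -> None:
    """Write each band to its own file plus a world file."""
    paths = [Path(p) for p in paths]
    if len(paths) != 3:
        raise ValueError("expected three output paths (red, green, blue)")
    dtype = np.uint8 if scene.red.bit_depth <= 8 else np.uint16
    for band, path in zip((scene.red, scene.green, scene.blue), paths):
        path.parent.mkdir(parents=True, exist_ok=True)
        _write_band_values(path, band.values.astype(dtype))
        _world_file_path(path).write_text(band.transform.to_world_file())


# ---------------------------------------------------------------------------
# fishnet GeoJSON I/O


def read_fishnet(path: str | Path) -> Fishnet:
    data = json.loads(Path(path).read_text())
    if data.get("type") != "FeatureCollection":
        raise ValueError("fishnet must be a GeoJSON FeatureCollection")
    polys = []
    for feat in data["features"]:
        geom = feat["geometry"]
        if geom["type"] != "Polygon":
            raise ValueError(f"unsupported geometry type {geom['type']}")
        props = dict(feat.get("properties") or {})
        plot_id = str(props.pop("plot_id"))
        genotype = str(props.pop("genotype", ""))
        rep = int(props.pop("rep", 0))
        row = props.pop("row", None)
        ring = [tuple(pt) for pt in geom["coordinates"][0]]
        polys.append(
            PlotPolygon(plot_id, genotype, rep, ring,
                        row=None if row is None else int(row), extra=props)
        )
    return Fishnet(polys)


def write_fishnet(fishnet: Fishnet, path: str | Path) -> None:
    features = []
    for p in fishnet:
        props = {"plot_id": p.plot_id, "genotype": p.genotype, "rep": p.rep}
        if p.row is not None:
            props["row"] = p.row
        props.update(p.extra)
        ring = [list(pt) for pt in p.ring]
        if ring[0] != ring[-1]:
            ring.append(list(ring[0]))
        features.append(
            {
                "type": "Feature",
                "properties": props,
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
    out = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(out))


# ---------------------------------------------------------------------------
# zonal statistics


def _interior_pixel_indices(
    poly: PlotPolygon, transform: Affine, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Rows/cols of pixels whose centers fall inside (or on) the polygon."""
    minx, miny, maxx, maxy = poly.geometry.bounds
    corners_px = np.array(
        [
            transform.world_to_pixel(x, y)
            for x, y in ((minx, miny), (minx, maxy), (maxx, miny), (maxx, maxy))
        ]
    )
    nrows, ncols = shape
    c0 = max(0, int(np.floor(corners_px[:, 0].min())) - 1)
    c1 = min(ncols - 1, int(np.ceil(corners_px[:, 0].max())) + 1)
    r0 = max(0, int(np.floor(corners_px[:, 1].min())) - 1)
    r1 = min(nrows - 1, int(np.ceil(corners_px[:, 1].max())) + 1)
    if c1 < c0 or r1 < r0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    cols, rows = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
    xs, ys = transform.pixel_to_world(cols.ravel(), rows.ravel())
    inside = shapely.intersects_xy(poly.geometry, xs, ys)  # boundary inclusive
    return rows.ravel()[inside], cols.ravel()[inside]


def zonal_mean_dn(
    scene: SceneRaster, fishnet: Fishnet
) -> tuple[list[ZonalResult], list[ZonalError]]:
    """Arithmetic mean DN per band over pixels whose centers fall in each polygon.

    Returns results for every polygon that covers at least one pixel center
    and an error record for every polygon that covers none.
    """
    results: list[ZonalResult] = []
    errors: list[ZonalError] = []
    for poly in fishnet:
        rr, cc = _interior_pixel_indices(poly, scene.transform, scene.shape)
        if rr.size == 0:
            errors.append(ZonalError(poly.plot_id, "no pixel centers inside polygon"))
            continue
        results.append(
            ZonalResult(
                plot_id=poly.plot_id,
                mean_dn_red=float(scene.red.values[rr, cc].mean()),
                mean_dn_green=float(scene.green.values[rr, cc].mean()),
                mean_dn_blue=float(scene.blue.values[rr, cc].mean()),
                pixel_count=int(rr.size),
            )
        )
    return results, errors


def zonal_results_to_frame(results: Iterable[ZonalResult]):
    """Tabulate zonal results with the canonical CSV header."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "plot_id": r.plot_id,
                "mean_dn_red": r.mean_dn_red,
                "mean_dn_green": r.mean_dn_green,
                "mean_dn_blue": r.mean_dn_blue,
                "pixel_count": r.pixel_count,
            }
            for r in results
        ]
    )


def average_rows_to_plot(
    row_values: Sequence[Sequence[float] | None],
) -> tuple[float, float, float]:
    """Componentwise mean of two per-row reflectance triples."""
    if len(row_values) != 2:
        raise ValueError("expected exactly two row triples")
    for i, triple in enumerate(row_values):
        if triple is None:
            raise ValueError(f"row {i + 1} reflectance is missing")
        if len(triple) != 3:
            raise ValueError(f"row {i + 1}: expected a 3-component triple")
    a, b = (np.asarray(t, dtype=float) for t in row_values)
    mean = (a + b) / 2.0
    return (float(mean[0]), float(mean[1]), float(mean[2]))
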