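"""Geospatial I/O: point clouds (LAS / XYZ text), GeoTIFF rasters,
GeoJSON polygons, and vector→raster conversion.

Only the formats the pipeline actually touches are supported, and only
north-up affine rasters.  The LAS codec is deliberately small: LAS
1.2–1.4 headers, point record formats 0–3, the classification byte and
optional 16-bit RGB — the fields the ground filter and vegetation
rasterizer consume.  Compressed LAZ is not supported.

GeoTIFF georeferencing uses the ModelPixelScale + ModelTiepoint tag
pair and the GDAL_NODATA ASCII tag; RGB rasters with a validity mask
are stored as RGBA (alpha 0 = nodata).
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
import tifffile
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .grids import GeoRaster, GridSpec
from .pointcloud import PointCloud

__all__ = [
    "PolygonSet",
    "read_point_cloud",
    "write_point_cloud",
    "read_raster",
    "write_raster",
    "read_polygons",
    "write_polygons",
    "rasterize_polygons",
]

MASK_NODATA = 255  # byte masks keep {0,1} payload distinct from nodata


# --------------------------------------------------------------------------
# polygons
# --------------------------------------------------------------------------


@dataclass
class PolygonSet:
    """A labelled collection of map-coordinate polygons (shapely)."""

    polygons: list[BaseGeometry]
    label: str = ""
    properties: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, poly in enumerate(self.polygons):
            if poly.is_empty or poly.area == 0:
                raise ValueError(f"polygon {i} is degenerate (zero area)")
        if self.properties and len(self.properties) != len(self.polygons):
            raise ValueError("properties must match polygons 1:1")

    def __len__(self) -> int:
        return len(self.polygons)


def read_polygons(path: str | Path, label: str = "") -> PolygonSet:
    """Read polygons from a GeoJSON FeatureCollection (or bare geometry)."""
    with open(path) as fh:
        doc = json.load(fh)
    polygons: list[BaseGeometry] = []
    properties: list[dict] = []
    if doc.get("type") == "FeatureCollection":
        for feat in doc["features"]:
            geom = shape(feat["geometry"])
            polygons.append(geom)
            properties.append(feat.get("properties") or {})
    else:
        polygons.append(shape(doc))
        properties.append({})
    return PolygonSet(polygons, label=label, properties=properties)


def write_polygons(polys: PolygonSet, path: str | Path) -> None:
    features = []
    for i, poly in enumerate(polys.polygons):
        props = dict(polys.properties[i]) if polys.properties else {}
        if polys.label and "label" not in props:
            props["label"] = polys.label
        features.append(
            {"type": "Feature", "geometry": mapping(poly), "properties": props}
        )
    doc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(doc))


def rasterize_polygons(polys: PolygonSet, grid: GridSpec) -> GeoRaster:
    """Burn polygons onto ``grid``: pixel = 1 iff its center is inside
    any polygon.

    This is the rule used to turn the hand-digitized affection polygons
    into a truth mask on the orthoimage grid.  An empty polygon set
    yields an all-zero mask.
    """
    out = np.zeros(grid.shape, dtype=np.uint8)
    if not polys.polygons:
        return GeoRaster(grid, out, nodata=MASK_NODATA)
    xs, ys = grid.center_coords()
    for poly in polys.polygons:
        xmin, ymin, xmax, ymax = poly.bounds
        c0 = int(np.searchsorted(xs, xmin, side="left"))
        c1 = int(np.searchsorted(xs, xmax, side="right"))
        # ys decreases with row index
        r0 = int(np.searchsorted(-ys, -ymax, side="left"))
        r1 = int(np.searchsorted(-ys, -ymin, side="right"))
        if c0 >= c1 or r0 >= r1:
            continue
        gx, gy = np.meshgrid(xs[c0:c1], ys[r0:r1])
        inside = shapely.contains_xy(poly, gx.ravel(), gy.ravel()).reshape(gx.shape)
        out[r0:r1, c0:c1] |= inside.astype(np.uint8)
    return GeoRaster(grid, out, nodata=MASK_NODATA)


# --------------------------------------------------------------------------
# point clouds
# --------------------------------------------------------------------------

_LAS_SIGNATURE = b"LASF"


def read_point_cloud(path: str | Path, format_hint: str | None = None) -> PointCloud:
    """Read a point cloud from LAS or plain XYZ(+RGB) text.

    ``format_hint`` may be ``"las"`` or ``"xyz"``; by default the format
    is sniffed from the file suffix and magic bytes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format_hint
    if fmt is None:
        if path.suffix.lower() in {".las", ".laz"}:
            fmt = "las"
        else:
            with open(path, "rb") as fh:
                fmt = "las" if fh.read(4) == _LAS_SIGNATURE else "xyz"
    if fmt == "las":
        return _read_las(path)
    if fmt == "xyz":
        return _read_xyz(path)
    raise ValueError(f"unknown point-cloud format {fmt!r}")


def write_point_cloud(
    cloud: PointCloud, path: str | Path, format_hint: str | None = None
) -> None:
    if len(cloud) == 0:
        raise ValueError("refusing to write an empty point cloud")
    path = Path(path)
    fmt = format_hint or ("las" if path.suffix.lower() == ".las" else "xyz")
    if fmt == "las":
        _write_las(cloud, path)
    elif fmt == "xyz":
        _write_xyz(cloud, path)
    else:
        raise ValueError(f"unknown point-cloud format {fmt!r}")


def _read_xyz(path: Path) -> PointCloud:
    """Whitespace- or comma-separated ``x y z [r g b] [class]`` text;
    '#' comments ignored.  A 4th column is a class code, 6 columns are
    RGB, 7 columns are RGB + class."""
    rows: list[list[float]] = []
    width: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            parts = body.replace(",", " ").split()
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed record {body!r}") from exc
            if len(vals) not in (3, 4, 6, 7):
                raise ValueError(
                    f"{path}:{lineno}: expected 3, 4, 6 or 7 columns, got {len(vals)}"
                )
            if width is None:
                width = len(vals)
            elif len(vals) != width:
                raise ValueError(f"{path}:{lineno}: inconsistent column count")
            rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: no data records")
    arr = np.asarray(rows, dtype=np.float64)
    rgb = cls = None
    if width in (6, 7):
        rgb = arr[:, 3:6].astype(np.uint8)
    if width == 4:
        cls = arr[:, 3].astype(np.uint8)
    elif width == 7:
        cls = arr[:, 6].astype(np.uint8)
    return PointCloud(arr[:, :3], rgb=rgb, classification=cls)


def _write_xyz(cloud: PointCloud, path: Path) -> None:
    cols = [cloud.xyz]
    fmt = ["%.6f", "%.6f", "%.6f"]
    if cloud.rgb is not None:
        cols.append(cloud.rgb.astype(np.float64))
        fmt += ["%d", "%d", "%d"]
    if cloud.classification is not None:
        cols.append(cloud.classification[:, None].astype(np.float64))
        fmt.append("%d")
    np.savetxt(path, np.hstack(cols), fmt=" ".join(fmt), comments="")


# LAS point record dtypes, formats 0-3 (LAS 1.2).
_LAS_COMMON = [
    ("X", "<i4"),
    ("Y", "<i4"),
    ("Z", "<i4"),
    ("intensity", "<u2"),
    ("flags", "u1"),
    ("classification", "u1"),
    ("scan_angle", "i1"),
    ("user_data", "u1"),
    ("point_source", "<u2"),
]
_GPS = [("gps_time", "<f8")]
_RGB = [("red", "<u2"), ("green", "<u2"), ("blue", "<u2")]
_LAS_DTYPES = {
    0: np.dtype(_LAS_COMMON),
    1: np.dtype(_LAS_COMMON + _GPS),
    2: np.dtype(_LAS_COMMON + _RGB),
    3: np.dtype(_LAS_COMMON + _GPS + _RGB),
}


def _read_las(path: Path) -> PointCloud:
    raw = path.read_bytes()
    if raw[:4] != _LAS_SIGNATURE:
        raise ValueError(f"{path}: not a LAS file")
    ver_major, ver_minor = raw[24], raw[25]
    if ver_major != 1:
        raise ValueError(f"{path}: unsupported LAS version {ver_major}.{ver_minor}")
    offset_to_data = struct.unpack_from("<I", raw, 96)[0]
    point_format = raw[104] & 0x3F
    record_len = struct.unpack_from("<H", raw, 105)[0]
    n_points = struct.unpack_from("<I", raw, 107)[0]
    if n_points == 0 and ver_minor >= 4:
        n_points = struct.unpack_from("<Q", raw, 247)[0]
    sx, sy, sz, ox, oy, oz = struct.unpack_from("<6d", raw, 131)
    if point_format not in _LAS_DTYPES:
        raise ValueError(
            f"{path}: point record format {point_format} unsupported (0-3 only)"
        )
    dtype = _LAS_DTYPES[point_format]
    if record_len < dtype.itemsize:
        raise ValueError(f"{path}: point record length {record_len} too small")
    buf = raw[offset_to_data : offset_to_data + n_points * record_len]
    if len(buf) < n_points * record_len:
        raise ValueError(f"{path}: truncated point data")
    if record_len == dtype.itemsize:
        rec = np.frombuffer(buf, dtype=dtype, count=n_points)
    else:  # extra bytes per record: view through a padded dtype
        padded = np.dtype({
            "names": list(dtype.names),
            "formats": [dtype.fields[n][0] for n in dtype.names],
            "offsets": [dtype.fields[n][1] for n in dtype.names],
            "itemsize": record_len,
        })
        rec = np.frombuffer(buf, dtype=padded, count=n_points)
    xyz = np.column_stack(
        [
            rec["X"] * sx + ox,
            rec["Y"] * sy + oy,
            rec["Z"] * sz + oz,
        ]
    )
    cls = (rec["classification"] & 0x1F).astype(np.uint8)
    rgb = None
    if "red" in dtype.names:
        rgb = np.column_stack(
            [rec["red"] >> 8, rec["green"] >> 8, rec["blue"] >> 8]
        ).astype(np.uint8)
    return PointCloud(xyz, rgb=rgb, classification=cls)


def _write_las(cloud: PointCloud, path: Path) -> None:
    """Write LAS 1.2, point format 0 (or 2 when the cloud carries RGB)."""
    point_format = 2 if cloud.rgb is not None else 0
    dtype = _LAS_DTYPES[point_format]
    n = len(cloud)
    scale = 0.001
    offs = cloud.xyz.min(axis=0)
    rec = np.zeros(n, dtype=dtype)
    quant = np.round((cloud.xyz - offs) / scale).astype(np.int64)
    if np.abs(quant).max() > np.iinfo(np.int32).max:
        raise ValueError("coordinate range too large for LAS int32 storage")
    rec["X"], rec["Y"], rec["Z"] = quant[:, 0], quant[:, 1], quant[:, 2]
    rec["flags"] = 0x11  # single return, first of one
    if cloud.classification is not None:
        rec["classification"] = cloud.classification
    if cloud.rgb is not None:
        rgb16 = cloud.rgb.astype(np.uint16) * 257  # 8-bit -> full-range 16-bit
        rec["red"], rec["green"], rec["blue"] = rgb16[:, 0], rgb16[:, 1], rgb16[:, 2]

    header = bytearray(227)
    header[0:4] = _LAS_SIGNATURE
    header[24] = 1
    header[25] = 2
    header[26:58] = b"vinepest".ljust(32, b"\x00")
    header[58:90] = b"vinepest las writer".ljust(32, b"\x00")
    struct.pack_into("<H", header, 94, 227)  # header size
    struct.pack_into("<I", header, 96, 227)  # offset to point data
    struct.pack_into("<I", header, 100, 0)  # number of VLRs
    header[104] = point_format
    struct.pack_into("<H", header, 105, dtype.itemsize)
    struct.pack_into("<I", header, 107, n)
    struct.pack_into("<I", header, 111, n)  # points by return[0]
    struct.pack_into("<6d", header, 131, scale, scale, scale, *offs)
    mx, mn = cloud.xyz.max(axis=0), cloud.xyz.min(axis=0)
    struct.pack_into("<6d", header, 179, mx[0], mn[0], mx[1], mn[1], mx[2], mn[2])
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(rec.tobytes())


# --------------------------------------------------------------------------
# rasters
# --------------------------------------------------------------------------

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113
_TAG_IMAGE_DESCRIPTION = 270


def write_raster(raster: GeoRaster, path: str | Path) -> None:
    """Write a :class:`GeoRaster` as a georeferenced (north-up) GeoTIFF."""
    grid = raster.grid
    data = raster.data
    if raster.is_rgb and raster.valid is not None:
        alpha = np.where(raster.valid, 255, 0).astype(np.uint8)
        data = np.dstack([data, alpha])
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (grid.pixel_size, grid.pixel_size, 0.0)),
        (
            _TAG_MODEL_TIEPOINT,
            "d",
            6,
            (0.0, 0.0, 0.0, grid.origin_x, grid.origin_y, 0.0),
        ),
    ]
    if raster.nodata is not None:
        extratags.append((_TAG_GDAL_NODATA, "s", 0, repr(raster.nodata)))
    photometric = "rgb" if data.ndim == 3 else "minisblack"
    tifffile.imwrite(
        str(path),
        data,
        photometric=photometric,
        description=json.dumps({"crs_id": grid.crs_id}),
        extratags=extratags,
    )


def read_raster(path: str | Path) -> GeoRaster:
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        data = page.asarray()
        tags = page.tags
        if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
            raise ValueError(f"{path}: missing georeferencing tags")
        scale = tags[_TAG_MODEL_PIXEL_SCALE].value
        tie = tags[_TAG_MODEL_TIEPOINT].value
        if abs(scale[0] - scale[1]) > 1e-12:
            raise ValueError(f"{path}: non-square pixels unsupported")
        if tie[0] != 0 or tie[1] != 0:
            raise ValueError(f"{path}: tiepoint not at raster origin")
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            txt = tags[_TAG_GDAL_NODATA].value
            nodata = float(txt) if "." in txt or "n" in txt.lower() else int(txt)
        crs_id = "local-metric"
        if _TAG_IMAGE_DESCRIPTION in tags:
            try:
                crs_id = json.loads(tags[_TAG_IMAGE_DESCRIPTION].value).get(
                    "crs_id", crs_id
                )
            except (json.JSONDecodeError, AttributeError):
                pass
    valid = None
    if data.ndim == 3 and data.shape[2] == 4:  # RGBA -> RGB + validity
        valid = data[:, :, 3] > 0
        data = data[:, :, :3]
    grid = GridSpec(
        origin_x=float(tie[3]),
        origin_y=float(tie[4]),
        pixel_size=float(scale[0]),
        n_rows=data.shape[0],
        n_cols=data.shape[1],
        crs_id=crs_id,
    )
    return GeoRaster(grid, data, nodata=nodata, valid=valid)
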