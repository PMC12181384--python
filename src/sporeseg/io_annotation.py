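"""Image/mask I/O and polygon-annotation handling.

Images are 2D grayscale rasters (TIFF or PNG, 8/16-bit).  Ground-truth
annotations are labelled closed polygons in pixel coordinates, stored as
JSON; they are rasterized to binary masks with a pixel-centre
point-in-polygon rule (boundary inclusive).

Coordinate convention: ``x`` is the column index and ``y`` the row
index, both 0-based; the centre of pixel ``(row, col)`` sits at the
integer coordinate ``(x=col, y=row)``.

Annotation JSON schema::

    [{"label": "spore", "points": [[x0, y0], [x1, y1], ...]}, ...]

A small import shim also accepts ``"vertices"`` instead of ``"points"``
and per-object ``{"x": [...], "y": [...]}`` coordinate lists, as written
by some web annotation tools.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import shapely

__all__ = [
    "GrayImage",
    "BinaryMask",
    "PolygonAnnotation",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "polygons_to_mask",
    "read_annotations",
    "write_annotations",
]


@dataclass
class GrayImage:
    """A 2D grayscale raster with an optional physical pixel size.

    Parameters
    ----------
    pixels
        2D array of intensities (any numeric dtype).
    px_per_um
        Optional resolution in pixels per micrometre (e.g. 16.5 for the
        stitched frames this package targets).
    """

    pixels: np.ndarray
    px_per_um: float | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2D raster, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must have at least one pixel")
        if self.px_per_um is not None and self.px_per_um <= 0:
            raise ValueError("px_per_um must be positive")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryMask:
    """A 2D boolean raster; ``True`` marks spore/cell foreground."""

    pixels: np.ndarray

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2D mask, got shape {self.pixels.shape}")
        if self.pixels.dtype != bool:
            self.pixels = self.pixels.astype(bool)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def __eq__(self, other) -> bool:
        if not isinstance(other, BinaryMask):
            return NotImplemented
        return self.shape == other.shape and bool(np.array_equal(self.pixels, other.pixels))


@dataclass
class PolygonAnnotation:
    """A labelled closed polygon outlining one spore or cell.

    Vertices are ordered ``(x, y)`` pixel coordinates; the polygon is
    implicitly closed (the last vertex connects back to the first).
    """

    label: str
    vertices: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array of (x, y) points")
        if len(self.vertices) < 3:
            raise ValueError("a polygon needs at least 3 vertices")
        if shapely.Polygon(self.vertices).area == 0:
            raise ValueError("degenerate polygon (zero area)")


def read_image(path: str | Path, px_per_um: float | None = None) -> GrayImage:
    """Read a TIFF/PNG image as grayscale.

    Multi-channel inputs are reduced to one channel by dropping any
    alpha channel and averaging the colour channels (rounded back to
    the source dtype), so channel-identical RGB reduces exactly to its
    single channel.
    """
    arr = iio.imread(path)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        dtype = arr.dtype
        arr = arr.mean(axis=2)
        if np.issubdtype(dtype, np.integer):
            arr = np.rint(arr).astype(dtype)
    if arr.ndim != 2:
        raise ValueError(f"cannot interpret {path} as a 2D grayscale image")
    if arr.size == 0:
        raise ValueError(f"zero-sized image: {path}")
    return GrayImage(arr, px_per_um=px_per_um)


def write_image(image: GrayImage, path: str | Path) -> None:
    """Write an 8/16-bit grayscale image as PNG or TIFF (by extension)."""
    iio.imwrite(path, np.asarray(image.pixels))


def read_mask(path: str | Path) -> BinaryMask:
    """Read a binary mask PNG (any value > 0 is foreground)."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return BinaryMask(arr > 0)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as an 8-bit PNG with values 0/255 (lossless round trip)."""
    iio.imwrite(path, mask.pixels.astype(np.uint8) * 255)


def polygons_to_mask(
    annotations: list[PolygonAnnotation], shape: tuple[int, int]
) -> BinaryMask:
    """Rasterize labelled polygons into a single-class binary mask.

    Each polygon is filled using pixel-centre sampling: pixel
    ``(row, col)`` is foreground iff the point ``(x=col, y=row)`` lies
    inside or on the boundary of the polygon.  Overlapping polygons are
    unioned and labels are collapsed to one foreground class.
    """
    h, w = shape
    out = np.zeros((h, w), dtype=bool)
    for ann in annotations:
        verts = ann.vertices
        if (
            verts[:, 0].min() < 0
            or verts[:, 1].min() < 0
            or verts[:, 0].max() > w - 1
            or verts[:, 1].max() > h - 1
        ):
            raise ValueError(
                f"polygon vertices outside image bounds {shape}: "
                f"x range {verts[:, 0].min()}..{verts[:, 0].max()}, "
                f"y range {verts[:, 1].min()}..{verts[:, 1].max()}"
            )
        poly = shapely.Polygon(verts)
        # restrict the membership test to the polygon's bounding box
        x0 = int(np.floor(verts[:, 0].min()))
        x1 = int(np.ceil(verts[:, 0].max()))
        y0 = int(np.floor(verts[:, 1].min()))
        y1 = int(np.ceil(verts[:, 1].max()))
        xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
        inside = shapely.intersects_xy(poly, xs.ravel(), ys.ravel())
        out[y0 : y1 + 1, x0 : x1 + 1] |= inside.reshape(ys.shape)
    return BinaryMask(out)


# -- annotation JSON --------------------------------------------------

def _object_to_annotation(obj: dict) -> PolygonAnnotation:
    label = str(obj.get("label", "object"))
    if "points" in obj:
        pts = obj["points"]
    elif "vertices" in obj:
        pts = obj["vertices"]
    elif "x" in obj and "y" in obj:
        pts = list(zip(obj["x"], obj["y"]))
    else:
        raise ValueError(f"unrecognized annotation object keys: {sorted(obj)}")
    return PolygonAnnotation(label=label, vertices=np.asarray(pts, dtype=float))


def read_annotations(path: str | Path) -> list[PolygonAnnotation]:
    """Read polygon annotations from JSON (see module docstring schema)."""
    with open(path) as fh:
        data = json.load(fh)
    if isinstance(data, dict):  # tolerate a top-level wrapper
        data = data.get("annotations", data.get("objects", []))
    return [_object_to_annotation(obj) for obj in data]


def write_annotations(annotations: list[PolygonAnnotation], path: str | Path) -> None:
    payload = [
        {"label": a.label, "points": [[float(x), float(y)] for x, y in a.vertices]}
        for a in annotations
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh)
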