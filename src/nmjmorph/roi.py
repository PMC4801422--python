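"""Polygon regions of interest and their raster masks.

A single polygon per NMJ restricts every analysis stage to the type-1b
terminal.  Polygons live in raster coordinates: 0-based, x rightward,
y downward.  The on-disk format is one ``x<TAB>y`` vertex per line.

Rasterization rule: a pixel belongs to the mask iff its *center* lies
inside or on the closed polygon, by the even-odd (crossing-number)
rule.  Out-of-bounds vertices are clipped to the image frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "RoiPolygon",
    "RoiMask",
    "rasterize_polygon",
    "apply_roi",
    "polygon_area",
    "read_roi_file",
    "write_roi_file",
    "roi_file_path",
]


@dataclass(frozen=True)
class RoiPolygon:
    nmj_id: str
    vertices: tuple  # ordered ((x, y), ...) pixel coordinates

    def __post_init__(self):
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        object.__setattr__(self, "vertices", verts)
        if len(verts) < 3:
            raise ValueError("polygon needs at least 3 vertices")

    def shoelace_px2(self) -> float:
        v = np.asarray(self.vertices)
        x, y = v[:, 0], v[:, 1]
        return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


@dataclass
class RoiMask:
    """Binary mask with the same x/y shape as the flat projection."""

    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2D")
        if not self.mask.any():
            raise ValueError("ROI mask has no true pixels")


def _points_on_boundary(px, py, verts, tol=1e-9):
    """Boolean array: does point (px, py) lie on any polygon edge?"""
    on = np.zeros(px.shape, dtype=bool)
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        cross = (px - x1) * (y2 - y1) - (py - y1) * (x2 - x1)
        seg2 = (x2 - x1) ** 2 + (y2 - y1) ** 2
        if seg2 == 0:
            on |= (np.abs(px - x1) < tol) & (np.abs(py - y1) < tol)
            continue
        within = (
            (px >= min(x1, x2) - tol)
            & (px <= max(x1, x2) + tol)
            & (py >= min(y1, y2) - tol)
            & (py <= max(y1, y2) + tol)
        )
        on |= within & (np.abs(cross) < tol * np.sqrt(seg2))
    return on


def _points_inside_evenodd(px, py, verts):
    """Even-odd crossing test, vectorized over a point grid."""
    inside = np.zeros(px.shape, dtype=bool)
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        crosses = (y1 > py) != (y2 > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (px < np.where(crosses, xint, 0.0))
    return inside


def rasterize_polygon(polygon: RoiPolygon, shape: tuple[int, int]) -> RoiMask:
    """Rasterize to a boolean mask of the given (height, width).

    Vertices are clipped to the frame; a zero-area polygon is an error.
    """
    h, w = shape
    verts = [
        (min(max(x, 0.0), w - 1.0), min(max(y, 0.0), h - 1.0)) for x, y in polygon.vertices
    ]
    clipped = RoiPolygon(polygon.nmj_id, verts)
    if clipped.shoelace_px2() <= 0:
        raise ValueError(f"degenerate (zero-area) polygon for {polygon.nmj_id}")
    v = np.asarray(verts)
    x0 = int(np.floor(v[:, 0].min()))
    x1 = int(np.ceil(v[:, 0].max()))
    y0 = int(np.floor(v[:, 1].min()))
    y1 = int(np.ceil(v[:, 1].max()))
    ys, xs = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    keep = _points_inside_evenodd(xs.astype(float), ys.astype(float), verts)
    keep |= _points_on_boundary(xs.astype(float), ys.astype(float), verts)
    mask = np.zeros((h, w), dtype=bool)
    mask[y0 : y1 + 1, x0 : x1 + 1] = keep
    return RoiMask(mask)


def apply_roi(image, roi: RoiMask):
    """Zero every pixel outside the ROI; 3D input is masked plane-wise."""
    image = np.asarray(image)
    if image.ndim == 2:
        if image.shape != roi.mask.shape:
            raise ValueError(f"shape mismatch: image {image.shape} vs roi {roi.mask.shape}")
        return np.where(roi.mask, image, 0)
    if image.ndim == 3:
        if image.shape[1:] != roi.mask.shape:
            raise ValueError(f"shape mismatch: stack {image.shape} vs roi {roi.mask.shape}")
        return np.where(roi.mask[None, :, :], image, 0)
    raise ValueError("expected 2D or 3D input")


def polygon_area(polygon: RoiPolygon, px_per_um: float) -> float:
    """Shoelace area converted to um^2 (helper for muscle outlines)."""
    area_px2 = polygon.shoelace_px2()
    if area_px2 <= 0:
        raise ValueError("degenerate polygon")
    return area_px2 / px_per_um**2


def roi_file_path(directory, nmj_id: str) -> Path:
    return Path(directory) / f"{nmj_id}_roi.txt"


def write_roi_file(path, polygon: RoiPolygon) -> None:
    lines = [f"{x:g}\t{y:g}" for x, y in polygon.vertices]
    Path(path).write_text("\n".join(lines) + "\n")


def read_roi_file(path, nmj_id: str | None = None) -> RoiPolygon:
    path = Path(path)
    verts = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        x, y = line.split("\t") if "\t" in line else line.split()
        verts.append((float(x), float(y)))
    if nmj_id is None:
        nmj_id = path.stem.removesuffix("_roi")
    return RoiPolygon(nmj_id, verts)
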