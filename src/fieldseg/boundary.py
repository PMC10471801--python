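"""From class mask to ordered per-region boundary coordinates.

Pipeline: select the classes of interest and binarize, clean the binary
image with a morphological opening (erosion then dilation, removing
speckle), label the 8-connected foreground regions while discarding the
smallest ones as likely misclassifications, then walk each region's
contour with Moore-neighbor tracing (Jacob's stopping criterion).

Coordinates follow the image Cartesian convention used throughout the
package: x = column, y = row, both 0-based at the top-left pixel center,
y increasing downward.  Path points are pixel centers, consecutive points
are 8-adjacent, and the outer trace runs clockwise on screen starting at
the region's uppermost-then-leftmost pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["RegionInfo", "RegionMap", "BoundaryPath", "binarize_and_clean",
           "label_regions", "trace_boundary", "trace_region_boundaries",
           "border_pixels"]

_EIGHT = np.ones((3, 3), dtype=bool)

# Moore neighborhood ring in (dx, dy), ordered so that scanning forward
# from the backtrack yields a clockwise-on-screen outer traversal.
_RING = ((-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1), (0, 1), (-1, 1))
_RING_INDEX = {d: i for i, d in enumerate(_RING)}


@dataclass(frozen=True)
class RegionInfo:
    region_id: int
    area: int
    bbox: tuple[int, int, int, int]     # (row0, col0, row1, col1), half-open


@dataclass(frozen=True)
class RegionMap:
    """Labelled regions: 0 = background, 1..R = surviving regions."""

    labels: np.ndarray
    regions: tuple[RegionInfo, ...]

    @property
    def num_regions(self) -> int:
        return len(self.regions)


@dataclass(frozen=True)
class BoundaryPath:
    region_id: int
    points: tuple[tuple[int, int], ...]    # (x, y) pixel centers
    closed: bool

    def as_array(self) -> np.ndarray:
        return np.asarray(self.points, dtype=np.float64)


def binarize_and_clean(mask: np.ndarray, target_classes,
                       kernel_size: int = 3,
                       invert: bool = False) -> np.ndarray:
    """Class selection, then morphological opening, then optional inversion.

    ``kernel_size`` is the side of the square structuring element; 1 makes
    the opening the identity.
    """
    targets = tuple(target_classes)
    if not targets:
        raise ValueError("target_classes must be non-empty")
    if kernel_size < 1 or kernel_size % 2 == 0:
        raise ValueError("kernel_size must be odd and >= 1")
    fg = np.isin(np.asarray(mask), targets)
    if kernel_size > 1:
        se = np.ones((kernel_size, kernel_size), dtype=bool)
        fg = ndimage.binary_dilation(ndimage.binary_erosion(fg, se), se)
    return (~fg if invert else fg).astype(np.uint8)


def label_regions(binary: np.ndarray, min_area: int | None = None) -> RegionMap:
    """8-connected components of the foreground, areas below ``min_area``
    dropped, labels renumbered 1..R by first pixel in row-major order.

    ``min_area`` defaults to 0.1% of the image pixels.
    """
    binary = np.asarray(binary).astype(bool)
    if min_area is None:
        min_area = max(1, binary.size // 1000)
    raw, n = ndimage.label(binary, structure=_EIGHT)
    labels = np.zeros_like(raw)
    regions = []
    if n:
        areas = np.bincount(raw.ravel(), minlength=n + 1)
        flat = raw.ravel()
        first = np.full(n + 1, flat.size, dtype=np.int64)
        idx = np.flatnonzero(flat)
        # reversed so earlier indices overwrite later ones
        first[flat[idx[::-1]]] = idx[::-1]
        survivors = [lab for lab in range(1, n + 1) if areas[lab] >= min_area]
        survivors.sort(key=lambda lab: first[lab])
        objects = ndimage.find_objects(raw)
        for new_id, lab in enumerate(survivors, start=1):
            labels[raw == lab] = new_id
            sl = objects[lab - 1]
            regions.append(RegionInfo(
                region_id=new_id, area=int(areas[lab]),
                bbox=(sl[0].start, sl[1].start, sl[0].stop, sl[1].stop)))
    return RegionMap(labels=labels, regions=tuple(regions))


def border_pixels(region: np.ndarray) -> set[tuple[int, int]]:
    """Brute-force border set: region pixels with a 4-neighbor outside the
    region or touching the image frame.  Returned as (x, y) tuples."""
    region = np.asarray(region).astype(bool)
    padded = np.pad(region, 1, constant_values=False)
    interior = (padded[:-2, 1:-1] & padded[2:, 1:-1] &
                padded[1:-1, :-2] & padded[1:-1, 2:])
    border = region & ~interior
    return {(int(c), int(r)) for r, c in np.argwhere(border)}


def _moore_trace(region: np.ndarray, start: tuple[int, int],
                 backtrack: tuple[int, int]) -> list[tuple[int, int]]:
    """Trace one closed contour; ``start``/``backtrack`` are (x, y)."""
    h, w = region.shape

    def fg(x: int, y: int) -> bool:
        return 0 <= x < w and 0 <= y < h and region[y, x]

    path = [start]
    p, b = start, backtrack
    limit = 4 * int(region.sum()) + 8
    for _ in range(limit):
        i = _RING_INDEX[(b[0] - p[0], b[1] - p[1])]
        nxt = None
        for k in range(1, 9):
            d = _RING[(i + k) % 8]
            q = (p[0] + d[0], p[1] + d[1])
            if fg(*q):
                prev_d = _RING[(i + k - 1) % 8]
                nxt = q
                new_b = (p[0] + prev_d[0], p[1] + prev_d[1])
                break
        if nxt is None:                       # isolated single pixel
            return path
        if nxt == start and new_b == backtrack:   # Jacob's criterion
            return path
        path.append(nxt)
        p, b = nxt, new_b
    return path     # safety cap; unreachable for well-formed regions


def trace_boundary(region_map: RegionMap, region_id: int) -> BoundaryPath:
    """Outer contour of one region, clockwise from its top-left pixel."""
    region = region_map.labels == region_id
    if not region.any():
        raise ValueError(f"unknown region_id {region_id}")
    rows, cols = np.nonzero(region)
    start = (int(cols[0]), int(rows[0]))      # uppermost, then leftmost
    backtrack = (start[0] - 1, start[1])      # entered from the west
    points = _moore_trace(region, start, backtrack)
    return BoundaryPath(region_id=region_id, points=tuple(points), closed=True)


def trace_region_boundaries(region_map: RegionMap,
                            region_id: int) -> list[BoundaryPath]:
    """Outer contour plus one contour per interior hole.

    Hole contours consist of region pixels bordering the hole (background
    4-connectivity), so the union of all returned point sets is exactly
    the region's border-pixel set.
    """
    paths = [trace_boundary(region_map, region_id)]
    region = region_map.labels == region_id
    holes = ndimage.binary_fill_holes(region) & ~region
    hole_labels, n_holes = ndimage.label(holes)   # 4-connected background
    for lab in range(1, n_holes + 1):
        rows, cols = np.nonzero(hole_labels == lab)
        hx, hy = int(cols[0]), int(rows[0])       # hole's top-left pixel
        start = (hx, hy - 1)                      # region pixel above it
        points = _moore_trace(region, start, (hx, hy))
        paths.append(BoundaryPath(region_id=region_id, points=tuple(points),
                                  closed=True))
    return paths
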