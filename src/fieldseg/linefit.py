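"""Boundary-line fitting: orientation split, robust least squares, errors.

Traced boundary points are partitioned into horizontal and vertical
candidate line sets (horizontal lines are fitted as y = f(x), vertical
ones as x = f(y) to keep slopes bounded), outliers are screened by
standardized residual |e_i| / S_e > 3 and the line is refitted, and fits
are scored against reference lines by angular error (degrees between the
directions) and vertical error (intercept gap at coordinate 0 normalized
by the image extent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as npoly

__all__ = ["OrientationRule", "PolynomialLine", "ResidualDiagnostics",
           "split_orientation", "fit_line_ls", "remove_outliers_and_refit",
           "angular_error", "vertical_error", "LineErrorReport"]

HORIZONTAL = "horizontal"
VERTICAL = "vertical"


@dataclass(frozen=True)
class OrientationRule:
    """Thresholds for grouping boundary points into line sets.

    ``delta_threshold`` is the largest perpendicular jump allowed between
    successive points of one line set (a 50 px band for 1024 px tiles);
    ``gap_threshold`` separates distinct parallel boundaries the same way.
    The effective split threshold is the smaller of the two; both scale
    linearly with image size via :meth:`scaled_for`.
    """

    delta_threshold: float = 50.0
    gap_threshold: float = 50.0
    min_points: int = 4
    end_trim: float = 3.0
    reference_size: int = 1024

    def __post_init__(self):
        if self.delta_threshold <= 0 or self.gap_threshold <= 0:
            raise ValueError("thresholds must be positive")

    def scaled_for(self, image_size: int) -> "OrientationRule":
        """Linearly rescale the perpendicular thresholds to another tile
        size.  ``end_trim`` is a raster-staircase margin and stays fixed."""
        f = image_size / self.reference_size
        return OrientationRule(self.delta_threshold * f,
                               self.gap_threshold * f,
                               self.min_points, self.end_trim, image_size)


@dataclass(frozen=True)
class PolynomialLine:
    """f(u) = theta_0 + theta_1 u + ... + theta_n u^n.

    For ``horizontal`` orientation u = x and f is y; for ``vertical`` the
    frame is swapped (u = y, f is x), keeping slopes below 1 in magnitude.
    """

    orientation: str
    order: int
    coefficients: tuple[float, ...]
    support: int

    def __post_init__(self):
        if self.orientation not in (HORIZONTAL, VERTICAL):
            raise ValueError("orientation must be horizontal or vertical")
        if len(self.coefficients) != self.order + 1:
            raise ValueError("need order + 1 coefficients")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients must be finite")

    def predict(self, u: np.ndarray) -> np.ndarray:
        return npoly.polyval(np.asarray(u, dtype=np.float64),
                             np.asarray(self.coefficients))

    @property
    def intercept(self) -> float:
        return self.coefficients[0]

    @property
    def slope(self) -> float:
        if self.order < 1:
            return 0.0
        return self.coefficients[1]


@dataclass(frozen=True)
class ResidualDiagnostics:
    residuals: np.ndarray            # over retained points
    residual_scale: float            # S_e = sqrt(S / (m - (order + 1)))
    standardized: np.ndarray         # Z_i = |e_i| / S_e
    sse: float                       # S = sum of squared residuals
    removed_indices: tuple[int, ...]  # indices into the original point array


@dataclass(frozen=True)
class LineErrorReport:
    angular_error: float             # degrees
    vertical_error: float            # dimensionless ratio
    image_height: int


_WINDOW = 3     # half-width, in path steps, of the direction window


def _orient_points(path_points: np.ndarray,
                   closed: bool) -> tuple[np.ndarray, np.ndarray]:
    """Split path points into horizontal/vertical candidate pools.

    Each point is classified by the displacement of the path across a
    short window around it (+-3 steps): mostly-x movement marks a point
    on a horizontal boundary, mostly-y movement a vertical one.  The
    window smooths over the single diagonal steps of a rasterized sloped
    edge; at corners the displacement is diagonal and the point joins
    both pools (membership is non-exclusive).
    """
    pts = np.asarray(path_points, dtype=np.float64)
    n = len(pts)
    w = min(_WINDOW, max(1, (n - 1) // 2))
    if closed:
        before = np.roll(pts, w, axis=0)
        after = np.roll(pts, -w, axis=0)
    else:
        idx = np.arange(n)
        before = pts[np.maximum(idx - w, 0)]
        after = pts[np.minimum(idx + w, n - 1)]
    dx = np.abs(after[:, 0] - before[:, 0])
    dy = np.abs(after[:, 1] - before[:, 1])
    h_pool = pts[dx >= dy]
    v_pool = pts[dy >= dx]
    return (np.unique(h_pool, axis=0) if len(h_pool) else np.empty((0, 2)),
            np.unique(v_pool, axis=0) if len(v_pool) else np.empty((0, 2)))


def _gap_cluster(values: np.ndarray, gap: float) -> list[np.ndarray]:
    """1-D clustering: sorted indices split where consecutive values jump
    by more than ``gap``."""
    order = np.argsort(values, kind="stable")
    sorted_vals = values[order]
    if len(values) == 0:
        return []
    breaks = np.flatnonzero(np.diff(sorted_vals) > gap)
    return [order[s] for s in np.split(np.arange(len(values)),
                                       breaks + 1)]


def split_orientation(path, rule: OrientationRule = OrientationRule()
                      ) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Partition a traced boundary into horizontal and vertical line sets.

    Accepts a :class:`~fieldseg.boundary.BoundaryPath` or an (m, 2) array
    of ordered (x, y) points.  Points where the path moves mostly in x
    join the horizontal pool, points where it moves mostly in y the
    vertical pool (corner points may join both).  Each pool is then
    clustered on the perpendicular coordinate: a jump larger than the
    rule's threshold starts a new set, and sets with fewer than
    ``min_points`` points are discarded.
    """
    closed = getattr(path, "closed", True)
    pts = path.as_array() if hasattr(path, "as_array") else \
        np.asarray(path, dtype=np.float64)
    if len(pts) < 4:
        raise ValueError("path must contain at least 4 points")
    h_pool, v_pool = _orient_points(pts, closed)
    gap = min(rule.gap_threshold, rule.delta_threshold)
    out: tuple[list[np.ndarray], list[np.ndarray]] = ([], [])
    for which, pool in ((0, h_pool), (1, v_pool)):
        perp = pool[:, 1] if which == 0 else pool[:, 0]
        for idx in _gap_cluster(perp, gap):
            cluster = pool[idx]
            if rule.end_trim > 0:
                # the ends of a segment abut the perpendicular edges;
                # trimming removes their corner-staircase points
                par = cluster[:, 0] if which == 0 else cluster[:, 1]
                keep = ((par >= par.min() + rule.end_trim) &
                        (par <= par.max() - rule.end_trim))
                if keep.sum() >= rule.min_points:
                    cluster = cluster[keep]
            if len(cluster) < rule.min_points:
                continue
            out[which].append(cluster)
    return out


def _design_values(points: np.ndarray, orientation: str
                   ) -> tuple[np.ndarray, np.ndarray]:
    pts = np.asarray(points, dtype=np.float64)
    if orientation == VERTICAL:
        return pts[:, 1], pts[:, 0]
    return pts[:, 0], pts[:, 1]


def fit_line_ls(points, order: int = 1, orientation: str = HORIZONTAL
                ) -> tuple[PolynomialLine, ResidualDiagnostics]:
    """Least-squares polynomial fit minimizing S = sum (f(u_i) - v_i)^2.

    Vertical-orientation point sets are fitted in the swapped frame.
    ``S_e = sqrt(S / (m - (order + 1)))`` is the usual residual standard
    error; standardized residuals are |e_i| / S_e.
    """
    u, v = _design_values(points, orientation)
    m = len(u)
    if m < order + 2:
        raise ValueError(f"need at least {order + 2} points, got {m}")
    if np.ptp(u) == 0:
        raise ValueError(
            "degenerate orientation: all abscissae identical; "
            f"fit this set with the "
            f"{VERTICAL if orientation == HORIZONTAL else HORIZONTAL} "
            "orientation instead")
    coeffs = npoly.polyfit(u, v, order)
    resid = v - npoly.polyval(u, coeffs)
    sse = float(resid @ resid)
    dof = m - (order + 1)
    scale = float(np.sqrt(sse / dof)) if dof > 0 else 0.0
    z = np.abs(resid) / scale if scale > 0 else np.zeros_like(resid)
    line = PolynomialLine(orientation=orientation, order=order,
                          coefficients=tuple(float(c) for c in coeffs),
                          support=m)
    return line, ResidualDiagnostics(residuals=resid, residual_scale=scale,
                                     standardized=z, sse=sse,
                                     removed_indices=())


def remove_outliers_and_refit(points, order: int = 1, z_max: float = 3.0,
                              orientation: str = HORIZONTAL,
                              max_iterations: int = 5
                              ) -> tuple[PolynomialLine, ResidualDiagnostics]:
    """Iterated standardized-residual screening around the least-squares
    fit: points with Z > ``z_max`` are removed and the line refitted until
    a fixed point or ``max_iterations``.  ``max_iterations=1`` gives a
    single screening pass."""
    if z_max <= 0:
        raise ValueError("z_max must be positive")
    pts = np.asarray(points, dtype=np.float64)
    if len(pts) < order + 3:
        raise ValueError(f"need at least {order + 3} points, got {len(pts)}")
    keep = np.arange(len(pts))
    removed: list[int] = []
    line = diag = None
    for _ in range(max_iterations):
        if len(keep) < order + 2:
            raise ValueError("over-pruned: outlier removal left fewer than "
                             f"{order + 2} points")
        line, diag = fit_line_ls(pts[keep], order, orientation)
        bad = diag.standardized > z_max
        if not bad.any():
            break
        removed.extend(int(i) for i in keep[bad])
        keep = keep[~bad]
    if len(keep) < order + 2:
        raise ValueError("over-pruned: outlier removal left fewer than "
                         f"{order + 2} points")
    return line, ResidualDiagnostics(residuals=diag.residuals,
                                     residual_scale=diag.residual_scale,
                                     standardized=diag.standardized,
                                     sse=diag.sse,
                                     removed_indices=tuple(sorted(removed)))


def _check_pair(line_true: PolynomialLine, line_fit: PolynomialLine) -> None:
    if line_true.order != 1 or line_fit.order != 1:
        raise ValueError("error metrics are defined for order-1 lines")
    if line_true.orientation != line_fit.orientation:
        raise ValueError("lines have mixed orientations; no common frame")


def angular_error(line_true, line_fit) -> float:
    """Angle in degrees between two order-1 lines of the same orientation,
    computed in their (possibly swapped) frame; result in [0, 90]."""
    _check_pair(line_true, line_fit)
    ang = abs(np.degrees(np.arctan(line_true.slope) -
                         np.arctan(line_fit.slope)))
    return float(min(ang, 180.0 - ang))


def vertical_error(line_true, line_fit, image_height: int,
                   image_width: int | None = None) -> float:
    """|f_true(0) - f_fit(0)| normalized by the image extent.

    For horizontal lines the extent is the image height; for
    vertical-orientation lines the swapped-frame analog divides by the
    image width (defaulting to the height if not given).
    """
    _check_pair(line_true, line_fit)
    if image_height <= 0 or (image_width is not None and image_width <= 0):
        raise ValueError("image extent must be positive")
    norm = image_height
    if line_true.orientation == VERTICAL and image_width is not None:
        norm = image_width
    return float(abs(line_true.intercept - line_fit.intercept) / norm)
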