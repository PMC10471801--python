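"""End-to-end orchestration: mask (or image + network) -> fitted lines.

The two stages are deliberately separable: the boundary-line algorithm
accepts a label mask directly, so it can run and be validated without any
trained network; given an RGB image and a checkpointed network it first
predicts the mask.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .boundary import binarize_and_clean, label_regions, trace_boundary
from .linefit import (OrientationRule, PolynomialLine, angular_error,
                      fit_line_ls, remove_outliers_and_refit,
                      split_orientation, vertical_error)
from .network import AttMobileDeeplab, predict_mask
from .synthetic import TrueLine

logger = logging.getLogger("fieldseg")

__all__ = ["PipelineConfig", "FittedLine", "LineEvaluation",
           "extract_field_lines", "evaluate_lines", "fitted_lines_to_json",
           "fitted_lines_from_json"]


@dataclass(frozen=True)
class PipelineConfig:
    """Parameters of the boundary-extraction pipeline."""

    target_classes: tuple[int, ...] = (1, 2)   # Crop and Soil
    kernel_size: int = 3
    min_area: int | None = None                # default: 0.1% of pixels
    rule: OrientationRule = field(default_factory=OrientationRule)
    scale_rule: bool = True                    # rescale thresholds to image
    order: int = 1
    z_max: float = 3.0
    max_iterations: int = 5
    invert: bool = False
    subpixel_correction: bool = True


@dataclass(frozen=True)
class FittedLine:
    region_id: int
    line: PolynomialLine
    support: int
    removed_outliers: tuple[int, ...]

    def to_dict(self) -> dict:
        return {"region_id": self.region_id,
                "orientation": self.line.orientation,
                "order": self.line.order,
                "coefficients": list(self.line.coefficients),
                "support": self.support,
                "removed_outliers": list(self.removed_outliers)}

    @classmethod
    def from_dict(cls, d: dict) -> "FittedLine":
        line = PolynomialLine(orientation=d["orientation"],
                              order=int(d["order"]),
                              coefficients=tuple(float(c)
                                                 for c in d["coefficients"]),
                              support=int(d["support"]))
        return cls(region_id=int(d["region_id"]), line=line,
                   support=line.support,
                   removed_outliers=tuple(int(i)
                                          for i in d["removed_outliers"]))


def extract_field_lines(image_or_mask: np.ndarray,
                        config: PipelineConfig = PipelineConfig(),
                        network: AttMobileDeeplab | None = None
                        ) -> list[FittedLine]:
    """Run the full boundary pipeline and return every fitted line.

    A 2-D input is taken as a label mask; a 3-D H x W x 3 input is first
    segmented with ``network``.  Regions that survive cleaning are traced,
    their boundary points split into horizontal/vertical line sets, each
    set screened for outliers (Z > z_max) and fitted by least squares.
    An input with no usable region yields an empty list, not an error.
    """
    arr = np.asarray(image_or_mask)
    if arr.ndim == 3:
        if network is None:
            raise ValueError("an RGB input requires a network checkpoint")
        mask = predict_mask(network, arr)
    elif arr.ndim == 2:
        mask = arr
    else:
        raise ValueError("input must be an H x W mask or H x W x 3 image")

    binary = binarize_and_clean(mask, config.target_classes,
                                config.kernel_size, config.invert)
    region_map = label_regions(binary, config.min_area)
    logger.info("pipeline: %d region(s) survive cleaning (kernel=%d)",
                region_map.num_regions, config.kernel_size)
    if region_map.num_regions == 0:
        logger.warning("pipeline: no regions to trace; empty result")
        return []
    rule = config.rule
    if config.scale_rule:
        rule = rule.scaled_for(max(mask.shape))
    fitted: list[FittedLine] = []
    for region in region_map.regions:
        path = trace_boundary(region_map, region.region_id)
        try:
            h_sets, v_sets = split_orientation(path, rule)
        except ValueError:
            logger.info("pipeline: region %d path too short; skipped",
                        region.region_id)
            continue
        for orientation, sets in (("horizontal", h_sets),
                                  ("vertical", v_sets)):
            for pts in sets:
                try:
                    if len(pts) >= config.order + 3:
                        line, diag = remove_outliers_and_refit(
                            pts, config.order, config.z_max, orientation,
                            config.max_iterations)
                    else:
                        line, diag = fit_line_ls(pts, config.order,
                                                 orientation)
                except ValueError:
                    continue        # degenerate or over-pruned set
                if config.subpixel_correction and config.order == 1:
                    line = _offset_half_pixel(line, region_map,
                                              region.region_id)
                fitted.append(FittedLine(
                    region_id=region.region_id, line=line,
                    support=line.support,
                    removed_outliers=diag.removed_indices))
        logger.info("pipeline: region %d -> %d horizontal, %d vertical "
                    "set(s)", region.region_id, len(h_sets), len(v_sets))
    return fitted


def _offset_half_pixel(line: PolynomialLine, region_map,
                       region_id: int) -> PolynomialLine:
    """Shift an order-1 line half a pixel away from its region.

    The fit runs through boundary *pixel centers*, which lie on average
    half a pixel inside the geometric field edge; the correction moves
    the intercept 0.5 px toward the exterior, judged from the region
    centroid's side of the line.
    """
    rows, cols = np.nonzero(region_map.labels == region_id)
    if line.orientation == "horizontal":
        par_c, perp_c = cols.mean(), rows.mean()
    else:
        par_c, perp_c = rows.mean(), cols.mean()
    side = np.sign(perp_c - float(line.predict(np.array([par_c]))[0]))
    if side == 0:
        return line
    c0, c1 = line.coefficients
    return PolynomialLine(orientation=line.orientation, order=1,
                          coefficients=(c0 - 0.5 * float(side), c1),
                          support=line.support)


@dataclass(frozen=True)
class LineEvaluation:
    """Per-line and aggregate angular/vertical errors (Table-4 style)."""

    pairs: tuple[tuple[TrueLine, FittedLine, float, float], ...]
    mean_angular: float
    mean_vertical: float
    per_class: dict

    def n_matched(self) -> int:
        return len(self.pairs)


def _truth_to_line(t: TrueLine) -> PolynomialLine:
    return PolynomialLine(orientation=t.orientation, order=1,
                          coefficients=t.coefficients, support=2)


def evaluate_lines(fitted: list[FittedLine], truth: list[TrueLine],
                   image_size: tuple[int, int],
                   truth_classes: dict[int, str] | None = None
                   ) -> LineEvaluation:
    """Match every true line to the nearest fitted line of the same
    orientation and report angular and vertical errors, with per-class
    (via ``truth_classes``: region_id -> label) and overall means.

    Nearness is the mean absolute deviation between the two lines over
    the true line's span, so parallel boundaries of neighbouring plots
    with similar intercepts but different slopes stay distinguishable.
    """
    h, w = image_size
    pairs = []
    for t in truth:
        candidates = [f for f in fitted
                      if f.line.orientation == t.orientation
                      and f.line.order == 1]
        if not candidates:
            continue
        u = np.array([t.span[0], 0.5 * (t.span[0] + t.span[1]), t.span[1]])
        t_vals = t.coefficients[0] + t.coefficients[1] * u
        best = min(candidates,
                   key=lambda f: float(np.mean(np.abs(
                       f.line.predict(u) - t_vals))))
        tline = _truth_to_line(t)
        ang = angular_error(tline, best.line)
        vert = vertical_error(tline, best.line, h, w)
        pairs.append((t, best, ang, vert))
    if not pairs:
        raise ValueError("no matching line pairs between truth and fit")
    angs = np.array([p[2] for p in pairs])
    verts = np.array([p[3] for p in pairs])
    per_class: dict = {}
    if truth_classes:
        for label in sorted(set(truth_classes.values())):
            sel = [i for i, p in enumerate(pairs)
                   if truth_classes.get(p[0].region_id) == label]
            if sel:
                per_class[label] = {
                    "angular": float(angs[sel].mean()),
                    "vertical": float(verts[sel].mean()),
                    "n": len(sel)}
    return LineEvaluation(pairs=tuple(pairs),
                          mean_angular=float(angs.mean()),
                          mean_vertical=float(verts.mean()),
                          per_class=per_class)


def fitted_lines_to_json(fitted: list[FittedLine], path) -> None:
    with open(path, "w") as fh:
        json.dump([f.to_dict() for f in fitted], fh, indent=1)


def fitted_lines_from_json(path) -> list[FittedLine]:
    with open(path) as fh:
        return [FittedLine.from_dict(d) for d in json.load(fh)]
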