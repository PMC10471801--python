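"""Seeded synthetic field scenes with exact masks and ground-truth lines.

Real orthoimagery of field plots is large and not redistributable, so
every downstream stage here is exercised against generated scenes: convex
quadrilateral plots (Crop or Soil) on a Background canvas, with textured
RGB renderings, masks rasterized exactly from the plot polygons
(pixel-center-in-polygon), and the analytic boundary-line parameters of
every plot edge.  A separate corruption step emulates imperfect
segmentation output (boundary jitter, label speckle, dropout blobs).

Randomness is split into named substreams (geometry / texture / noise)
derived from the scene seed, so adding texture or noise never changes the
geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .dataio import DEFAULT_PALETTE, write_image, write_mask

__all__ = ["SceneConfig", "TrueLine", "NoiseConfig", "generate_scene",
           "perturb_mask", "write_fixture_set"]

CROP, SOIL = 1, 2


@dataclass(frozen=True)
class SceneConfig:
    """Layout and texture of one synthetic scene.

    Plots are convex quadrilaterals jittered from axis-aligned rectangles;
    ``max_edge_slope`` bounds how far each edge may tilt (0.3 by default so
    every edge is unambiguously horizontal or vertical).  Plots are placed
    in disjoint grid cells, guaranteeing >= ``separation`` px between them
    and full containment in the frame.
    """

    size: tuple[int, int] = (256, 256)
    n_plots: int = 1
    plot_classes: tuple[int, ...] | None = None
    base_colors: dict[int, tuple[int, int, int]] = field(default_factory=lambda: {
        0: (96, 96, 104),      # background: gravel/road grey
        CROP: (62, 120, 48),   # crop canopy green
        SOIL: (140, 104, 72),  # bare soil brown
    })
    noise_std: float = 10.0
    crop_stripes: bool = True
    max_edge_slope: float = 0.3
    margin_frac: float = 0.12
    separation: int = 8
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.n_plots <= 4:
            raise ValueError("n_plots must be between 0 and 4")
        if self.plot_classes is not None and len(self.plot_classes) != self.n_plots:
            raise ValueError("plot_classes must have one entry per plot")

    def resolved_classes(self) -> tuple[int, ...]:
        if self.plot_classes is not None:
            return tuple(self.plot_classes)
        return tuple(CROP if i % 2 == 0 else SOIL for i in range(self.n_plots))


@dataclass(frozen=True)
class TrueLine:
    """Analytic boundary line of one plot edge.

    Horizontal lines are ``y = c0 + c1 x`` (|c1| < 1), vertical lines are
    ``x = c0 + c1 y``; coordinates are pixel centers with x rightward,
    y downward, origin at the top-left pixel center.  ``span`` is the range
    of the free coordinate covered by the edge.
    """

    region_id: int
    orientation: str
    coefficients: tuple[float, float]
    span: tuple[float, float]

    def to_dict(self) -> dict:
        return {"region_id": self.region_id, "orientation": self.orientation,
                "coefficients": list(self.coefficients),
                "span": list(self.span)}

    @classmethod
    def from_dict(cls, d: dict) -> "TrueLine":
        return cls(region_id=int(d["region_id"]),
                   orientation=str(d["orientation"]),
                   coefficients=tuple(float(c) for c in d["coefficients"]),
                   span=tuple(float(s) for s in d["span"]))


@dataclass(frozen=True)
class NoiseConfig:
    """Mask corruption emulating imperfect segmentation output."""

    jitter_sigma: float = 0.0
    flip_rate: float = 0.0
    blob_count: int = 0
    blob_radius: tuple[int, int] = (3, 8)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.flip_rate < 0.5:
            raise ValueError("flip_rate must be in [0, 0.5)")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")


def _grid_cells(h: int, w: int, n: int) -> list[tuple[int, int, int, int]]:
    """Disjoint (r0, r1, c0, c1) cells for up to 4 plots, with a gutter."""
    if n == 1:
        return [(0, h, 0, w)]
    if n == 2:
        if w >= h:
            return [(0, h, 0, w // 2), (0, h, w // 2, w)]
        return [(0, h // 2, 0, w), (h // 2, h, 0, w)]
    cells = [(0, h // 2, 0, w // 2), (0, h // 2, w // 2, w),
             (h // 2, h, 0, w // 2), (h // 2, h, w // 2, w)]
    return cells[:n]


def _convex(poly: np.ndarray) -> bool:
    d = np.roll(poly, -1, axis=0) - poly
    cross = d[:, 0] * np.roll(d, -1, axis=0)[:, 1] - \
        d[:, 1] * np.roll(d, -1, axis=0)[:, 0]
    return bool(np.all(cross > 0) or np.all(cross < 0))


def _make_plot_polygon(cell, cfg: SceneConfig, rng: np.random.Generator,
                       sep_half: float) -> np.ndarray:
    """Jittered convex quadrilateral (4 x 2 array of (x, y)) inside a cell."""
    r0, r1, c0, c1 = cell
    ch, cw = r1 - r0, c1 - c0
    my = max(int(cfg.margin_frac * ch), int(np.ceil(sep_half)) + 1)
    mx = max(int(cfg.margin_frac * cw), int(np.ceil(sep_half)) + 1)
    x0, x1 = c0 + mx, c1 - 1 - mx
    y0, y1 = r0 + my, r1 - 1 - my
    if x1 - x0 < 12 or y1 - y0 < 12:
        raise ValueError("scene generation failed: cell too small for a plot")
    width, height = x1 - x0, y1 - y0
    jy = min(0.5 * cfg.max_edge_slope * width, 0.10 * height)
    jx = min(0.5 * cfg.max_edge_slope * height, 0.10 * width)
    for _ in range(64):
        poly = np.array([
            [x0 + rng.uniform(0, jx), y0 + rng.uniform(0, jy)],   # top-left
            [x1 - rng.uniform(0, jx), y0 + rng.uniform(0, jy)],   # top-right
            [x1 - rng.uniform(0, jx), y1 - rng.uniform(0, jy)],   # bottom-right
            [x0 + rng.uniform(0, jx), y1 - rng.uniform(0, jy)],   # bottom-left
        ])
        if _convex(poly):
            return poly
    raise ValueError("scene generation failed: no convex plot after retries")


def _rasterize(poly: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Exact pixel-center-in-(closed)-polygon test for a convex quad."""
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    inside = np.ones(shape, dtype=bool)
    for i in range(len(poly)):
        x0, y0 = poly[i]
        x1, y1 = poly[(i + 1) % len(poly)]
        cross = (x1 - x0) * (ys - y0) - (y1 - y0) * (xs - x0)
        inside &= cross >= 0
    return inside


def _edge_lines(poly: np.ndarray, region_id: int) -> list[TrueLine]:
    lines = []
    for i in range(len(poly)):
        x0, y0 = poly[i]
        x1, y1 = poly[(i + 1) % len(poly)]
        dx, dy = x1 - x0, y1 - y0
        if abs(dx) >= abs(dy):
            slope = dy / dx
            lines.append(TrueLine(region_id, "horizontal",
                                  (float(y0 - slope * x0), float(slope)),
                                  (float(min(x0, x1)), float(max(x0, x1)))))
        else:
            slope = dx / dy
            lines.append(TrueLine(region_id, "vertical",
                                  (float(x0 - slope * y0), float(slope)),
                                  (float(min(y0, y1)), float(max(y0, y1)))))
    return lines


def _texture(mask: np.ndarray, cfg: SceneConfig,
             rng: np.random.Generator) -> np.ndarray:
    h, w = mask.shape
    img = np.zeros((h, w, 3), dtype=np.float32)
    for cls, rgb in cfg.base_colors.items():
        img[mask == cls] = rgb
    img += rng.normal(0.0, cfg.noise_std, size=img.shape)
    if cfg.crop_stripes:
        rows = (np.sin(2 * np.pi * np.arange(h) / 9.0) * 10.0)[:, None, None]
        img += np.where((mask == CROP)[:, :, None], rows, 0.0)
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_scene(config: SceneConfig
                   ) -> tuple[np.ndarray, np.ndarray, list[TrueLine]]:
    """Render one scene: (RGB image, label mask, ground-truth lines).

    The mask is rasterized exactly from the plot polygons (pixel center
    inside the closed polygon -> plot class, else Background), so every
    returned line coincides with a mask class transition to within one
    pixel along its span.  Identical configs produce identical output.
    """
    h, w = config.size
    seq = np.random.SeedSequence(config.seed)
    geom_rng, tex_rng = (np.random.default_rng(s) for s in seq.spawn(2))
    mask = np.zeros((h, w), dtype=np.uint8)
    lines: list[TrueLine] = []
    classes = config.resolved_classes()
    cells = _grid_cells(h, w, config.n_plots) if config.n_plots else []
    for i, cell in enumerate(cells):
        poly = _make_plot_polygon(cell, config, geom_rng,
                                  sep_half=config.separation / 2)
        mask[_rasterize(poly, (h, w))] = classes[i]
        lines.extend(_edge_lines(poly, region_id=i))
    image = _texture(mask, config, tex_rng)
    return image, mask, lines


def perturb_mask(mask: np.ndarray, noise: NoiseConfig) -> np.ndarray:
    """Corrupt a mask: boundary jitter, independent label flips, dropout
    blobs.  All-zero noise returns the input unchanged (same array values).
    """
    out = np.asarray(mask, dtype=np.uint8).copy()
    h, w = out.shape
    seq = np.random.SeedSequence(noise.seed)
    jit_rng, flip_rng, blob_rng = (np.random.default_rng(s)
                                   for s in seq.spawn(3))
    if noise.jitter_sigma > 0:
        smooth = 4.0
        disp = []
        for _ in range(2):
            f = ndimage.gaussian_filter(
                jit_rng.normal(size=(h, w)), smooth, mode="reflect")
            std = f.std()
            disp.append(f * (noise.jitter_sigma / std) if std > 0 else f)
        ys, xs = np.mgrid[0:h, 0:w].astype(np.float64)
        coords = np.array([np.clip(ys + disp[0], 0, h - 1),
                           np.clip(xs + disp[1], 0, w - 1)])
        out = ndimage.map_coordinates(out, coords, order=0, mode="nearest")
    if noise.flip_rate > 0:
        flips = flip_rng.random((h, w)) < noise.flip_rate
        offsets = flip_rng.integers(1, 3, size=(h, w)).astype(np.uint8)
        out = np.where(flips, (out + offsets) % 3, out).astype(np.uint8)
    for _ in range(noise.blob_count):
        r = int(blob_rng.integers(noise.blob_radius[0],
                                  noise.blob_radius[1] + 1))
        cy = int(blob_rng.integers(0, h))
        cx = int(blob_rng.integers(0, w))
        ys, xs = np.ogrid[0:h, 0:w]
        out[(ys - cy) ** 2 + (xs - cx) ** 2 <= r * r] = 0
    return out


def write_fixture_set(configs: list[SceneConfig], out_dir,
                      noise: NoiseConfig | None = None) -> list[str]:
    """Emit a dataset in the standard layout plus per-scene truth records
    (``truth/<name>.lines.json``).  Returns the scene names."""
    out = Path(out_dir)
    for sub in ("images", "masks", "truth"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    names = []
    for i, cfg in enumerate(configs):
        name = f"scene_{i:04d}"
        image, mask, lines = generate_scene(cfg)
        if noise is not None:
            mask = perturb_mask(mask, noise)
        write_image(out / "images" / f"{name}.png", image)
        write_mask(out / "masks" / f"{name}.png", mask, DEFAULT_PALETTE)
        (out / "truth" / f"{name}.lines.json").write_text(
            json.dumps([ln.to_dict() for ln in lines], indent=1))
        names.append(name)
    return names
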