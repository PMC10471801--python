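"""Dataset I/O: palette label masks, image tiling and train/val splitting.

Label masks are 8-bit indexed PNGs with the class palette embedded; the
index raster (0=Background, 1=Crop, 2=Soil) is authoritative and the
palette colors are display-only.  Source imagery may be PNG or TIFF
(read as plain RGB; geotags are ignored).  Datasets live on disk as
``images/<name>.png``, ``masks/<name>.png`` and ``splits/{train,val}.txt``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["ClassPalette", "DEFAULT_PALETTE", "SegmentationSample",
           "DatasetSplit", "read_mask", "write_mask", "read_image",
           "write_image", "tile_image", "split_dataset", "write_split",
           "read_split"]


@dataclass(frozen=True)
class ClassPalette:
    """Ordered label set; index 0 is always Background."""

    names: tuple[str, ...] = ("Background", "Crop", "Soil")
    colors: tuple[tuple[int, int, int], ...] = (
        (0, 0, 0), (0, 160, 60), (150, 100, 40))

    def __post_init__(self):
        if len(self.names) != len(self.colors):
            raise ValueError("names and colors must align")
        if self.names[0] != "Background":
            raise ValueError("index 0 must be Background")

    @property
    def num_classes(self) -> int:
        """k + 1 (object classes plus background)."""
        return len(self.names)

    @property
    def indices(self) -> tuple[int, ...]:
        return tuple(range(len(self.names)))

    def flat_palette(self) -> list[int]:
        flat = [c for rgb in self.colors for c in rgb]
        flat += [0] * (768 - len(flat))
        return flat


DEFAULT_PALETTE = ClassPalette()


@dataclass
class SegmentationSample:
    """One tile: RGB image, its label mask and the tile name."""

    image: np.ndarray
    mask: np.ndarray
    name: str

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError("image and mask dimensions must match")


@dataclass(frozen=True)
class DatasetSplit:
    train: tuple[str, ...]
    val: tuple[str, ...]
    ratio: float
    seed: int


def _validate_mask(mask: np.ndarray, palette: ClassPalette) -> np.ndarray:
    mask = np.asarray(mask)
    bad = mask > palette.num_classes - 1
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"unknown label {int(mask[r, c])} at pixel (row={int(r)}, "
            f"col={int(c)}); valid labels are {palette.indices}")
    return mask.astype(np.uint8)


def write_mask(path, mask: np.ndarray,
               palette: ClassPalette = DEFAULT_PALETTE) -> None:
    """Write a label mask as an 8-bit indexed PNG with embedded palette."""
    mask = _validate_mask(mask, palette)
    img = Image.fromarray(mask, mode="P")
    img.putpalette(palette.flat_palette())
    img.save(path, format="PNG")


def read_mask(path, palette: ClassPalette = DEFAULT_PALETTE) -> np.ndarray:
    """Read an indexed-PNG label mask back to its index raster."""
    with Image.open(path) as img:
        if img.mode not in ("P", "L"):
            raise ValueError(
                f"{path}: expected an 8-bit indexed mask PNG, got mode "
                f"{img.mode!r}")
        arr = np.asarray(img, dtype=np.uint8)
    return _validate_mask(arr, palette)


def read_image(path) -> np.ndarray:
    """Read PNG/TIFF imagery as an H x W x 3 uint8 array (geotags ignored)."""
    with Image.open(path) as img:
        return np.asarray(img.convert("RGB"), dtype=np.uint8)


def write_image(path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)


def tile_image(image: np.ndarray, tile_size: int, count: int,
               seed: int = 0) -> list[tuple[str, np.ndarray]]:
    """Randomly crop ``count`` square tiles, named ``"<row>_<col>"`` after
    the (0-based) pixel coordinates of each tile's top-left pixel."""
    h, w = image.shape[:2]
    if tile_size > min(h, w):
        raise ValueError(
            f"tile larger than image: tile_size {tile_size} exceeds image "
            f"extent {h}x{w}")
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(seed)
    tiles = []
    for _ in range(count):
        row = int(rng.integers(0, h - tile_size + 1))
        col = int(rng.integers(0, w - tile_size + 1))
        tiles.append((f"{row}_{col}",
                      image[row:row + tile_size, col:col + tile_size].copy()))
    return tiles


def split_dataset(names: list[str], ratio: float = 0.9,
                  seed: int = 0) -> DatasetSplit:
    """Deterministic random partition into train/val at the given ratio.

    The train size is ``floor(ratio * n)``; the remainder goes to
    validation (6386 names at 0.9 -> 5747 train / 639 val).
    """
    if not names:
        raise ValueError("empty dataset")
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = list(names)
    rng.shuffle(order)
    n_train = int(np.floor(ratio * len(order)))
    return DatasetSplit(train=tuple(order[:n_train]),
                        val=tuple(order[n_train:]), ratio=ratio, seed=seed)


def write_split(split: DatasetSplit, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for part in ("train", "val"):
        (out / f"{part}.txt").write_text(
            "".join(f"{n}\n" for n in getattr(split, part)))


def read_split(split_dir) -> tuple[list[str], list[str]]:
    d = Path(split_dir)
    return ([ln for ln in (d / "train.txt").read_text().splitlines() if ln],
            [ln for ln in (d / "val.txt").read_text().splitlines() if ln])
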