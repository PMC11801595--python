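"""Micrograph I/O, dataset manifests, quadrant tiling and the stratified split.

Source micrographs are 512x512 8-bit grayscale images organized by imaging
modality (SEM or AFM) and diagnostic class (normal, benign, malign).  Each
source image is cut into four non-overlapping 256x256 quadrant tiles; the
study protocol uses 45 source images per class per modality, hence
3 * 4 * 45 = 540 tiles per modality, of which half (270, stratified by class)
train the classifiers and half test them.

Manifests are plain CSV tables with columns
``path,modality,label,source_id,tile_index,split``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

MODALITIES = ("SEM", "AFM")
LABELS = ("normal", "benign", "malign")
SOURCE_SIZE = 512
TILE_SIZE = 256
MANIFEST_COLUMNS = ("path", "modality", "label", "source_id", "tile_index", "split")

#: Row-major quadrant offsets: 0 top-left, 1 top-right, 2 bottom-left,
#: 3 bottom-right, coordinates 0-based (row, col).
QUADRANT_OFFSETS = ((0, 0), (0, TILE_SIZE), (TILE_SIZE, 0), (TILE_SIZE, TILE_SIZE))

# ITU-R BT.601 luma weights, used to collapse RGB inputs.
_LUMA = np.array([0.299, 0.587, 0.114])


class FormatError(ValueError):
    """Raised for images whose layout or dtype is not a supported raster."""


class DimensionError(ValueError):
    """Raised when an image does not have the dimensions an operation requires."""


class SplitError(ValueError):
    """Raised when the manifest cannot be split per the stratified protocol."""


@dataclass
class GrayImage:
    """A 2-D 8-bit intensity raster with acquisition metadata.

    ``tile_index`` is None for a 512x512 source image and 0-3 for one of its
    quadrant tiles.
    """

    pixels: np.ndarray
    modality: str
    label: str
    source_id: str
    tile_index: int | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise FormatError(f"expected a 2-D raster, got ndim={self.pixels.ndim}")
        if self.pixels.size == 0:
            raise FormatError("empty raster")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise FormatError("pixel values outside [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if self.modality not in MODALITIES:
            raise FormatError(f"unknown modality {self.modality!r}")
        if self.label not in LABELS:
            raise FormatError(f"unknown label {self.label!r}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def load_image(path: str | Path, modality: str, label: str,
               source_id: str | None = None) -> GrayImage:
    """Read a PNG/TIFF micrograph as an 8-bit grayscale :class:`GrayImage`.

    RGB(A) input is collapsed to luma (BT.601 weights) and rounded to 8-bit.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - decoder errors vary by plugin
        raise IOError(f"cannot read image {path}: {exc}") from exc
    raw = np.asarray(raw)
    if raw.ndim == 3:
        if raw.shape[2] not in (3, 4):
            raise FormatError(f"unsupported channel count {raw.shape[2]} in {path}")
        raw = np.rint(raw[..., :3].astype(np.float64) @ _LUMA)
        raw = np.clip(raw, 0, 255).astype(np.uint8)
    elif raw.ndim != 2:
        raise FormatError(f"non-2-D image data in {path} (ndim={raw.ndim})")
    return GrayImage(pixels=raw, modality=modality, label=label,
                     source_id=source_id or path.stem)


def save_image(img: GrayImage, path: str | Path) -> None:
    """Write an 8-bit grayscale PNG/TIFF (format chosen by extension)."""
    iio.imwrite(Path(path), img.pixels)


def tile_image(img: GrayImage) -> list[GrayImage]:
    """Cut a 512x512 source image into its four 256x256 quadrants.

    Quadrants are indexed row-major: 0 top-left, 1 top-right, 2 bottom-left,
    3 bottom-right.  The tiles are views-copies of disjoint pixel regions
    whose union reconstructs the source exactly.
    """
    if img.pixels.shape != (SOURCE_SIZE, SOURCE_SIZE):
        raise DimensionError(
            f"tiling requires a {SOURCE_SIZE}x{SOURCE_SIZE} image, "
            f"got {img.pixels.shape}")
    tiles = []
    for idx, (r, c) in enumerate(QUADRANT_OFFSETS):
        tiles.append(replace(
            img,
            pixels=img.pixels[r:r + TILE_SIZE, c:c + TILE_SIZE].copy(),
            tile_index=idx,
        ))
    return tiles


def mosaic_tiles(tiles: Sequence[GrayImage]) -> np.ndarray:
    """Reassemble four quadrant tiles into the 512x512 source raster."""
    if len(tiles) != 4:
        raise DimensionError(f"need exactly 4 tiles, got {len(tiles)}")
    out = np.empty((SOURCE_SIZE, SOURCE_SIZE), dtype=np.uint8)
    for t in tiles:
        if t.tile_index is None or t.pixels.shape != (TILE_SIZE, TILE_SIZE):
            raise DimensionError("mosaic requires four indexed 256x256 tiles")
        r, c = QUADRANT_OFFSETS[t.tile_index]
        out[r:r + TILE_SIZE, c:c + TILE_SIZE] = t.pixels
    return out


def new_manifest(records: Sequence[dict] = ()) -> pd.DataFrame:
    """Build a manifest DataFrame with the canonical column set."""
    df = pd.DataFrame(list(records), columns=list(MANIFEST_COLUMNS))
    if "split" in df.columns:
        df["split"] = df["split"].fillna("unassigned")
    return df


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"source_id": str, "path": str, "split": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"manifest {path} missing columns {sorted(missing)}")
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=list(MANIFEST_COLUMNS))


def validate_manifest(df: pd.DataFrame) -> None:
    """Check uniqueness of (source_id, tile_index) and known enum values."""
    dup = df.duplicated(subset=["modality", "source_id", "tile_index"])
    if dup.any():
        raise FormatError("duplicate (source_id, tile_index) pairs in manifest")
    if not df["modality"].isin(MODALITIES).all():
        raise FormatError("manifest contains unknown modality values")
    if not df["label"].isin(LABELS).all():
        raise FormatError("manifest contains unknown label values")


def split_train_test(manifest: pd.DataFrame, seed: int,
                     by_source: bool = False) -> pd.DataFrame:
    """Assign a stratified half/half train/test split to a tile manifest.

    Within each (modality, label) stratum, exactly half the tiles are drawn
    uniformly at random (seeded) into the training split and the rest into
    the test split: with the standard 540-tile protocol this gives 270 train
    and 270 test tiles, 90 training tiles per class.  The split is
    deterministic for a fixed seed.

    With ``by_source=True`` the draw is over source images instead, so the
    four sibling tiles of one micrograph never straddle the split; source
    counts are halved with the odd remainder going to the test side.
    """
    df = manifest.copy()
    for label in LABELS:
        if not (df["label"] == label).any():
            raise SplitError(f"label {label!r} missing from manifest")
    rng = np.random.default_rng(seed)
    df["split"] = "unassigned"
    # deterministic stratum order regardless of row order
    for modality in sorted(df["modality"].unique()):
        for label in LABELS:
            sel = (df["modality"] == modality) & (df["label"] == label)
            idx = df.index[sel]
            if not by_source:
                if len(idx) % 2:
                    raise SplitError(
                        f"odd tile count ({len(idx)}) for {modality}/{label}")
                perm = rng.permutation(len(idx))
                train_idx = idx[perm[:len(idx) // 2]]
            else:
                sources = sorted(df.loc[idx, "source_id"].unique())
                perm = rng.permutation(len(sources))
                train_sources = {sources[i] for i in perm[:len(sources) // 2]}
                train_idx = idx[df.loc[idx, "source_id"].isin(train_sources)]
            df.loc[idx, "split"] = "test"
            df.loc[train_idx, "split"] = "train"
    return df


def tile_dataset(manifest: pd.DataFrame, out_dir: str | Path) -> pd.DataFrame:
    """Tile every source image of a manifest to disk; return the tile manifest.

    Tiles are written as PNG next to their metadata; rows of the input
    manifest that already describe tiles (tile_index set) are passed through.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for _, row in manifest.iterrows():
        if not pd.isna(row["tile_index"]) and str(row["tile_index"]) != "":
            records.append(row.to_dict())
            continue
        img = load_image(row["path"], row["modality"], row["label"],
                         source_id=str(row["source_id"]))
        for tile in tile_image(img):
            tpath = out_dir / f"{tile.source_id}_t{tile.tile_index}.png"
            save_image(tile, tpath)
            records.append({
                "path": str(tpath), "modality": tile.modality,
                "label": tile.label, "source_id": tile.source_id,
                "tile_index": tile.tile_index, "split": "unassigned",
            })
    return new_manifest(records)
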