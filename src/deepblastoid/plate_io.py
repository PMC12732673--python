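"""Plate-image cropping, manifest I/O and dataset splitting.

A whole-well brightfield image contains a regular grid of microwells. With
a declared :class:`PlateLayout` (origin, pitch, tile size) cropping is a
pure byte-exact slicing operation — no resampling and no intensity
adjustment — so that crop followed by re-assembly is lossless.

Splitting supports the three schemes used when training microwell
classifiers: a seeded random train/validation/test partition, k-fold
cross-validation, and round-robin by experimental batch (train on all
batches but one, validate on the held-out batch).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "PlateLayout",
    "DatasetSplit",
    "crop_plate",
    "assemble_plate",
    "split_dataset",
    "read_manifest",
    "write_manifest",
    "merge_manifests",
    "read_image",
    "write_image",
]

MANIFEST_COLUMNS = ["path", "label", "batch", "row", "col"]


@dataclasses.dataclass(frozen=True)
class PlateLayout:
    """Grid geometry mapping plate pixels to microwell tiles.

    ``origin_px`` is the (x, y) of the first tile's top-left corner;
    ``pitch_px`` the (dx, dy) between adjacent tile origins; ``tile_px``
    the (w, h) of each tile. Boxes are half-open [x0, x1) x [y0, y1),
    0-based, row-major.
    """

    rows: int
    cols: int
    origin_px: tuple[int, int] = (0, 0)
    pitch_px: tuple[int, int] = (300, 300)
    tile_px: tuple[int, int] = (300, 300)

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("rows and cols must be >= 1")
        if self.tile_px[0] > self.pitch_px[0] or self.tile_px[1] > self.pitch_px[1]:
            raise ValueError("tile must fit within the pitch")

    def tile_box(self, row: int, col: int) -> tuple[int, int, int, int]:
        """Pixel box (x0, y0, x1, y1) of the tile at (row, col)."""
        x0 = self.origin_px[0] + col * self.pitch_px[0]
        y0 = self.origin_px[1] + row * self.pitch_px[1]
        return x0, y0, x0 + self.tile_px[0], y0 + self.tile_px[1]

    def plate_extent(self) -> tuple[int, int]:
        """Minimal (height, width) of a plate image holding every tile."""
        x0, y0, x1, y1 = self.tile_box(self.rows - 1, self.cols - 1)
        return y1, x1


def crop_plate(
    plate_image: np.ndarray, layout: PlateLayout
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Cut a plate image into its microwell tiles.

    Tiles are byte-exact sub-rectangles in row-major order. A layout whose
    boxes leave the image raises a ValueError listing the offending tiles.

    Returns the tiles and a manifest with (row, col, x0, y0, x1, y1).
    """
    plate_image = np.asarray(plate_image)
    h, w = plate_image.shape[:2]
    offending = []
    for row in range(layout.rows):
        for col in range(layout.cols):
            x0, y0, x1, y1 = layout.tile_box(row, col)
            if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
                offending.append((row, col))
    if offending:
        raise ValueError(f"layout exceeds image bounds for tiles {offending}")

    tiles, records = [], []
    for row in range(layout.rows):
        for col in range(layout.cols):
            x0, y0, x1, y1 = layout.tile_box(row, col)
            tiles.append(plate_image[y0:y1, x0:x1].copy())
            records.append({"row": row, "col": col, "x0": x0, "y0": y0, "x1": x1, "y1": y1})
    return tiles, pd.DataFrame.from_records(records)


def assemble_plate(
    tiles: Sequence[np.ndarray], layout: PlateLayout, fill: int = 0
) -> np.ndarray:
    """Place row-major tiles at the layout's boxes (the inverse of cropping
    on the covered region)."""
    if len(tiles) != layout.rows * layout.cols:
        raise ValueError("need exactly rows*cols tiles")
    ph, pw = layout.plate_extent()
    plate = np.full((ph, pw), fill, dtype=np.asarray(tiles[0]).dtype)
    for idx, tile in enumerate(tiles):
        row, col = divmod(idx, layout.cols)
        x0, y0, x1, y1 = layout.tile_box(row, col)
        plate[y0:y1, x0:x1] = tile
    return plate


# ---------------------------------------------------------------------------
# splits


@dataclasses.dataclass(frozen=True)
class DatasetSplit:
    """Disjoint train/validation/test index lists covering the input set."""

    train: tuple[int, ...]
    val: tuple[int, ...]
    test: tuple[int, ...] = ()
    scheme: str = "random"

    def __post_init__(self) -> None:
        parts = [set(self.train), set(self.val), set(self.test)]
        total = sum(len(p) for p in parts)
        union = set().union(*parts)
        if total != len(union):
            raise ValueError("split index lists must be disjoint")

    @property
    def indices(self) -> set[int]:
        return set(self.train) | set(self.val) | set(self.test)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "scheme": self.scheme,
                    "train": list(self.train),
                    "val": list(self.val),
                    "test": list(self.test),
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "DatasetSplit":
        d = json.loads(Path(path).read_text())
        return cls(tuple(d["train"]), tuple(d["val"]), tuple(d["test"]), d["scheme"])


def _random_split(
    n: int,
    n_train: int,
    n_val: int,
    n_test: int,
    rng: np.random.Generator,
    stratify_labels: Sequence | None = None,
) -> DatasetSplit:
    if n_train + n_val + n_test != n:
        raise ValueError(
            f"requested sizes {n_train}+{n_val}+{n_test} != dataset size {n}"
        )
    if stratify_labels is not None:
        # proportional allocation per class via a single shuffled pass per class
        labels = np.asarray(stratify_labels)
        if labels.shape[0] != n:
            raise ValueError("stratify labels must match dataset size")
        train, val, test = [], [], []
        quota = {"train": n_train, "val": n_val, "test": n_test}
        classes = sorted(pd.unique(labels).tolist())
        for cls_v in classes:
            idx = np.nonzero(labels == cls_v)[0]
            rng.shuffle(idx)
            ntr = int(round(len(idx) * n_train / n))
            nva = int(round(len(idx) * n_val / n))
            train.extend(idx[:ntr]); val.extend(idx[ntr : ntr + nva]); test.extend(idx[ntr + nva :])
        # fix rounding drift by moving surplus items between lists
        pools = {"train": train, "val": val, "test": test}
        for name in ("train", "val"):
            while len(pools[name]) > quota[name]:
                pools["test"].append(pools[name].pop())
            while len(pools[name]) < quota[name] and pools["test"]:
                pools[name].append(pools["test"].pop())
        return DatasetSplit(tuple(map(int, train)), tuple(map(int, val)), tuple(map(int, test)), "random")
    perm = rng.permutation(n)
    return DatasetSplit(
        tuple(map(int, perm[:n_train])),
        tuple(map(int, perm[n_train : n_train + n_val])),
        tuple(map(int, perm[n_train + n_val :])),
        "random",
    )


def split_dataset(
    manifest: pd.DataFrame | int,
    scheme: str = "random",
    seed: int = 0,
    n_train: int | None = None,
    n_val: int | None = None,
    n_test: int = 0,
    k: int = 5,
    fold: int = 0,
    holdout_batch: int | None = None,
    stratify: bool = False,
) -> DatasetSplit:
    """Partition a dataset into train/validation(/test) index lists.

    Parameters
    ----------
    manifest:
        A manifest DataFrame, or just the dataset size for schemes that do
        not need per-item metadata.
    scheme:
        ``random`` — seeded permutation into sizes (n_train, n_val, n_test);
        ``kfold`` — fold ``fold`` of ``k`` contiguous-after-shuffle folds is
        validation, the rest train;
        ``round_robin`` — train on every batch except ``holdout_batch``,
        which becomes validation (batches come from the manifest's
        ``batch`` column).
    stratify:
        For ``random`` only: allocate each class proportionally (requires a
        manifest with a ``label`` column). Off by default.

    All schemes are reproducible under a fixed seed.
    """
    if isinstance(manifest, (int, np.integer)):
        n, df = int(manifest), None
    else:
        df, n = manifest, len(manifest)
    rng = np.random.default_rng(seed)

    if scheme == "random":
        if n_train is None or n_val is None:
            raise ValueError("random scheme needs n_train and n_val")
        labels = None
        if stratify:
            if df is None or "label" not in df:
                raise ValueError("stratified split needs a manifest with labels")
            labels = df["label"].to_numpy()
        return _random_split(n, n_train, n_val, n_test, rng, labels)

    if scheme == "kfold":
        if k > n:
            raise ValueError(f"k={k} exceeds dataset size {n}")
        if not 0 <= fold < k:
            raise ValueError(f"fold must lie in [0, {k})")
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
        val = folds[fold]
        train = np.concatenate([f for i, f in enumerate(folds) if i != fold])
        return DatasetSplit(tuple(map(int, train)), tuple(map(int, val)), (), f"kfold({k},{fold})")

    if scheme == "round_robin":
        if df is None or "batch" not in df:
            raise ValueError("round_robin needs a manifest with a batch column")
        batches = df["batch"].to_numpy()
        if holdout_batch is None:
            raise ValueError("round_robin needs holdout_batch")
        if holdout_batch not in set(batches.tolist()):
            raise ValueError(f"batch {holdout_batch} not present in manifest")
        val = np.nonzero(batches == holdout_batch)[0]
        train = np.nonzero(batches != holdout_batch)[0]
        return DatasetSplit(
            tuple(map(int, train)), tuple(map(int, val)), (), f"round_robin({holdout_batch})"
        )

    raise ValueError(f"unknown split scheme {scheme!r}")


# ---------------------------------------------------------------------------
# manifests and images


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a CSV manifest (path,label,batch,row,col)."""
    return pd.read_csv(path)


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, index=False)


def merge_manifests(*manifests: pd.DataFrame) -> pd.DataFrame:
    """Concatenate manifests (e.g. labeled + unlabeled pools) into one
    bookkeeping table; row count is the total image count."""
    return pd.concat(manifests, ignore_index=True)


def load_tiles(manifest: pd.DataFrame, root: str | Path) -> np.ndarray:
    """Stack the manifest's PNG tiles (paths relative to root) into an
    (n, h, w) array."""
    root = Path(root)
    return np.stack([read_image(root / p) for p in manifest["path"]])


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale PNG tile, preserving 16-bit depth."""
    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., 0]
    return img


def write_image(path: str | Path, image: np.ndarray) -> None:
    iio.imwrite(path, image)
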