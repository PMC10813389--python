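"""Image / annotation / split I/O and bookkeeping.

Coordinate convention used throughout the package: 0-based, ``x`` is the
column index, ``y`` the row index, sub-pixel float positions allowed.

Annotation files are CSV with header ``image_id,x,y`` (one row per center);
split files are JSON with keys ``train`` / ``val`` / ``test`` / ``seed``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import imageio.v3 as iio
import numpy as np

DEFAULT_UM_PER_PX = 0.645

ANNOTATION_SOURCES = ("manual", "model", "model_corrected")


class AnnotationFormatError(ValueError):
    """Malformed annotation file (reported with the offending line number)."""


class AnnotationBoundsError(ValueError):
    """A center coordinate lies outside the image bounds."""


@dataclass
class AnnotatedImage:
    """A grayscale image plus its cell-center points and provenance.

    ``pixels`` may be None for annotation-only records (e.g. straight from a
    CSV before the image is loaded); bounds validation is skipped then.
    """

    image_id: str
    pixels: np.ndarray | None
    centers: np.ndarray
    source: str = "manual"
    um_per_px: float = DEFAULT_UM_PER_PX

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=np.float64).reshape(-1, 2)
        if self.source not in ANNOTATION_SOURCES:
            raise ValueError(
                f"source must be one of {ANNOTATION_SOURCES}, got {self.source!r}"
            )
        if self.pixels is not None:
            self.pixels = np.asarray(self.pixels)
            if self.pixels.ndim != 2:
                raise ValueError(f"{self.image_id}: pixels must be 2-D grayscale")
            validate_centers(self.centers, self.pixels.shape, self.image_id)

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def n_centers(self) -> int:
        return int(self.centers.shape[0])

    def with_(self, **changes) -> "AnnotatedImage":
        return replace(self, **changes)


def validate_centers(
    centers: np.ndarray, shape: tuple[int, int], image_id: str = "?"
) -> None:
    """Raise :class:`AnnotationBoundsError` unless all (x, y) lie inside ``shape``."""
    centers = np.asarray(centers, dtype=np.float64).reshape(-1, 2)
    if centers.size == 0:
        return
    h, w = shape
    x, y = centers[:, 0], centers[:, 1]
    bad = (x < 0) | (x > w - 1) | (y < 0) | (y > h - 1) | ~np.isfinite(x) | ~np.isfinite(y)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise AnnotationBoundsError(
            f"image {image_id!r}: center {tuple(centers[i])} outside {w}x{h} bounds"
        )


# ---------------------------------------------------------------------------
# images


def save_image(path: str | Path, pixels: np.ndarray) -> None:
    """Write an 8-bit grayscale PNG/TIFF."""
    arr = np.asarray(pixels)
    if arr.dtype != np.uint8:
        arr = np.clip(np.round(arr), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), arr)


def load_image(path: str | Path) -> np.ndarray:
    """Read an image as a 2-D grayscale array (averaging channels if needed)."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
        arr = np.clip(np.round(arr), 0, 255).astype(np.uint8)
    return arr


# ---------------------------------------------------------------------------
# annotations


def save_annotations(records: Iterable[AnnotatedImage] | AnnotatedImage, path: str | Path) -> None:
    """Write center annotations as CSV ``image_id,x,y`` (repr-precision floats)."""
    if isinstance(records, AnnotatedImage):
        records = [records]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["image_id", "x", "y"])
        for rec in records:
            for x, y in rec.centers:
                w.writerow([rec.image_id, repr(float(x)), repr(float(y))])


def load_annotations(
    path: str | Path,
    shapes: Mapping[str, tuple[int, int]] | None = None,
    image_ids: Sequence[str] | None = None,
    source: str = "manual",
) -> list[AnnotatedImage]:
    """Load an annotation CSV into pixel-less :class:`AnnotatedImage` records.

    ``shapes`` maps image_id -> (height, width) and enables bounds validation.
    ``image_ids`` forces records (possibly with zero centers) for the listed
    ids, so an image with an empty annotation set still yields a record.
    Malformed rows raise :class:`AnnotationFormatError` with the line number.
    """
    path = Path(path)
    per_image: dict[str, list[tuple[float, float]]] = {}
    if image_ids is not None:
        for iid in image_ids:
            per_image[iid] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [c.strip().lower() for c in header[:3]] != ["image_id", "x", "y"]:
            raise AnnotationFormatError(f"{path}: line 1: expected header 'image_id,x,y'")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 3:
                raise AnnotationFormatError(f"{path}: line {lineno}: expected 3 fields, got {len(row)}")
            iid = row[0].strip()
            try:
                x, y = float(row[1]), float(row[2])
            except ValueError as exc:
                raise AnnotationFormatError(f"{path}: line {lineno}: non-numeric coordinate") from exc
            per_image.setdefault(iid, []).append((x, y))
    out = []
    for iid, pts in per_image.items():
        centers = np.asarray(pts, dtype=np.float64).reshape(-1, 2)
        if shapes is not None and iid in shapes:
            validate_centers(centers, shapes[iid], iid)
        out.append(AnnotatedImage(image_id=iid, pixels=None, centers=centers, source=source))
    return out


# ---------------------------------------------------------------------------
# splits


@dataclass
class SplitSpec:
    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]
    seed: int = 0

    def __post_init__(self) -> None:
        parts = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        total = sum(len(p) for p in parts)
        if len(parts[0] | parts[1] | parts[2]) != total:
            raise ValueError("split parts are not pairwise disjoint")

    @property
    def all_ids(self) -> list[str]:
        return list(self.train_ids) + list(self.val_ids) + list(self.test_ids)


def make_split(
    ids: Sequence[str],
    sizes: tuple[int, int, int],
    seed: int,
    groups: Mapping[str, str] | None = None,
) -> SplitSpec:
    """Deterministic seeded shuffle of ``ids`` partitioned into train/val/test.

    With ``groups`` (image_id -> lot label) whole groups are assigned greedily
    in shuffled order, keeping same-lot images in one part; part sizes are then
    only approximate (filled to target in train, val, test order).
    """
    ids = list(ids)
    n_train, n_val, n_test = (int(s) for s in sizes)
    if n_train + n_val + n_test != len(ids):
        raise ValueError(f"sizes {sizes} do not sum to {len(ids)} ids")
    if min(n_train, n_val, n_test) < 0:
        raise ValueError("split sizes must be non-negative")
    rng = np.random.default_rng(seed)
    if groups is None:
        perm = rng.permutation(len(ids))
        shuffled = [ids[i] for i in perm]
        return SplitSpec(
            train_ids=shuffled[:n_train],
            val_ids=shuffled[n_train : n_train + n_val],
            test_ids=shuffled[n_train + n_val :],
            seed=seed,
        )
    group_names = sorted({groups[i] for i in ids})
    order = rng.permutation(len(group_names))
    parts: list[list[str]] = [[], [], []]
    targets = [n_train, n_val, n_test]
    for gi in order:
        members = [i for i in ids if groups[i] == group_names[gi]]
        # place in the part furthest below its target
        deficit = [targets[k] - len(parts[k]) for k in range(3)]
        k = int(np.argmax(deficit))
        parts[k].extend(members)
    return SplitSpec(train_ids=parts[0], val_ids=parts[1], test_ids=parts[2], seed=seed)


def save_split(split: SplitSpec, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "train": list(split.train_ids),
        "val": list(split.val_ids),
        "test": list(split.test_ids),
        "seed": split.seed,
    }
    path.write_text(json.dumps(payload, indent=2))


def load_split(path: str | Path) -> SplitSpec:
    data = json.loads(Path(path).read_text())
    return SplitSpec(
        train_ids=data["train"], val_ids=data["val"], test_ids=data["test"],
        seed=int(data.get("seed", 0)),
    )


# ---------------------------------------------------------------------------
# manifests (written by synthetic.generate_dataset)


def load_from_manifest(manifest_path: str | Path, source: str = "manual") -> list[AnnotatedImage]:
    """Load images + annotations listed in a dataset manifest CSV."""
    import pandas as pd

    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    root = manifest_path.parent
    records = []
    for row in df.itertuples(index=False):
        pixels = load_image(root / row.path)
        anns = load_annotations(
            root / row.annotation_path,
            shapes={row.image_id: pixels.shape},
            image_ids=[row.image_id],
            source=source,
        )
        by_id = {a.image_id: a for a in anns}
        centers = by_id[row.image_id].centers if row.image_id in by_id else np.empty((0, 2))
        records.append(
            AnnotatedImage(image_id=row.image_id, pixels=pixels, centers=centers, source=source)
        )
    return records
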