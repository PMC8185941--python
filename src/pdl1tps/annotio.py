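"""Readers/writers, coordinate conventions, and tiling.

Conventions used throughout the package:

* coordinates are 0-based, ``x`` = pixel column, ``y`` = pixel row,
  pixel-center convention;
* tile ranges are half-open ``[off, off + size)``;
* region masks are stored at region scale (1/4 of the cell-scale linear
  resolution by default, mirroring a 10x region vs 40x cell annotation
  regime) and upsampled by nearest neighbour when a *label* map must reach
  cell scale.
"""

from __future__ import annotations

import csv
import enum
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import imageio.v3 as iio

logger = logging.getLogger("pdl1tps")


class CellClass(enum.Enum):
    """The five annotated cell classes."""

    TC_POS = "TC_POS"
    TC_NEG = "TC_NEG"
    LYMPHOCYTE = "LYMPHOCYTE"
    HISTOCYTE = "HISTOCYTE"
    FIBROCYTE = "FIBROCYTE"


#: Classes that count as tumor cells for TPS.
TUMOR_CLASSES = (CellClass.TC_POS, CellClass.TC_NEG)
#: Classes that can count as intratumoral immune cells for IPS.
IMMUNE_CLASSES = (CellClass.LYMPHOCYTE, CellClass.HISTOCYTE)

#: channel order shared by target maps, probability maps and detections
CLASS_ORDER = (
    CellClass.TC_POS,
    CellClass.TC_NEG,
    CellClass.LYMPHOCYTE,
    CellClass.HISTOCYTE,
    CellClass.FIBROCYTE,
)
CLASS_INDEX = {c: i for i, c in enumerate(CLASS_ORDER)}


class RegionLabel(enum.IntEnum):
    """Region-mask label values (single-channel PNG)."""

    BACKGROUND = 0
    TC_POS_REGION = 1
    TC_NEG_REGION = 2
    NORMAL_REGION = 3


TUMOR_REGION_LABELS = (RegionLabel.TC_POS_REGION, RegionLabel.TC_NEG_REGION)


@dataclass(frozen=True)
class CellAnnotation:
    """A ground-truth cell: point coordinate plus one of five classes."""

    x: int
    y: int
    cls: CellClass

    def shifted(self, dx: int, dy: int) -> "CellAnnotation":
        return CellAnnotation(self.x + dx, self.y + dy, self.cls)


@dataclass
class RegionMask:
    """Dense region-label map at region scale.

    ``scale_factor`` is the ratio of cell-scale to region-scale resolution
    (default 4, i.e. 40x cell tiles against 10x region tiles).
    """

    labels: np.ndarray
    scale_factor: int = 4

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        valid = {int(v) for v in RegionLabel}
        present = set(np.unique(self.labels).tolist())
        if not present <= valid:
            raise ValueError(
                f"region mask contains labels {sorted(present - valid)} "
                f"outside the admissible set {sorted(valid)}"
            )

    def at_cell_scale(self, shape: tuple[int, int] | None = None) -> np.ndarray:
        """Nearest-neighbour upsampled label map at cell scale."""
        up = np.repeat(
            np.repeat(self.labels, self.scale_factor, axis=0),
            self.scale_factor,
            axis=1,
        )
        if shape is not None:
            up = up[: shape[0], : shape[1]]
        return up

    def tumor_mask_cell_scale(self, shape: tuple[int, int] | None = None) -> np.ndarray:
        """Boolean tumor-region mask (TC(+) or TC(-) region) at cell scale."""
        labels = self.at_cell_scale(shape)
        return np.isin(labels, [int(l) for l in TUMOR_REGION_LABELS])


# ---------------------------------------------------------------------------
# point-annotation IO
# ---------------------------------------------------------------------------

_ANNOT_HEADER = ["x", "y", "class"]


def write_annotations(annotations: Sequence[CellAnnotation], path: str | Path) -> None:
    """Write annotations as CSV with columns ``x,y,class`` (or JSON for .json)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = [{"x": a.x, "y": a.y, "class": a.cls.value} for a in annotations]
        path.write_text(json.dumps(payload, indent=1))
        return
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_ANNOT_HEADER)
        for a in annotations:
            writer.writerow([a.x, a.y, a.cls.value])


def read_annotations(path: str | Path) -> list[CellAnnotation]:
    """Read annotations from CSV (``x,y,class``) or JSON.

    Raises ``ValueError`` naming the offending row on an unknown class
    string, so bad labels never pass silently.
    """
    path = Path(path)
    out: list[CellAnnotation] = []
    if path.suffix.lower() == ".json":
        for i, row in enumerate(json.loads(path.read_text())):
            out.append(_parse_annotation(row["x"], row["y"], row["class"], i + 1, path))
        return out
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise ValueError(f"{path}: empty annotation file (missing header)")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 columns, got {len(row)}")
            out.append(_parse_annotation(row[0], row[1], row[2], lineno, path))
    return out


def _parse_annotation(x, y, cls: str, lineno: int, path: Path) -> CellAnnotation:
    try:
        klass = CellClass(str(cls).strip())
    except ValueError:
        raise ValueError(
            f"{path}: line {lineno}: unknown cell class {cls!r} "
            f"(expected one of {[c.value for c in CellClass]})"
        ) from None
    return CellAnnotation(int(x), int(y), klass)


# ---------------------------------------------------------------------------
# image / mask IO
# ---------------------------------------------------------------------------

def write_image(image: np.ndarray, path: str | Path) -> None:
    iio.imwrite(Path(path), np.asarray(image))


def read_image(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path)))


def write_region_mask(mask: RegionMask, path: str | Path) -> None:
    iio.imwrite(Path(path), mask.labels.astype(np.uint8))


def read_region_mask(path: str | Path, scale_factor: int = 4) -> RegionMask:
    return RegionMask(labels=read_image(path).astype(np.uint8), scale_factor=scale_factor)


# ---------------------------------------------------------------------------
# score tables
# ---------------------------------------------------------------------------

_SUBTYPES = {"SCC", "AD", "ADSQ"}


@dataclass(frozen=True)
class ScoreRow:
    """One case of a two-rater TPS score table."""

    case_id: str
    rater_a: float
    rater_b: float
    subtype: str | None = None


def read_score_table(path: str | Path) -> list[ScoreRow]:
    """Read a CSV score table (case_id, rater_a, rater_b[, subtype]).

    Rows with a missing rater value are rejected; scores must lie in
    [0, 100].
    """
    path = Path(path)
    rows: list[ScoreRow] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for lineno, rec in enumerate(reader, start=2):
            a, b = rec.get("rater_a", ""), rec.get("rater_b", "")
            if a in ("", None) or b in ("", None):
                raise ValueError(f"{path}: line {lineno}: missing rater value")
            a, b = float(a), float(b)
            if not (0 <= a <= 100 and 0 <= b <= 100):
                raise ValueError(f"{path}: line {lineno}: score outside [0, 100]")
            subtype = (rec.get("subtype") or "").strip() or None
            if subtype is not None and subtype not in _SUBTYPES:
                raise ValueError(f"{path}: line {lineno}: unknown subtype {subtype!r}")
            rows.append(ScoreRow(rec["case_id"], a, b, subtype))
    return rows


def write_score_table(rows: Iterable[ScoreRow], path: str | Path) -> None:
    with open(Path(path), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case_id", "rater_a", "rater_b", "subtype"])
        for r in rows:
            writer.writerow([r.case_id, r.rater_a, r.rater_b, r.subtype or ""])


# ---------------------------------------------------------------------------
# tiling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Tile:
    """One tile cut from a parent image.

    ``offset`` is the (x, y) of the tile's top-left corner in parent
    coordinates; ``pad`` is the (right, bottom) reflection-padding extent
    applied to bring edge tiles to full size.
    """

    image: np.ndarray
    offset: tuple[int, int]
    pad: tuple[int, int] = (0, 0)


def tile_image(image: np.ndarray, tile_size: int, overlap: int = 0) -> list[Tile]:
    """Cut ``image`` into overlapping tiles of ``tile_size``.

    Tiles cover the image with stride ``tile_size - overlap``; edge tiles
    are padded by reflection to full size with the pad extent recorded.
    """
    if not tile_size > overlap >= 0:
        raise ValueError("require tile_size > overlap >= 0")
    h, w = image.shape[:2]
    stride = tile_size - overlap
    if tile_size >= h and tile_size >= w:
        logger.warning(
            "tile_size %d covers the whole %dx%d image; emitting a single padded tile",
            tile_size, w, h,
        )

    def _starts(extent: int) -> list[int]:
        if extent <= tile_size:
            return [0]
        n = -(-(extent - overlap) // stride)  # ceil((extent-overlap)/stride)
        return [i * stride for i in range(n)]

    tiles: list[Tile] = []
    for y0 in _starts(h):
        for x0 in _starts(w):
            patch = image[y0 : y0 + tile_size, x0 : x0 + tile_size]
            pad_b = tile_size - patch.shape[0]
            pad_r = tile_size - patch.shape[1]
            if pad_b or pad_r:
                pad_width = [(0, pad_b), (0, pad_r)] + [(0, 0)] * (image.ndim - 2)
                patch = np.pad(patch, pad_width, mode="reflect")
            tiles.append(Tile(patch, offset=(x0, y0), pad=(pad_r, pad_b)))
    return tiles


def detections_to_parent(detections, tile: Tile):
    """Map tile-local detections into parent coordinates.

    Detections falling into the reflection-padded margin (beyond the true
    image content) are dropped: they are mirror artefacts of cells that the
    unpadded area already contains.
    """
    from .cnet import Detection  # local import to avoid a cycle

    x0, y0 = tile.offset
    h, w = tile.image.shape[:2]
    limit_x, limit_y = w - tile.pad[0], h - tile.pad[1]
    out = []
    for d in detections:
        if d.x >= limit_x or d.y >= limit_y:
            continue
        out.append(Detection(x=d.x + x0, y=d.y + y0, cls=d.cls, score=d.score))
    return out


def merge_tile_detections(per_tile, tiles: Sequence[Tile], tile_size: int,
                          dedup_radius: float = 9.0):
    """Merge per-tile detections into parent coordinates, de-duplicating
    overlap zones.

    Among same-class detections within ``dedup_radius`` of each other the
    copy whose distance to its own tile center is smaller is kept (that
    copy saw the cell with the most context).
    """
    from scipy.spatial import cKDTree

    mapped = []  # (detection, center_dist)
    for dets, tile in zip(per_tile, tiles):
        cx = tile.offset[0] + tile_size / 2.0
        cy = tile.offset[1] + tile_size / 2.0
        for d in detections_to_parent(dets, tile):
            mapped.append((d, (d.x - cx) ** 2 + (d.y - cy) ** 2))
    if not mapped:
        return []
    # keep order stable: prefer smaller tile-center distance, tie -> first
    order = sorted(range(len(mapped)), key=lambda i: (mapped[i][1], i))
    pts = np.array([[mapped[i][0].x, mapped[i][0].y] for i in order], dtype=float)
    classes = [mapped[i][0].cls for i in order]
    tree = cKDTree(pts)
    keep = np.ones(len(order), dtype=bool)
    for i in range(len(order)):
        if not keep[i]:
            continue
        for j in tree.query_ball_point(pts[i], dedup_radius):
            if j > i and classes[j] is classes[i]:
                keep[j] = False
    return [mapped[order[i]][0] for i in range(len(order)) if keep[i]]


# ---------------------------------------------------------------------------
# dataset split
# ---------------------------------------------------------------------------

def split_dataset(keys: Sequence, strata: Sequence, seed: int,
                  fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)):
    """Deterministic 60/20/20 train/val/test split, stratified.

    ``strata`` gives one hashable stratum (e.g. a planned-TPS bin) per key;
    each stratum is shuffled and cut independently so every split sees every
    stratum where counts allow.
    """
    if len(keys) != len(strata):
        raise ValueError("keys and strata must have equal length")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    groups: dict = {}
    for k, s in zip(keys, strata):
        groups.setdefault(s, []).append(k)
    train, val, test = [], [], []
    for s in sorted(groups, key=repr):
        members = groups[s]
        idx = rng.permutation(len(members))
        n = len(members)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        for pos, i in enumerate(idx):
            if pos < n_train:
                train.append(members[i])
            elif pos < n_train + n_val:
                val.append(members[i])
            else:
                test.append(members[i])
    return train, val, test
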