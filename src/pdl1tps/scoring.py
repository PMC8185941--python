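"""Clinical scores from detections: TPS, IPS, expression categories.

TPS (tumor proportion score) is the count ratio
``100 * n_TC(+) / (n_TC(+) + n_TC(-))`` — computed from cellular counts,
never from region areas, and aggregated over a slide by summing counts
across tiles before taking the ratio.  IPS (immune cell proportion score)
is the percentage of intratumoral immune cells (lymphocytes, histocytes in
tumor regions) showing membranous or cytoplasmic PD-L1 staining; immune
cell positivity is decided by the mean DAB optical density (Ruifrok–
Johnston color deconvolution) in a disk around the detection.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
from skimage.color import hdx_from_rgb

from .annotio import IMMUNE_CLASSES, CellClass
from .cnet import Detection


class ExpressionCategory(enum.Enum):
    """PD-L1 expression bins: negative (<1%), low (1-25%), moderate
    (25-50%), high (>=50%); boundaries belong to the upper bin."""

    NEGATIVE = "NEGATIVE"
    LOW = "LOW"
    MODERATE = "MODERATE"
    HIGH = "HIGH"


@dataclass
class SlideScore:
    """Counts and scores for one slide (or one tile)."""

    n_tc_pos: int
    n_tc_neg: int
    n_ic: int = 0
    n_ic_pos: int = 0
    tps: float | None = None
    ips: float | None = None
    category: ExpressionCategory | None = None
    amenable: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        d["category"] = self.category.value if self.category else None
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def categorize_tps(tps: float) -> ExpressionCategory:
    """Map a TPS percentage onto the four half-open expression bins."""
    if not 0 <= tps <= 100:
        raise ValueError(f"TPS {tps} outside [0, 100]")
    if tps < 1:
        return ExpressionCategory.NEGATIVE
    if tps < 25:
        return ExpressionCategory.LOW
    if tps < 50:
        return ExpressionCategory.MODERATE
    return ExpressionCategory.HIGH


def slide_score_from_counts(n_tc_pos: int, n_tc_neg: int,
                            n_ic: int = 0, n_ic_pos: int = 0) -> SlideScore:
    """Assemble a SlideScore from raw counts; flags instead of dividing by 0."""
    total = n_tc_pos + n_tc_neg
    if total > 0:
        tps = 100.0 * n_tc_pos / total
        return SlideScore(
            n_tc_pos=n_tc_pos, n_tc_neg=n_tc_neg, n_ic=n_ic, n_ic_pos=n_ic_pos,
            tps=tps, ips=(100.0 * n_ic_pos / n_ic if n_ic > 0 else None),
            category=categorize_tps(tps), amenable=True,
        )
    return SlideScore(
        n_tc_pos=n_tc_pos, n_tc_neg=n_tc_neg, n_ic=n_ic, n_ic_pos=n_ic_pos,
        tps=None, ips=(100.0 * n_ic_pos / n_ic if n_ic > 0 else None),
        category=None, amenable=False,
    )


def compute_tps(detections: Iterable[Detection]) -> SlideScore:
    """TPS from a detection list; non-tumor classes are ignored.

    Zero tumor cells -> ``amenable=False`` (the tile/slide is not amenable
    to image-analysis scoring), never a division by zero.
    """
    n_pos = sum(1 for d in detections if d.cls is CellClass.TC_POS)
    n_neg = sum(1 for d in detections if d.cls is CellClass.TC_NEG)
    return slide_score_from_counts(n_pos, n_neg)


# ---------------------------------------------------------------------------
# DAB optical density / immune-cell positivity
# ---------------------------------------------------------------------------

def dab_od_map(image: np.ndarray) -> np.ndarray:
    """Per-pixel DAB optical density via Ruifrok–Johnston deconvolution.

    OD is computed as ``-log10(I/255)`` per RGB channel and projected onto
    the published H-DAB stain basis; returns the DAB channel.
    """
    rgb = np.maximum(np.asarray(image, dtype=np.float64), 1.0) / 255.0
    od = -np.log10(rgb)
    conc = od @ hdx_from_rgb
    return conc[..., 1]


def ic_positivity(image: np.ndarray, detections: Sequence[Detection],
                  tumor_mask: np.ndarray, od_threshold: float = 0.15,
                  disk_radius: int = 4) -> list[tuple[Detection, bool]]:
    """Flag intratumoral immune cells as PD-L1 positive or negative.

    Only lymphocyte/histocyte detections whose center lies on a
    tumor-region pixel count as ICs.  An IC is positive iff the mean DAB
    optical density in a disk of ``disk_radius`` around its center is at
    least ``od_threshold``.
    """
    dab = dab_od_map(image)
    h, w = dab.shape
    yy, xx = np.mgrid[-disk_radius : disk_radius + 1, -disk_radius : disk_radius + 1]
    disk = (xx ** 2 + yy ** 2) <= disk_radius ** 2
    out: list[tuple[Detection, bool]] = []
    for d in detections:
        if d.cls not in IMMUNE_CLASSES:
            continue
        if not (0 <= d.y < h and 0 <= d.x < w) or not tumor_mask[d.y, d.x]:
            continue
        y0, y1 = max(0, d.y - disk_radius), min(h, d.y + disk_radius + 1)
        x0, x1 = max(0, d.x - disk_radius), min(w, d.x + disk_radius + 1)
        sub = dab[y0:y1, x0:x1]
        dsub = disk[(y0 - d.y + disk_radius):(y1 - d.y + disk_radius),
                    (x0 - d.x + disk_radius):(x1 - d.x + disk_radius)]
        out.append((d, float(sub[dsub].mean()) >= od_threshold))
    return out


def compute_ips(ic_flags: Sequence[tuple[Detection, bool]] | Sequence[bool]):
    """IPS = 100 * positive ICs / ICs; ``None`` (flag) when there are no ICs."""
    flags = [f[1] if isinstance(f, tuple) else bool(f) for f in ic_flags]
    if not flags:
        return None
    return 100.0 * sum(flags) / len(flags)


# ---------------------------------------------------------------------------
# slide aggregation
# ---------------------------------------------------------------------------

def aggregate_slide(per_tile: Sequence[SlideScore]) -> SlideScore:
    """Slide score from per-tile counts: counts are summed, then ratios
    computed — never the mean of per-tile TPS values."""
    if not per_tile:
        raise ValueError("need at least one tile")
    return slide_score_from_counts(
        n_tc_pos=sum(t.n_tc_pos for t in per_tile),
        n_tc_neg=sum(t.n_tc_neg for t in per_tile),
        n_ic=sum(t.n_ic for t in per_tile),
        n_ic_pos=sum(t.n_ic_pos for t in per_tile),
    )


def score_from_annotations(annotations, tumor_mask: np.ndarray | None = None,
                           positive_flags: Sequence[bool] | None = None) -> SlideScore:
    """Ground-truth scoring: SlideScore directly from point annotations.

    Tumor cells are counted by class; immune cells are counted as ICs when
    ``tumor_mask`` marks their center (all of them when no mask is given).
    ``positive_flags``, when given, pairs with the annotations to mark
    PD-L1-positive ICs.
    """
    n_pos = sum(1 for a in annotations if a.cls is CellClass.TC_POS)
    n_neg = sum(1 for a in annotations if a.cls is CellClass.TC_NEG)
    n_ic = n_ic_pos = 0
    for i, a in enumerate(annotations):
        if a.cls not in IMMUNE_CLASSES:
            continue
        if tumor_mask is not None and not tumor_mask[a.y, a.x]:
            continue
        n_ic += 1
        if positive_flags is not None and positive_flags[i]:
            n_ic_pos += 1
    return slide_score_from_counts(n_pos, n_neg, n_ic, n_ic_pos)
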