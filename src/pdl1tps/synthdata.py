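"""Synthetic bright-field IHC tile generator with exact ground truth.

Stands in for proprietary PD-L1–stained NSCLC slides.  Each tile carries

* an RGB image rendered by linear mixing of the Ruifrok–Johnston
  hematoxylin and DAB stain vectors in optical-density space plus Gaussian
  pixel noise, so downstream color deconvolution is exercised honestly;
* point annotations for five cell classes — PD-L1–positive tumor cells
  (brown membranous ring around a blue nucleus), negative tumor cells
  (blue nucleus only), lymphocytes (small, round, dark; diffuse brown
  cytoplasm when PD-L1 positive), histocytes (larger, irregular, pale;
  membranous-style brown staining when PD-L1 positive — the cell-scale
  lookalike of TC(+) that regional context must disambiguate), and
  fibrocytes (elongated, stromal);
* a region label mask at 1/4 linear resolution (nest-shaped tumor regions,
  split into TC(+)/TC(-) sub-regions, against stroma and background);
* the planned slide truth (TC counts, TPS, IPS) realized *exactly*:
  round(n_tumor_cells * planned_tps / 100) cells are generated TC(+).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .annotio import (
    CellAnnotation,
    CellClass,
    RegionLabel,
    RegionMask,
    write_annotations,
    write_image,
    write_region_mask,
)

# Ruifrok–Johnston stain OD vectors (rows: hematoxylin, DAB, residual),
# identical to scikit-image's rgb_from_hdx so that deconvolution in the
# scoring module sees exactly this basis.
RGB_FROM_HDX = np.array(
    [
        [0.650, 0.704, 0.286],
        [0.268, 0.570, 0.776],
        [0.383284, -0.427752, 0.181828],
    ]
)


class PackingError(RuntimeError):
    """Raised when the requested cells cannot be packed into the tile."""


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic tile.

    The planned TPS/IPS are realized exactly by construction, not sampled:
    ``round(n_tumor_cells * planned_tps / 100)`` cells are rendered TC(+)
    and ``round(n_immune_cells * planned_ips / 100)`` intratumoral immune
    cells are rendered PD-L1 positive.
    """

    tile_width: int = 128
    tile_height: int = 128
    planned_tps: float = 50.0          # percent of tumor cells PD-L1(+)
    planned_ips: float = 25.0          # percent of intratumoral ICs PD-L1(+)
    n_tumor_cells: int = 40
    n_immune_cells: int = 8
    n_fibrocytes: int = 5
    n_stromal_histocytes: int = 0      # DAB(+) confounders placed in stroma
    tumor_area_fraction: float = 0.6
    stain_noise_sd: float = 3.0        # Gaussian noise SD on the 8-bit image
    seed: int = 0
    # geometry (pixels at cell scale, nominal 40x)
    nucleus_radius: tuple[float, float] = (4.0, 5.0)
    membrane_px: float = 2.0
    min_separation: float = 10.0
    adjacent_fraction: float = 0.15    # fraction of tumor cells in close pairs
    adjacent_separation_factor: float = 0.8  # x nuclear diameter
    region_scale: int = 4              # cell-scale px per region-scale px

    def validate(self) -> None:
        if not (0 <= self.planned_tps <= 100 and 0 <= self.planned_ips <= 100):
            raise ValueError("planned_tps / planned_ips must lie in [0, 100]")
        if min(self.n_tumor_cells, self.n_immune_cells, self.n_fibrocytes,
               self.n_stromal_histocytes) < 0:
            raise ValueError("cell counts must be >= 0")
        if not 0 <= self.tumor_area_fraction <= 1:
            raise ValueError("tumor_area_fraction must lie in [0, 1]")
        if self.stain_noise_sd < 0:
            raise ValueError("stain_noise_sd must be >= 0")
        if self.planned_tps > 0 and self.n_tumor_cells < 1:
            raise ValueError("planned_tps > 0 requires n_tumor_cells >= 1")


@dataclass
class SynthTile:
    """A rendered tile with its exact ground truth."""

    image: np.ndarray                  # (H, W, 3) uint8
    annotations: list[CellAnnotation]
    region_mask: RegionMask
    truth: "SlideScore"                # noqa: F821 — scoring.SlideScore
    spec: SynthSpec


# ---------------------------------------------------------------------------
# region geometry
# ---------------------------------------------------------------------------

def _region_labels(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    """Nest-shaped region label map at region scale.

    Two independent smoothed Gaussian fields are thresholded at quantiles:
    the first carves tumor tissue (exactly ``tumor_area_fraction`` of the
    tile) and a small background margin, the second splits the tumor area
    into TC(+) / TC(-) sub-regions in the planned TPS proportion.
    """
    rh = spec.tile_height // spec.region_scale
    rw = spec.tile_width // spec.region_scale
    f1 = ndimage.gaussian_filter(rng.standard_normal((rh, rw)), sigma=max(rh, rw) / 8)
    f2 = ndimage.gaussian_filter(rng.standard_normal((rh, rw)), sigma=max(rh, rw) / 8)

    labels = np.full((rh, rw), int(RegionLabel.NORMAL_REGION), dtype=np.uint8)
    taf = spec.tumor_area_fraction
    if taf > 0:
        tumor = f1 >= np.quantile(f1, 1.0 - taf)
    else:
        tumor = np.zeros_like(f1, dtype=bool)
    # a sliver of bare glass in the non-tumor remainder
    if taf < 1:
        bg = (~tumor) & (f1 <= np.quantile(f1[~tumor], 0.08))
        labels[bg] = int(RegionLabel.BACKGROUND)

    if tumor.any():
        pos_frac = spec.planned_tps / 100.0
        if pos_frac >= 1.0:
            pos = tumor
        elif pos_frac <= 0.0:
            pos = np.zeros_like(tumor)
        else:
            thr = np.quantile(f2[tumor], 1.0 - pos_frac)
            pos = tumor & (f2 >= thr)
        labels[tumor & pos] = int(RegionLabel.TC_POS_REGION)
        labels[tumor & ~pos] = int(RegionLabel.TC_NEG_REGION)
    return labels


# ---------------------------------------------------------------------------
# cell placement
# ---------------------------------------------------------------------------

_MAX_TRIES = 400


def _sample_point(allowed_yx: np.ndarray, rng: np.random.Generator) -> tuple[int, int]:
    i = int(rng.integers(len(allowed_yx)))
    return int(allowed_yx[i, 1]), int(allowed_yx[i, 0])  # (x, y)


def _place_cells(spec: SynthSpec, cell_mask: np.ndarray, n: int,
                 placed: list[tuple[float, float]], rng: np.random.Generator,
                 n_adjacent_pairs: int = 0,
                 clearance: tuple[list[tuple[float, float]], float] | None = None,
                 ) -> list[tuple[int, int]]:
    """Dart-throwing placement of ``n`` centers inside ``cell_mask``.

    All centers respect ``min_separation`` against every previously placed
    cell, except deliberately adjacent pairs whose two members sit at
    ``adjacent_separation_factor`` x nuclear diameter from each other.
    ``clearance`` imposes a larger exclusion radius around specific points
    (e.g. immune cells kept clear of tumor-cell membrane rings so their
    own stain, not a neighbour's, decides their measured positivity).
    Raises :class:`PackingError` instead of silently truncating.
    """
    allowed = np.argwhere(cell_mask)
    if n > 0 and len(allowed) == 0:
        raise PackingError("no admissible pixels for requested cells")
    sep2 = spec.min_separation ** 2
    clear_pts, clear2 = ([], 0.0)
    if clearance is not None:
        clear_pts, cd = clearance
        clear2 = cd ** 2
    mean_diam = sum(spec.nucleus_radius)  # 2 * mean radius
    pair_dist = spec.adjacent_separation_factor * mean_diam

    out: list[tuple[int, int]] = []
    h, w = cell_mask.shape
    pairs_left = n_adjacent_pairs
    i = 0
    while i < n:
        make_pair = pairs_left > 0 and i + 1 < n
        found = False
        for attempt in range(2 * _MAX_TRIES):
            x, y = _sample_point(allowed, rng)
            if not all((x - px) ** 2 + (y - py) ** 2 >= sep2 for px, py in placed):
                continue
            # clearance is best-effort: after _MAX_TRIES fall back to the
            # plain separation rule (dense tiles, e.g. TPS ~100, leave no
            # membrane-free spots)
            if attempt >= _MAX_TRIES or all(
                    (x - px) ** 2 + (y - py) ** 2 >= clear2 for px, py in clear_pts):
                found = True
                break
        if not found:
            raise PackingError(
                f"could not place cell {len(placed) + 1} after {2 * _MAX_TRIES} "
                "tries; tile too crowded for the requested cell counts"
            )
        out.append((x, y))
        placed.append((float(x), float(y)))
        i += 1
        if make_pair:
            # partner at pair_dist, exempt from the separation rule w.r.t. its mate
            for attempt in range(_MAX_TRIES):
                ang = rng.uniform(0, 2 * np.pi)
                qx = int(round(x + pair_dist * np.cos(ang)))
                qy = int(round(y + pair_dist * np.sin(ang)))
                if not (0 <= qx < w and 0 <= qy < h and cell_mask[qy, qx]):
                    continue
                ok = all(
                    (qx - px) ** 2 + (qy - py) ** 2 >= sep2
                    for px, py in placed[:-1]  # everyone but the mate
                )
                if ok:
                    out.append((qx, qy))
                    placed.append((float(qx), float(qy)))
                    i += 1
                    pairs_left -= 1
                    break
            else:
                pairs_left -= 1  # give up on this pair, keep the lone cell
    return out


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _paint_ellipse(buf: np.ndarray, cx: float, cy: float, ry: float, rx: float,
                   angle: float, value: float) -> None:
    """Add an anti-aliased filled ellipse to a concentration map."""
    h, w = buf.shape
    r = max(ry, rx) + 1.5
    x0, x1 = max(0, int(cx - r)), min(w, int(cx + r) + 2)
    y0, y1 = max(0, int(cy - r)), min(h, int(cy + r) + 2)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - cx, yy - cy
    ca, sa = np.cos(angle), np.sin(angle)
    u = (dx * ca + dy * sa) / rx
    v = (-dx * sa + dy * ca) / ry
    d = np.sqrt(u * u + v * v)
    cover = np.clip((1.0 - d) * min(rx, ry) + 0.5, 0.0, 1.0)  # ~1 px soft edge
    buf[y0:y1, x0:x1] += value * cover


def _paint_ring(buf: np.ndarray, cx: float, cy: float, radius: float,
                width: float, value: float) -> None:
    """Add an anti-aliased circular ring (membranous staining)."""
    h, w = buf.shape
    r = radius + width + 1.5
    x0, x1 = max(0, int(cx - r)), min(w, int(cx + r) + 2)
    y0, y1 = max(0, int(cy - r)), min(h, int(cy + r) + 2)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
    cover = np.clip(width / 2.0 - np.abs(d - radius) + 0.5, 0.0, 1.0)
    buf[y0:y1, x0:x1] += value * cover


def _render(spec: SynthSpec, cells, region_up: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    """Render the tile: stain concentration maps -> OD -> RGB."""
    h, w = spec.tile_height, spec.tile_width
    conc_h = np.zeros((h, w), dtype=np.float64)
    conc_d = np.zeros((h, w), dtype=np.float64)

    # faint tissue washes: tumor cytoplasm is bluish, TC(+) regions carry a
    # light diffuse DAB tint, stroma is paler — the low-magnification cues
    # the region segmenter keys on
    tumor = np.isin(region_up, (int(RegionLabel.TC_POS_REGION),
                                int(RegionLabel.TC_NEG_REGION)))
    stroma = region_up == int(RegionLabel.NORMAL_REGION)
    conc_h += ndimage.gaussian_filter(tumor * 0.20 + stroma * 0.08, 2.0)
    conc_d += ndimage.gaussian_filter(
        (region_up == int(RegionLabel.TC_POS_REGION)) * 0.05, 2.0)

    rmin, rmax = spec.nucleus_radius
    for (x, y), cls, positive in cells:
        if cls in (CellClass.TC_POS, CellClass.TC_NEG):
            r = rng.uniform(rmin, rmax)
            _paint_ellipse(conc_h, x, y, r, r * rng.uniform(0.85, 1.0),
                           rng.uniform(0, np.pi), 1.0)
            if cls is CellClass.TC_POS:
                _paint_ring(conc_d, x, y, r + spec.membrane_px,
                            spec.membrane_px, 0.9)
        elif cls is CellClass.LYMPHOCYTE:
            r = rng.uniform(0.55 * rmin, 0.7 * rmin)
            _paint_ellipse(conc_h, x, y, r, r, 0.0, 1.4)
            if positive:
                _paint_ellipse(conc_d, x, y, r + 2.5, r + 2.5, 0.0, 0.45)
        elif cls is CellClass.HISTOCYTE:
            r = rng.uniform(rmin, 1.2 * rmax)
            _paint_ellipse(conc_h, x, y, r, r * rng.uniform(0.55, 0.75),
                           rng.uniform(0, np.pi), 0.65)
            if positive:
                # PD-L1(+) histocytes show membranous staining too — the
                # cell-level lookalike of TC(+) that regional context must
                # disambiguate
                _paint_ring(conc_d, x, y, r + 1.5, 1.5, 0.7)
                _paint_ellipse(conc_d, x, y, r + 2.0, r + 2.0, 0.0, 0.35)
        elif cls is CellClass.FIBROCYTE:
            r = rng.uniform(0.35 * rmin, 0.5 * rmin)
            _paint_ellipse(conc_h, x, y, r, r * rng.uniform(3.5, 4.5),
                           rng.uniform(0, np.pi), 0.9)

    od = (np.stack([conc_h, conc_d, np.zeros_like(conc_h)], axis=-1)
          @ RGB_FROM_HDX)
    rgb = 255.0 * np.power(10.0, -od)
    if spec.stain_noise_sd > 0:
        rgb = rgb + rng.normal(0.0, spec.stain_noise_sd, rgb.shape)
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def simulate_tile(spec: SynthSpec) -> SynthTile:
    """Generate one synthetic IHC tile; bit-identical for a fixed seed."""
    from .scoring import slide_score_from_counts  # late import, no cycle

    spec.validate()
    rng = np.random.default_rng(spec.seed)

    region = _region_labels(spec, rng)
    mask = RegionMask(labels=region, scale_factor=spec.region_scale)
    up = mask.at_cell_scale((spec.tile_height, spec.tile_width))

    n_pos = int(round(spec.n_tumor_cells * spec.planned_tps / 100.0))
    n_neg = spec.n_tumor_cells - n_pos
    n_ic_pos = int(round(spec.n_immune_cells * spec.planned_ips / 100.0))

    pos_mask = up == int(RegionLabel.TC_POS_REGION)
    neg_mask = up == int(RegionLabel.TC_NEG_REGION)
    tumor_mask = pos_mask | neg_mask
    stroma_mask = up == int(RegionLabel.NORMAL_REGION)
    if n_pos > 0 and not pos_mask.any():
        raise PackingError("planned TPS > 0 but no TC(+) region was generated")

    placed: list[tuple[float, float]] = []
    n_pairs_pos = int(round(spec.adjacent_fraction * n_pos / 2.0))
    n_pairs_neg = int(round(spec.adjacent_fraction * n_neg / 2.0))
    pos_pts = _place_cells(spec, pos_mask, n_pos, placed, rng, n_pairs_pos)
    neg_pts = _place_cells(spec, neg_mask, n_neg, placed, rng, n_pairs_neg)
    # keep ICs clear of TC(+) membrane rings: ring radius + measurement disk
    ic_clear = max(spec.nucleus_radius) + 2 * spec.membrane_px + 5.0
    ic_pts = _place_cells(spec, tumor_mask, spec.n_immune_cells, placed, rng,
                          clearance=([(float(x), float(y)) for x, y in pos_pts],
                                     ic_clear))
    fib_pts = _place_cells(spec, stroma_mask, spec.n_fibrocytes, placed, rng)
    sh_pts = _place_cells(spec, stroma_mask, spec.n_stromal_histocytes, placed, rng)

    cells: list[tuple[tuple[int, int], CellClass, bool]] = []
    cells += [(p, CellClass.TC_POS, True) for p in pos_pts]
    cells += [(p, CellClass.TC_NEG, False) for p in neg_pts]
    for i, p in enumerate(ic_pts):
        cls = CellClass.LYMPHOCYTE if rng.random() < 0.6 else CellClass.HISTOCYTE
        cells.append((p, cls, i < n_ic_pos))
    cells += [(p, CellClass.FIBROCYTE, False) for p in fib_pts]
    cells += [(p, CellClass.HISTOCYTE, True) for p in sh_pts]  # stromal DAB(+)

    image = _render(spec, cells, up, rng)
    annotations = [CellAnnotation(x=p[0], y=p[1], cls=c) for p, c, _ in cells]

    truth = slide_score_from_counts(
        n_tc_pos=n_pos, n_tc_neg=n_neg,
        n_ic=spec.n_immune_cells, n_ic_pos=n_ic_pos,
    )
    return SynthTile(image=image, annotations=annotations,
                     region_mask=mask, truth=truth, spec=spec)


def simulate_slide(spec_list: Sequence[SynthSpec]):
    """Generate a multi-tile synthetic slide.

    Slide-level truth counts are the sums of tile counts and the slide TPS
    is recomputed from the summed counts — never the mean of per-tile TPS.
    """
    from .scoring import slide_score_from_counts

    if not spec_list:
        raise ValueError("spec_list must be non-empty")
    tiles = [simulate_tile(s) for s in spec_list]
    truth = slide_score_from_counts(
        n_tc_pos=sum(t.truth.n_tc_pos for t in tiles),
        n_tc_neg=sum(t.truth.n_tc_neg for t in tiles),
        n_ic=sum(t.truth.n_ic for t in tiles),
        n_ic_pos=sum(t.truth.n_ic_pos for t in tiles),
    )
    return tiles, truth


def write_tile(tile: SynthTile, outdir: str | Path, stem: str) -> None:
    """Materialize one tile: PNG image, CSV+JSON annotations, mask, truth."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_image(tile.image, outdir / f"{stem}.png")
    write_annotations(tile.annotations, outdir / f"{stem}.annotations.csv")
    write_annotations(tile.annotations, outdir / f"{stem}.annotations.json")
    write_region_mask(tile.region_mask, outdir / f"{stem}.mask.png")
    (outdir / f"{stem}.truth.json").write_text(json.dumps(tile.truth.to_dict(), indent=1))
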