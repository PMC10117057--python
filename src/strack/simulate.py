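"""Synthetic monolayer microcolonies of elongating, dividing rod cells.

The generator grows spherocylindrical (rod) cells on a 2-D plane the way
surface-attached bacteria grow in a single focal layer: each cell elongates
along its long axis at a constant rate, divides at its midpoint when it
reaches a (slightly cell-specific) threshold length, and shoves its
neighbours aside so the colony stays a monolayer.  Every frame is rendered
to a labeled mask and every true mother→daughter relation is recorded, so a
tracker can be scored against exact ground truth without any real imagery.

What it does *not* emulate: phase-contrast optics, segmentation errors,
cell motility, curved or branched morphologies, or out-of-plane growth.

All randomness comes from one seeded generator, drawn in a fixed order
(founder placement → per-division axis noise and threshold noise → per-cell
jitter, frame by frame), so one seed gives bit-identical masks and links.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .masks import LabeledMask
from .tracking import TrackLink

logger = logging.getLogger(__name__)

__all__ = ["ColonyParams", "GroundTruth", "simulate_colony", "render_rod", "write_ground_truth"]

TRUTH = "truth"


@dataclass(frozen=True)
class ColonyParams:
    """Growth and imaging parameters of a simulated microcolony.

    Lengths are tip-to-tip in pixels; rates are pixels per frame.  Defaults
    emulate a ~0.5 µm-wide rod imaged at high magnification (≈14 px/µm) and
    a frame interval short enough that a cell doubles over about three
    frames, as slow-growing soil isolates do when imaged every 10–20 min.
    Faster per-frame growth makes the colony shove its members sideways by
    several pixels per frame, which is the regime where neighbour swaps
    defeat any overlap-based tracker.
    """

    image_size: tuple[int, int] = (256, 256)
    n_founders: int = 2
    rod_width: float = 7.0
    initial_length: float = 18.0
    elongation_rate: float = 6.0
    division_length: float = 36.0
    division_axis_noise_deg: float = 10.0
    jitter_px: float = 1.0
    n_frames: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 1:
            raise ValueError("n_founders must be >= 1")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not self.division_length > self.initial_length:
            raise ValueError("division_length must exceed initial_length")
        if not self.rod_width < self.initial_length:
            raise ValueError("rod_width must be smaller than initial_length")
        for name in ("elongation_rate", "division_axis_noise_deg", "jitter_px"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Rendered mask series plus the true mother→daughter edges."""

    masks: list[LabeledMask]
    links: frozenset[TrackLink]
    params: ColonyParams


@dataclass
class _Cell:
    uid: int
    center: np.ndarray  # (x, y)
    orientation_deg: float
    length: float
    div_length: float
    born_frame: int


def render_rod(
    center: tuple[float, float],
    orientation_deg: float,
    length: float,
    width: float,
    grid_shape: tuple[int, int],
) -> set[tuple[int, int]]:
    """Rasterize a spherocylinder (rectangle with semicircular caps).

    A pixel (row, col) is included when its center lies within ``width/2``
    of the rod's central segment; ``length`` is tip to tip, so
    ``length == width`` degenerates to a disk.
    """
    if not length >= width or width <= 0:
        raise ValueError("need length >= width > 0")
    h, w = grid_shape
    cx, cy = center
    half = (length - width) / 2.0
    rad = math.radians(orientation_deg)
    ux, uy = math.cos(rad), math.sin(rad)
    ax, ay = cx - half * ux, cy - half * uy
    bx, by = cx + half * ux, cy + half * uy
    r = width / 2.0
    r0 = max(0, int(math.floor(min(ay, by) - r)))
    r1 = min(h - 1, int(math.ceil(max(ay, by) + r)))
    c0 = max(0, int(math.floor(min(ax, bx) - r)))
    c1 = min(w - 1, int(math.ceil(max(ax, bx) + r)))
    if r0 > r1 or c0 > c1:
        return set()
    rows, cols = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    px, py = cols.astype(float), rows.astype(float)
    # distance from pixel centers to the segment a-b
    seg2 = half * half * 4.0
    if seg2 == 0.0:
        dist2 = (px - ax) ** 2 + (py - ay) ** 2
    else:
        t = np.clip(((px - ax) * (bx - ax) + (py - ay) * (by - ay)) / seg2, 0.0, 1.0)
        dist2 = (px - (ax + t * (bx - ax))) ** 2 + (py - (ay + t * (by - ay))) ** 2
    inside = dist2 <= r * r
    return {(int(r_), int(c_)) for r_, c_ in zip(rows[inside], cols[inside])}


def _segment_endpoints(cells: list[_Cell], width: float) -> tuple[np.ndarray, np.ndarray]:
    centers = np.array([c.center for c in cells], dtype=float)
    ang = np.radians([c.orientation_deg for c in cells])
    half = np.maximum(np.array([c.length for c in cells]) - width, 0.0) / 2.0
    axis = np.column_stack([np.cos(ang), np.sin(ang)])
    return centers - axis * half[:, None], centers + axis * half[:, None]


def _segment_pair_closest(p1, q1, p2, q2):
    """Closest points between segment pairs (vectorized clamped solver)."""
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = np.einsum("ij,ij->i", d1, d1)
    e = np.einsum("ij,ij->i", d2, d2)
    f = np.einsum("ij,ij->i", d2, r)
    c = np.einsum("ij,ij->i", d1, r)
    b = np.einsum("ij,ij->i", d1, d2)
    denom = a * e - b * b
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(denom > 1e-12, np.clip((b * f - c * e) / np.where(denom > 1e-12, denom, 1.0), 0.0, 1.0), 0.0)
        t = np.where(e > 1e-12, (b * s + f) / np.where(e > 1e-12, e, 1.0), 0.0)
        s_lo = np.where(a > 1e-12, np.clip(-c / np.where(a > 1e-12, a, 1.0), 0.0, 1.0), 0.0)
        s_hi = np.where(a > 1e-12, np.clip((b - c) / np.where(a > 1e-12, a, 1.0), 0.0, 1.0), 0.0)
    s = np.where(t < 0.0, s_lo, np.where(t > 1.0, s_hi, s))
    t = np.clip(t, 0.0, 1.0)
    return p1 + d1 * s[:, None], p2 + d2 * t[:, None]


def _relax(cells: list[_Cell], width: float, max_iter: int = 200, margin: float = 0.5) -> None:
    """Push overlapping spherocylinders apart along their closest-point line.

    Simple pairwise repulsion, not mechanics: each overlapping pair is
    separated by half the deficit on each side, iterated until all outlines
    are disjoint or ``max_iter`` is hit (then accepted with a warning).
    """
    n = len(cells)
    if n < 2:
        return
    target = width + margin
    ii, jj = np.triu_indices(n, k=1)
    for _ in range(max_iter):
        p, q = _segment_endpoints(cells, width)
        c1, c2 = _segment_pair_closest(p[ii], q[ii], p[jj], q[jj])
        delta = c2 - c1
        dist = np.hypot(delta[:, 0], delta[:, 1])
        overlapping = (target - dist) > 1e-6  # tolerance: exact contacts are fine
        if not overlapping.any():
            return
        # accumulate all pushes against the current geometry, then apply at
        # once: per-pair sequential updates against stale closest points
        # oscillate in crowded colonies
        disp = np.zeros((n, 2))
        for k in np.flatnonzero(overlapping):
            i, j = int(ii[k]), int(jj[k])
            d = dist[k]
            if d > 1e-9:
                nvec = delta[k] / d
            else:
                cvec = cells[j].center - cells[i].center
                cn = math.hypot(*cvec)
                nvec = cvec / cn if cn > 1e-9 else np.array([1.0, 0.0])
            push = 0.5 * (target - d)
            disp[i] -= nvec * push
            disp[j] += nvec * push
        for i, cell in enumerate(cells):
            cell.center = cell.center + disp[i]
    logger.warning("relaxation did not fully separate %d cells after %d iterations", n, max_iter)


def _render_frame(
    cells: list[_Cell], params: ColonyParams, frame: int
) -> tuple[LabeledMask, dict[int, int], list[int]]:
    """Render cells (uid order) to a mask; returns uid→label and dropped uids."""
    grid = np.zeros(params.image_size, dtype=np.uint16)
    uid_to_label = {}
    dropped = []
    label = 0
    for cell in sorted(cells, key=lambda c: c.uid):
        pixels = render_rod(
            tuple(cell.center), cell.orientation_deg, cell.length, params.rod_width, params.image_size
        )
        pixels = {(r, c) for r, c in pixels if grid[r, c] == 0}
        if not pixels:
            dropped.append(cell.uid)
            continue
        label += 1
        rows, cols = zip(*pixels)
        grid[rows, cols] = label
        uid_to_label[cell.uid] = label
    mask = LabeledMask(frame_index=frame, grid=grid, source_name=f"sim_t{frame:04d}")
    return mask, uid_to_label, dropped


def simulate_colony(params: ColonyParams) -> GroundTruth:
    """Grow a colony for ``n_frames`` frames and return masks + true links.

    Per frame: every cell elongates; any cell over its division threshold
    splits at its midpoint into two half-length daughters along the mother
    axis perturbed by up to ``division_axis_noise_deg``; surviving cells
    jitter by up to ``jitter_px`` (newborns keep their birth geometry that
    frame); overlaps are relaxed away; cells rendered fully outside the
    image are dropped and their tracks end.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_size
    margin = params.division_length
    cells: list[_Cell] = []
    next_uid = 0
    for _ in range(params.n_founders):
        center = np.array([
            rng.uniform(margin, w - margin) if w > 2 * margin else w / 2.0,
            rng.uniform(margin, h - margin) if h > 2 * margin else h / 2.0,
        ])
        # founders start desynchronized, partway through their cycles
        hi = max(params.initial_length, 0.85 * params.division_length)
        length = rng.uniform(params.initial_length, hi)
        cells.append(
            _Cell(
                uid=next_uid,
                center=center,
                orientation_deg=rng.uniform(0.0, 180.0),
                length=max(length, params.rod_width),
                div_length=params.division_length * (1.0 + rng.uniform(-0.08, 0.08)),
                born_frame=0,
            )
        )
        next_uid += 1
    _relax(cells, params.rod_width)
    mask0, labels_prev, dropped = _render_frame(cells, params, 0)
    cells = [c for c in cells if c.uid not in dropped]
    masks = [mask0]
    links: set[TrackLink] = set()
    parent_of: dict[int, int] = {}

    for t in range(1, params.n_frames):
        for cell in cells:
            cell.length += params.elongation_rate
        newborn: list[_Cell] = []
        survivors: list[_Cell] = []
        for cell in cells:
            if cell.length >= cell.div_length and cell.length / 2.0 >= params.rod_width:
                delta = rng.uniform(-params.division_axis_noise_deg, params.division_axis_noise_deg)
                axis_deg = cell.orientation_deg + delta
                rad = math.radians(axis_deg)
                axis = np.array([math.cos(rad), math.sin(rad)])
                dlen = cell.length / 2.0 - 0.5
                for sign in (-1.0, 1.0):
                    daughter = _Cell(
                        uid=next_uid,
                        center=cell.center + sign * (cell.length / 4.0) * axis,
                        orientation_deg=axis_deg % 180.0,
                        length=dlen,
                        div_length=params.division_length * (1.0 + rng.uniform(-0.08, 0.08)),
                        born_frame=t,
                    )
                    parent_of[daughter.uid] = cell.uid
                    newborn.append(daughter)
                    next_uid += 1
            else:
                survivors.append(cell)
        cells = survivors + newborn
        for cell in cells:
            if cell.born_frame == t:
                continue
            theta = rng.uniform(0.0, 2.0 * math.pi)
            mag = rng.uniform(0.0, params.jitter_px)
            cell.center = cell.center + mag * np.array([math.cos(theta), math.sin(theta)])
        _relax(cells, params.rod_width)
        mask, labels_now, dropped = _render_frame(cells, params, t)
        cells = [c for c in cells if c.uid not in dropped]
        for uid, label in labels_now.items():
            if uid in labels_prev:
                mother_uid = uid
            elif parent_of.get(uid) in labels_prev:
                mother_uid = parent_of[uid]
            else:
                continue  # entered from nowhere: does not happen in practice
            links.add(
                TrackLink(
                    mother=(t - 1, labels_prev[mother_uid]),
                    daughter=(t, label),
                    method=TRUTH,
                )
            )
        masks.append(mask)
        labels_prev = labels_now
    return GroundTruth(masks=masks, links=frozenset(links), params=params)


def write_ground_truth(gt: GroundTruth, out_dir: str | Path) -> tuple[list[Path], Path]:
    """Write mask TIFFs plus the true edge table (evaluation-reader schema)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mask_paths = []
    for mask in gt.masks:
        path = out / f"mask_t{mask.frame_index:04d}.tif"
        tifffile.imwrite(path, mask.grid)
        mask_paths.append(path)
    rows = [
        {
            "mother_frame": l.mother[0],
            "mother_label": l.mother[1],
            "daughter_frame": l.daughter[0],
            "daughter_label": l.daughter[1],
            "link_method": l.method,
        }
        for l in sorted(gt.links, key=lambda l: (l.daughter, l.mother))
    ]
    csv_path = out / "ground_truth_tracks.csv"
    pd.DataFrame(
        rows,
        columns=["mother_frame", "mother_label", "daughter_frame", "daughter_label", "link_method"],
    ).to_csv(csv_path, index=False)
    return mask_paths, csv_path
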