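"""Track-overlay images and lineage-tree figures.

Overlays reproduce the visual-checking convention of the tracker's image
output: the mask rendered light-on-dark with one red line per assigned
link, drawn from the mother's centroid (previous-frame coordinates) to the
daughter's centroid in the current frame.  Lineage trees put time on the
vertical axis, one leaf slot per final cell, and can color edges by
agreement with a reference tracking (gray = match, red = mismatch).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from skimage.draw import line as _draw_line

from .lineage import LineageForest
from .masks import CellRegion, LabeledMask, extract_regions
from .tracking import TrackLink

__all__ = ["render_overlay", "save_overlays", "render_lineage_tree"]

_RED = np.array([255, 0, 0], dtype=np.uint8)
_CELL_GRAY = 200


def render_overlay(
    mask: LabeledMask,
    incoming_links: Sequence[TrackLink],
    prev_regions: Sequence[CellRegion],
    regions: Optional[Sequence[CellRegion]] = None,
) -> np.ndarray:
    """RGB image of one frame's mask with red mother→daughter track lines.

    ``incoming_links`` are the links whose daughters live in this mask;
    new-track marks draw nothing.
    """
    if regions is None:
        regions = extract_regions(mask, warn_disconnected=False)
    rgb = np.zeros((mask.height, mask.width, 3), dtype=np.uint8)
    rgb[mask.grid > 0] = _CELL_GRAY
    prev_centroid = {r.label: r.centroid for r in prev_regions}
    centroid = {r.label: r.centroid for r in regions}
    for link in incoming_links:
        if link.is_new_track:
            continue
        mx, my = prev_centroid[link.mother[1]]
        dx, dy = centroid[link.daughter[1]]
        rr, cc = _draw_line(int(round(my)), int(round(mx)), int(round(dy)), int(round(dx)))
        keep = (rr >= 0) & (rr < mask.height) & (cc >= 0) & (cc < mask.width)
        rgb[rr[keep], cc[keep]] = _RED
    return rgb


def save_overlays(
    masks: Sequence[LabeledMask],
    forest: LineageForest,
    out_dir: str | Path,
    regions: Optional[Sequence[Sequence[CellRegion]]] = None,
) -> list[Path]:
    """Write one ``overlay_t{frame:04d}.png`` per frame (frame 0 has no lines)."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if regions is None:
        regions = [extract_regions(m, warn_disconnected=False) for m in masks]
    paths = []
    for t, mask in enumerate(masks):
        incoming = [l for l in forest.links if l.daughter[0] == t]
        prev = regions[t - 1] if t > 0 else []
        rgb = render_overlay(mask, incoming, prev, regions[t])
        path = out / f"overlay_t{t:04d}.png"
        iio.imwrite(path, rgb)
        paths.append(path)
    return paths


def _subtree_layout(forest: LineageForest, cell, x_positions, next_slot):
    kids = forest.children(cell)
    if not kids:
        x_positions[cell] = next_slot[0]
        next_slot[0] += 1.0
        return x_positions[cell]
    xs = [_subtree_layout(forest, k, x_positions, next_slot) for k in kids]
    x_positions[cell] = sum(xs) / len(xs)
    return x_positions[cell]


def render_lineage_tree(
    forest: LineageForest,
    mismatches: Optional[Iterable[TrackLink]] = None,
    ax=None,
):
    """Plot the lineage forest with time running downward.

    Leaves get consecutive horizontal slots (roots ordered by track ID,
    children by label), internal cells sit over the mean of their children,
    so identical forests always render identically.  When ``mismatches`` is
    given, those edges are drawn red and the rest gray.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 5))
    mismatch_keys = set()
    if mismatches is not None:
        mismatch_keys = {l.edge_key for l in mismatches if not l.is_new_track}
    x_positions: dict = {}
    next_slot = [0.0]
    for root in sorted(forest.roots, key=lambda c: (forest.track_id[c], c)):
        _subtree_layout(forest, root, x_positions, next_slot)
    for link in forest.edges:
        color = "red" if link.edge_key in mismatch_keys else "0.5"
        x0, x1 = x_positions[link.mother], x_positions[link.daughter]
        y0, y1 = link.mother[0], link.daughter[0]
        ax.plot([x0, x1], [y0, y1], color=color, linewidth=1.2)
    for cell, x in x_positions.items():
        ax.plot([x], [cell[0]], marker="o", markersize=2, color="0.3")
    ax.invert_yaxis()
    ax.set_ylabel("time point")
    ax.set_xticks([])
    ax.figure.tight_layout()
    return ax.figure
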