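"""Reading and validating labeled-mask series and extracting per-cell geometry.

A *labeled mask* is a 2-D integer image in which background pixels are 0 and
each segmented cell carries a distinct positive label.  A time-lapse series is
a directory of such images, one per time point, ordered lexicographically by
filename.  Segmentation itself happens upstream; this module only consumes
its output.

Coordinate convention: origin at the top-left pixel, ``x`` = column index,
``y`` = row index, both 0-based.  Orientations are measured from the +x axis
with y pointing down, in degrees in ``[0, 180)`` (an undirected axis).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledMask",
    "CellRegion",
    "MaskSeriesError",
    "load_mask_series",
    "extract_regions",
]


class MaskSeriesError(ValueError):
    """Raised when a mask series violates the input contract."""


@dataclass(frozen=True, eq=False)
class LabeledMask:
    """One time point's integer-labeled segmentation grid."""

    frame_index: int
    grid: np.ndarray
    source_name: str = ""

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 2:
            raise MaskSeriesError(
                f"not a labeled mask: expected a 2-D image, got {grid.ndim}-D"
            )
        if not np.issubdtype(grid.dtype, np.integer):
            raise MaskSeriesError(
                f"not a labeled mask: pixel dtype {grid.dtype} is not integer"
            )
        if grid.size and grid.min() < 0:
            raise MaskSeriesError("not a labeled mask: negative labels present")
        object.__setattr__(self, "grid", grid)

    @property
    def height(self) -> int:
        return int(self.grid.shape[0])

    @property
    def width(self) -> int:
        return int(self.grid.shape[1])

    @property
    def labels(self) -> list[int]:
        """Sorted positive labels present in the grid."""
        vals = np.unique(self.grid)
        return [int(v) for v in vals if v > 0]


@dataclass(frozen=True, eq=False)
class CellRegion:
    """One segmented cell: pixels, centroid, area and major-axis orientation.

    ``centroid`` is the arithmetic mean of the pixel coordinates as
    ``(x, y) = (mean column, mean row)``.  ``orientation_deg`` is the angle of
    the equivalent-ellipse major axis in ``[0, 180)``.
    """

    frame_index: int
    label: int
    pixel_set: frozenset[tuple[int, int]] = field(repr=False)
    centroid: tuple[float, float]
    area: int
    orientation_deg: float

    @property
    def cell(self) -> tuple[int, int]:
        """The (frame, label) key identifying this cell in a series."""
        return (self.frame_index, self.label)


def _read_image(path: Path) -> np.ndarray:
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        return np.asarray(tifffile.imread(path))
    import imageio.v3 as iio

    return np.asarray(iio.imread(path))


def load_mask_series(directory_path: str | Path, pattern: str = "*.tif*") -> list[LabeledMask]:
    """Load a time-ordered labeled mask series from a directory.

    Files matching ``pattern`` are ordered lexicographically by name and
    assigned ``frame_index`` 0..T-1.  All masks must share one shape.

    Raises
    ------
    MaskSeriesError
        "insufficient frames" for < 2 matching files, "inconsistent
        dimensions" on a shape mismatch, "not a labeled mask" for
        non-integer pixel data.
    """
    directory = Path(directory_path)
    if not directory.is_dir():
        raise MaskSeriesError(f"not a directory: {directory}")
    paths = sorted(directory.glob(pattern))
    if len(paths) < 2:
        raise MaskSeriesError(
            f"insufficient frames: {len(paths)} file(s) match {pattern!r} in {directory}"
        )
    masks: list[LabeledMask] = []
    for t, path in enumerate(paths):
        grid = _read_image(path)
        mask = LabeledMask(frame_index=t, grid=grid, source_name=path.name)
        if masks and mask.grid.shape != masks[0].grid.shape:
            raise MaskSeriesError(
                "inconsistent dimensions: "
                f"{path.name} is {mask.grid.shape}, {paths[0].name} is {masks[0].grid.shape}"
            )
        masks.append(mask)
    return masks


def _orientation_deg(props: measure._regionprops.RegionProperties) -> float:
    # regionprops' orientation t is measured from the row axis; the major-axis
    # direction in (x=col, y=row) coordinates is (sin t, cos t), so the angle
    # from +x (y down) is 90 - t.
    theta = math.degrees(props.orientation)
    return (90.0 - theta) % 180.0


def extract_regions(mask: LabeledMask, *, warn_disconnected: bool = True) -> list[CellRegion]:
    """Extract one :class:`CellRegion` per positive label, sorted by label.

    Labels are taken as given: a disconnected pixel set is treated as one
    object (with a logged warning), since segmentation quality is the
    upstream tool's responsibility.
    """
    regions: list[CellRegion] = []
    for props in measure.regionprops(mask.grid):
        coords = props.coords  # (row, col) pairs
        cy, cx = props.centroid
        if warn_disconnected:
            _, n_parts = ndi.label(mask.grid == props.label)
            if n_parts > 1:
                logger.warning(
                    "label %d in frame %d has %d disconnected parts; treating as one object",
                    props.label, mask.frame_index, n_parts,
                )
        regions.append(
            CellRegion(
                frame_index=mask.frame_index,
                label=int(props.label),
                pixel_set=frozenset((int(r), int(c)) for r, c in coords),
                centroid=(float(cx), float(cy)),
                area=int(props.area),
                orientation_deg=_orientation_deg(props),
            )
        )
    regions.sort(key=lambda r: r.label)
    return regions
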