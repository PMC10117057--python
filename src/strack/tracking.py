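"""Two-pass greedy linking of segmented cells between consecutive frames.

The tracker assigns mother→daughter links under two user parameters:

``max_dist``
    search radius (pixels) around a mother cell within which candidate
    daughters are considered;
``max_angle``
    maximum acute angle (degrees) between a mother's major axis and the
    *division axis* — the line through the centroids of its two putative
    daughters — for a second daughter to be accepted.

Pass 1 walks candidate pairs with positive pixel overlap in decreasing
overlap order; pass 2 walks the remaining unassigned daughters' candidates
(zero-overlap pairs included) in increasing centroid distance; daughters
still unassigned start new tracks, which lets cells entering the field
mid-series be tracked from their first appearance.

Rod-shaped bacteria divide by elongation, so the true division axis is
nearly collinear with the mother's long axis; the angle gate encodes that
prior while ``max_angle`` can be widened for species that snap almost
perpendicular at division.  The angle constraint applies only to the
acceptance of a *second* daughter — plain continuation links are gated by
distance alone.

Ties are broken deterministically: equal overlap by smaller distance, then
by (mother label, daughter label); equal distance in pass 2 by larger
overlap, then labels.  Identical inputs therefore always yield identical
links.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .masks import CellRegion, LabeledMask, extract_regions

__all__ = [
    "TrackingConfig",
    "TrackLink",
    "CandidatePair",
    "DegenerateDivisionAxisError",
    "candidate_pairs",
    "division_angle",
    "link_frames",
    "track_series",
]

NEW_TRACK = "new-track"


class DegenerateDivisionAxisError(ValueError):
    """Two putative daughters share a centroid: the division axis is undefined."""


@dataclass(frozen=True)
class TrackingConfig:
    """The tracker's two parameters.

    Defaults (50 px, 45°) suit typical 100x-objective microcolony images but
    are arbitrary; both should be set from the data at hand.
    """

    max_dist: float = 50.0
    max_angle: float = 45.0

    def __post_init__(self) -> None:
        if not self.max_dist > 0:
            raise ValueError(f"max_dist must be > 0, got {self.max_dist}")
        if not 0 < self.max_angle <= 90:
            raise ValueError(
                f"max_angle must be in (0, 90] degrees, got {self.max_angle}"
            )


@dataclass(frozen=True, order=True)
class TrackLink:
    """A directed mother→daughter edge between consecutive frames.

    ``mother`` is ``None`` for a new-track mark (a daughter with no mother).
    ``method`` records how the link was assigned: ``"overlap"`` or
    ``"distance"`` for the two greedy passes, ``"new-track"`` for motherless
    cells, ``"truth"`` / ``"imported"`` for simulator ground truth and
    externally loaded edges.
    """

    mother: Optional[tuple[int, int]]
    daughter: tuple[int, int]
    method: str
    overlap_px: int = 0
    center_dist: float = 0.0

    @property
    def is_new_track(self) -> bool:
        return self.mother is None

    @property
    def edge_key(self) -> tuple[tuple[int, int], tuple[int, int]]:
        if self.mother is None:
            raise ValueError("a new-track mark has no edge key")
        return (self.mother, self.daughter)


@dataclass(frozen=True, eq=False)
class CandidatePair:
    """A mother/daughter pair within ``max_dist``, with its link evidence."""

    mother: CellRegion
    daughter: CellRegion
    overlap_px: int
    center_dist: float


def _axis_unit(orientation_deg: float) -> tuple[float, float]:
    rad = math.radians(orientation_deg)
    return (math.cos(rad), math.sin(rad))


def division_angle(mother: CellRegion, daughter_a: CellRegion, daughter_b: CellRegion) -> float:
    """Acute angle in [0, 90] between the mother's major axis and the line
    through the two daughter centroids.  Symmetric in daughter order."""
    vx = daughter_b.centroid[0] - daughter_a.centroid[0]
    vy = daughter_b.centroid[1] - daughter_a.centroid[1]
    norm = math.hypot(vx, vy)
    if norm == 0.0:
        raise DegenerateDivisionAxisError(
            "degenerate division axis: daughter centroids coincide at "
            f"{daughter_a.centroid}"
        )
    ux, uy = _axis_unit(mother.orientation_deg)
    cosang = abs(ux * vx + uy * vy) / norm
    return math.degrees(math.acos(min(1.0, cosang)))


def candidate_pairs(
    mothers: Sequence[CellRegion],
    daughters: Sequence[CellRegion],
    config: TrackingConfig,
) -> list[CandidatePair]:
    """All mother×daughter pairs with centroid distance ≤ ``max_dist``,
    with pixel overlap computed on the shared grid."""
    pairs: list[CandidatePair] = []
    for m in mothers:
        mx, my = m.centroid
        for d in daughters:
            dist = math.hypot(d.centroid[0] - mx, d.centroid[1] - my)
            if dist <= config.max_dist:
                pairs.append(
                    CandidatePair(
                        mother=m,
                        daughter=d,
                        overlap_px=len(m.pixel_set & d.pixel_set),
                        center_dist=dist,
                    )
                )
    return pairs


def _try_accept(
    pair: CandidatePair,
    method: str,
    config: TrackingConfig,
    assigned: dict[int, TrackLink],
    children: dict[int, list[CellRegion]],
) -> None:
    if pair.daughter.label in assigned:
        return
    sibs = children.setdefault(pair.mother.label, [])
    if len(sibs) >= 2:
        return
    if len(sibs) == 1:
        try:
            angle = division_angle(pair.mother, sibs[0], pair.daughter)
        except DegenerateDivisionAxisError:
            return
        if not angle < config.max_angle:  # strict: needs to be *smaller*
            return
    assigned[pair.daughter.label] = TrackLink(
        mother=pair.mother.cell,
        daughter=pair.daughter.cell,
        method=method,
        overlap_px=pair.overlap_px,
        center_dist=pair.center_dist,
    )
    sibs.append(pair.daughter)


def link_frames(
    mothers: Sequence[CellRegion],
    daughters: Sequence[CellRegion],
    config: TrackingConfig,
) -> list[TrackLink]:
    """Assign every daughter to at most one mother; unmatched daughters
    become new tracks.  Returns links sorted by daughter label.

    Pass 1 (overlap): positive-overlap pairs in decreasing overlap order.
    Pass 2 (distance): pairs of still-unassigned daughters in increasing
    centroid distance.  Both passes enforce the two-daughter capacity and
    the strict ``max_angle`` gate on a second daughter; accepting a second
    daughter never revokes the first.
    """
    pairs = candidate_pairs(mothers, daughters, config)
    assigned: dict[int, TrackLink] = {}
    children: dict[int, list[CellRegion]] = {}

    pass1 = sorted(
        (p for p in pairs if p.overlap_px > 0),
        key=lambda p: (-p.overlap_px, p.center_dist, p.mother.label, p.daughter.label),
    )
    for p in pass1:
        _try_accept(p, "overlap", config, assigned, children)

    pass2 = sorted(
        (p for p in pairs if p.daughter.label not in assigned),
        key=lambda p: (p.center_dist, -p.overlap_px, p.mother.label, p.daughter.label),
    )
    for p in pass2:
        _try_accept(p, "distance", config, assigned, children)

    links = [assigned[d.label] for d in daughters if d.label in assigned]
    links.extend(
        TrackLink(mother=None, daughter=d.cell, method=NEW_TRACK)
        for d in daughters
        if d.label not in assigned
    )
    links.sort(key=lambda l: l.daughter)
    return links


def track_series(
    masks: Sequence[LabeledMask],
    config: TrackingConfig = TrackingConfig(),
    *,
    regions: Optional[Sequence[Sequence[CellRegion]]] = None,
):
    """Track a whole mask series and return the assembled lineage forest.

    Iterates over consecutive frame pairs, linking each; frame-0 cells are
    track roots.  Precomputed per-frame ``regions`` may be supplied to avoid
    re-extraction.
    """
    from .lineage import build_forest

    if len(masks) < 2:
        raise ValueError("insufficient frames: need at least 2 masks to track")
    if regions is None:
        regions = [extract_regions(m) for m in masks]
    links: list[TrackLink] = []
    for t in range(len(masks) - 1):
        links.extend(link_frames(regions[t], regions[t + 1], config))
    return build_forest(masks, links, regions=regions)


def links_to_edge_keys(links: Iterable[TrackLink]) -> set[tuple]:
    """Edge keys of the non-new links (the unit the Jaccard index counts)."""
    return {l.edge_key for l in links if not l.is_new_track}
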