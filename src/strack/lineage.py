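"""Lineage forest assembly, stable track IDs, and tabular export.

Cells are nodes keyed by ``(frame, label)``; mother→daughter links are
edges.  Restricted to that direction the graph is a forest: a daughter has
at most one mother and frame indices strictly increase along edges.

Track-ID convention: a continuation (single daughter) propagates the
mother's track ID; at a division *both* daughters receive fresh IDs and the
mother's ID terminates, so a track is exactly an inter-division segment.
Roots (frame-0 cells and mid-series entrants) open fresh tracks.  IDs are
dense positive integers assigned in (frame, label) order, so identical
forests always number identically.

Export formats: one CSV per time point (``tracks_t0001.csv`` …), combined
``tracks_all.csv`` / ``cells_all.csv`` (also written as .xlsx for
spreadsheet use; CSV is normative), and a two-column source/target edge
list importable into Cytoscape for manual track editing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import pandas as pd

from .masks import CellRegion, LabeledMask, extract_regions
from .tracking import NEW_TRACK, TrackLink

__all__ = [
    "CellNode",
    "LineageForest",
    "DanglingLinkError",
    "build_forest",
    "export_per_frame_tables",
    "export_combined_tables",
    "export_cytoscape_edges",
    "read_per_frame_tables",
]

Cell = tuple[int, int]


class DanglingLinkError(ValueError):
    """A link references a cell absent from the masks."""


@dataclass(frozen=True)
class CellNode:
    """Geometry carried by each forest node."""

    cell: Cell
    centroid: tuple[float, float]
    area: int


@dataclass
class LineageForest:
    """All cells of a series plus their mother→daughter links."""

    nodes: dict[Cell, CellNode]
    links: list[TrackLink] = field(repr=False)
    track_id: dict[Cell, int] = field(repr=False)

    def __post_init__(self) -> None:
        self._parent: dict[Cell, TrackLink] = {}
        self._children: dict[Cell, list[Cell]] = {}
        for link in self.links:
            if link.is_new_track:
                continue
            self._parent[link.daughter] = link
            self._children.setdefault(link.mother, []).append(link.daughter)
        for kids in self._children.values():
            kids.sort()

    # -- structure ---------------------------------------------------------

    @property
    def edges(self) -> list[TrackLink]:
        """Non-new links (the mother→daughter edge set)."""
        return [l for l in self.links if not l.is_new_track]

    @property
    def edge_keys(self) -> set[tuple[Cell, Cell]]:
        return {l.edge_key for l in self.edges}

    @property
    def roots(self) -> list[Cell]:
        return sorted(c for c in self.nodes if c not in self._parent)

    @property
    def n_frames(self) -> int:
        return 1 + max(c[0] for c in self.nodes) if self.nodes else 0

    @property
    def n_divisions(self) -> int:
        return sum(1 for kids in self._children.values() if len(kids) == 2)

    def parent_link(self, cell: Cell) -> Optional[TrackLink]:
        return self._parent.get(cell)

    def children(self, cell: Cell) -> list[Cell]:
        return self._children.get(cell, [])

    def cells_in_frame(self, frame: int) -> list[Cell]:
        return sorted(c for c in self.nodes if c[0] == frame)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for cell, node in self.nodes.items():
            g.add_node(cell, centroid=node.centroid, area=node.area,
                       track_id=self.track_id[cell])
        for link in self.edges:
            g.add_edge(link.mother, link.daughter, method=link.method)
        return g


def _assign_track_ids(
    nodes: dict[Cell, CellNode],
    parent: dict[Cell, TrackLink],
    children: dict[Cell, list[Cell]],
) -> dict[Cell, int]:
    track_id: dict[Cell, int] = {}
    next_id = 1
    for cell in sorted(nodes):
        link = parent.get(cell)
        if link is None or len(children[link.mother]) > 1:
            track_id[cell] = next_id
            next_id += 1
        else:
            track_id[cell] = track_id[link.mother]
    return track_id


def build_forest(
    masks: Sequence[LabeledMask],
    links: Sequence[TrackLink],
    *,
    regions: Optional[Sequence[Sequence[CellRegion]]] = None,
) -> LineageForest:
    """Assemble masks and links into a :class:`LineageForest`.

    Raises :class:`DanglingLinkError` if a link references a cell that no
    mask contains.
    """
    if regions is None:
        regions = [extract_regions(m, warn_disconnected=False) for m in masks]
    nodes = {
        r.cell: CellNode(cell=r.cell, centroid=r.centroid, area=r.area)
        for frame in regions
        for r in frame
    }
    parent: dict[Cell, TrackLink] = {}
    children: dict[Cell, list[Cell]] = {}
    for link in links:
        if link.daughter not in nodes:
            raise DanglingLinkError(f"dangling link: daughter {link.daughter} not in masks")
        if link.is_new_track:
            continue
        if link.mother not in nodes:
            raise DanglingLinkError(f"dangling link: mother {link.mother} not in masks")
        if link.daughter[0] != link.mother[0] + 1:
            raise DanglingLinkError(
                f"non-consecutive link {link.mother} -> {link.daughter}"
            )
        if link.daughter in parent:
            raise DanglingLinkError(f"cell {link.daughter} has two mothers")
        parent[link.daughter] = link
        children.setdefault(link.mother, []).append(link.daughter)
    track_id = _assign_track_ids(nodes, parent, children)
    return LineageForest(nodes=nodes, links=list(links), track_id=track_id)


# -- export ----------------------------------------------------------------

_FMT = "{:.2f}".format


def _link_rows(forest: LineageForest, frame: int) -> list[dict]:
    rows = []
    for cell in forest.cells_in_frame(frame):
        link = forest.parent_link(cell)
        d = forest.nodes[cell]
        row = {
            "mother_label": "",
            "mother_x": "",
            "mother_y": "",
            "daughter_label": cell[1],
            "daughter_x": _FMT(d.centroid[0]),
            "daughter_y": _FMT(d.centroid[1]),
            "link_method": NEW_TRACK if link is None else link.method,
            "track_id": forest.track_id[cell],
        }
        if link is not None:
            m = forest.nodes[link.mother]
            row.update(
                mother_label=link.mother[1],
                mother_x=_FMT(m.centroid[0]),
                mother_y=_FMT(m.centroid[1]),
            )
        rows.append(row)
    return rows


def export_per_frame_tables(forest: LineageForest, out_dir: str | Path) -> list[Path]:
    """Write one ``tracks_t{frame:04d}.csv`` per time point t ≥ 1.

    Each row is one daughter cell of that frame with its mother's label and
    centroid; new-track daughters carry empty mother fields.  Rows are
    sorted by daughter label; coordinates use two decimal places.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for frame in range(1, forest.n_frames):
        df = pd.DataFrame(
            _link_rows(forest, frame),
            columns=["mother_label", "mother_x", "mother_y", "daughter_label",
                     "daughter_x", "daughter_y", "link_method", "track_id"],
        )
        path = out / f"tracks_t{frame:04d}.csv"
        df.to_csv(path, index=False)
        paths.append(path)
    return paths


def export_combined_tables(forest: LineageForest, out_dir: str | Path) -> tuple[Path, Path]:
    """Write the combined tracks and cells tables.

    ``tracks_all.csv``: every link across all frames, with explicit
    mother/daughter frame columns.  ``cells_all.csv``: one row per cell.
    Both are also written as .xlsx; the CSVs are normative.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    track_rows = []
    for frame in range(1, forest.n_frames):
        for row in _link_rows(forest, frame):
            track_rows.append({
                "mother_frame": frame - 1 if row["mother_label"] != "" else "",
                "daughter_frame": frame,
                **row,
            })
    tracks = pd.DataFrame(
        track_rows,
        columns=["mother_frame", "mother_label", "mother_x", "mother_y",
                 "daughter_frame", "daughter_label", "daughter_x", "daughter_y",
                 "link_method", "track_id"],
    )
    cells = pd.DataFrame(
        [
            {
                "frame": cell[0],
                "label": cell[1],
                "x": _FMT(node.centroid[0]),
                "y": _FMT(node.centroid[1]),
                "area": node.area,
                "track_id": forest.track_id[cell],
            }
            for cell, node in sorted(forest.nodes.items())
        ],
        columns=["frame", "label", "x", "y", "area", "track_id"],
    )
    tracks_path = out / "tracks_all.csv"
    cells_path = out / "cells_all.csv"
    tracks.to_csv(tracks_path, index=False)
    cells.to_csv(cells_path, index=False)
    tracks.to_excel(out / "tracks_all.xlsx", index=False)
    cells.to_excel(out / "cells_all.xlsx", index=False)
    return tracks_path, cells_path


def export_cytoscape_edges(forest: LineageForest, path: str | Path) -> Path:
    """Write a two-column source/target edge list (``t{frame}_c{label}`` ids)."""
    path = Path(path)
    rows = [
        {"source": f"t{l.mother[0]}_c{l.mother[1]}",
         "target": f"t{l.daughter[0]}_c{l.daughter[1]}"}
        for l in sorted(forest.edges, key=lambda l: (l.daughter, l.mother))
    ]
    pd.DataFrame(rows, columns=["source", "target"]).to_csv(path, index=False)
    return path


def read_per_frame_tables(directory: str | Path) -> list[TrackLink]:
    """Re-parse ``tracks_t*.csv`` files back into links (round-trip reader)."""
    links: list[TrackLink] = []
    for path in sorted(Path(directory).glob("tracks_t*.csv")):
        frame = int(path.stem.split("_t")[1])
        df = pd.read_csv(path, dtype={"mother_label": "Int64"})
        for _, row in df.iterrows():
            daughter = (frame, int(row["daughter_label"]))
            if pd.isna(row["mother_label"]):
                links.append(TrackLink(mother=None, daughter=daughter, method=NEW_TRACK))
            else:
                links.append(
                    TrackLink(
                        mother=(frame - 1, int(row["mother_label"])),
                        daughter=daughter,
                        method=str(row["link_method"]),
                    )
                )
    return links
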