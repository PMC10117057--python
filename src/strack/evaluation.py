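"""Comparing two trackings of one segmentation with the track-edge Jaccard index.

Both trackings must refer to the same masks, so cells are identified by
``(frame, label)`` and a *track* is a single mother→daughter edge between
consecutive frames.  The index is |common edges| / |union of edges|: 1 is a
perfect match, and a division counts as two edges.  New-track marks are
excluded — a track requires a mother.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .tracking import TrackLink

__all__ = [
    "EvaluationResult",
    "UndefinedIndexError",
    "ReferenceTableError",
    "jaccard_index",
    "load_reference_tracks",
]


class UndefinedIndexError(ValueError):
    """Both edge sets are empty: 0/0 has no value and is never coerced to 0 or 1."""


class ReferenceTableError(ValueError):
    """An edge table failed to parse."""


@dataclass(frozen=True)
class EvaluationResult:
    jaccard: float
    n_common: int
    n_union: int
    mismatched_edges: frozenset[TrackLink] = field(repr=False, default=frozenset())


def _to_keyed(links: Iterable[TrackLink]) -> dict:
    keyed = {}
    for link in links:
        if link.is_new_track:
            continue
        keyed[link.edge_key] = link
    return keyed


def jaccard_index(reference: Iterable[TrackLink], candidate: Iterable[TrackLink]) -> EvaluationResult:
    """Jaccard index over mother→daughter edges of two trackings.

    Edges are compared by their (mother, daughter) cell keys only, so the
    assignment method and link evidence do not affect the comparison.

    Raises :class:`UndefinedIndexError` when both sets are empty.
    """
    ref = _to_keyed(reference)
    cand = _to_keyed(candidate)
    common = ref.keys() & cand.keys()
    union = ref.keys() | cand.keys()
    if not union:
        raise UndefinedIndexError("undefined index: both edge sets are empty")
    mismatched = frozenset(
        (ref | cand)[k] for k in (ref.keys() ^ cand.keys())
    )
    return EvaluationResult(
        jaccard=len(common) / len(union),
        n_common=len(common),
        n_union=len(union),
        mismatched_edges=mismatched,
    )


_REQUIRED = ["mother_frame", "mother_label", "daughter_frame", "daughter_label"]


def load_reference_tracks(path: str | Path) -> set[TrackLink]:
    """Load an edge table (e.g. expert annotation, simulator ground truth,
    or an exported ``tracks_all.csv``) into a set of links.

    Rows with empty mother fields (new-track rows) are skipped.  Each kept
    row must have integer frame/label fields with daughter frame = mother
    frame + 1; violations raise :class:`ReferenceTableError` naming the row.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - surface as a table error
        raise ReferenceTableError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ReferenceTableError(f"{path}: missing column(s) {missing}")
    links: set[TrackLink] = set()
    for i, row in df.iterrows():
        line = i + 2  # 1-based, after the header line
        if any(pd.isna(row[c]) or row[c] == "" for c in ("mother_frame", "mother_label")):
            continue
        try:
            mf, ml = int(row["mother_frame"]), int(row["mother_label"])
            df_, dl = int(row["daughter_frame"]), int(row["daughter_label"])
        except (TypeError, ValueError) as exc:
            raise ReferenceTableError(
                f"{path}, line {line}: non-integer frame/label field"
            ) from exc
        if df_ != mf + 1:
            raise ReferenceTableError(
                f"{path}, line {line}: non-consecutive edge "
                f"(mother frame {mf}, daughter frame {df_})"
            )
        links.add(TrackLink(mother=(mf, ml), daughter=(df_, dl), method="imported"))
    return links
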