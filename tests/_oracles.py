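"""Independent brute-force oracles used by the test suite.

These share no logic with the package's greedy tracker: feasibility and the
division angle are recomputed from first principles, and the best assignment
is found by exhaustive enumeration over all daughter→mother choices.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_force_angle(orientation_deg, ca, cb):
    """Acute angle between an axis at ``orientation_deg`` and the line ca-cb."""
    v = np.array([cb[0] - ca[0], cb[1] - ca[1]], dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        return None
    u = np.array([math.cos(math.radians(orientation_deg)), math.sin(math.radians(orientation_deg))])
    return math.degrees(math.acos(min(1.0, abs(float(u @ v)) / n)))


def _feasible(choice, mothers_by_label, max_angle):
    """choice: dict daughter_region -> mother_region or None."""
    broods: dict[int, list] = {}
    for d, m in choice.items():
        if m is not None:
            broods.setdefault(m.label, []).append(d)
    for label, kids in broods.items():
        if len(kids) > 2:
            return False
        if len(kids) == 2:
            ang = brute_force_angle(
                mothers_by_label[label].orientation_deg, kids[0].centroid, kids[1].centroid
            )
            if ang is None or not ang < max_angle:
                return False
    return True


def oracle_link_frames(mothers, daughters, config):
    """Exhaustively find the link set the two-pass greedy priority selects.

    Enumerates every assignment of each daughter to one in-range mother (or
    none), keeps the feasible ones, and returns the assignment whose sorted
    priority-position signature is lexicographically smallest, where the
    priority sequence is: positive-overlap pairs by (overlap desc, distance
    asc, labels), then zero-overlap pairs by (distance asc, labels).
    Missing links pad the signature with +inf, so more links beat fewer on
    equal prefixes.
    """
    pairs = []
    for m in mothers:
        for d in daughters:
            dist = math.hypot(d.centroid[0] - m.centroid[0], d.centroid[1] - m.centroid[1])
            if dist <= config.max_dist:
                ov = len(m.pixel_set & d.pixel_set)
                pairs.append((m, d, ov, dist))
    pos_pairs = sorted(
        (p for p in pairs if p[2] > 0), key=lambda p: (-p[2], p[3], p[0].label, p[1].label)
    )
    zero_pairs = sorted(
        (p for p in pairs if p[2] == 0), key=lambda p: (p[3], -p[2], p[0].label, p[1].label)
    )
    seq = pos_pairs + zero_pairs
    position = {(p[0].label, p[1].label): i for i, p in enumerate(seq)}
    mothers_by_label = {m.label: m for m in mothers}
    options = []
    for d in daughters:
        cands = [m for (m, dd, ov, dist) in pairs if dd.label == d.label]
        options.append([None] + cands)
    n_combos = 1
    for opt in options:
        n_combos *= len(opt)
    if n_combos > 500_000:
        raise RuntimeError(f"instance too large for exhaustive oracle ({n_combos} combos)")
    best_sig = None
    best_choice = None
    for combo in itertools.product(*options):
        choice = dict(zip(daughters, combo))
        if not _feasible(choice, mothers_by_label, config.max_angle):
            continue
        sig = sorted(
            position[(m.label, d.label)] for d, m in choice.items() if m is not None
        )
        padded = sig + [math.inf] * (len(daughters) - len(sig))
        if best_sig is None or padded < best_sig:
            best_sig = padded
            best_choice = choice
    edges = {
        ((m.frame_index, m.label), (d.frame_index, d.label))
        for d, m in best_choice.items()
        if m is not None
    }
    return edges
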