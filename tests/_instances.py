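"""Random small two-frame instances for oracle-equivalence checks."""

from __future__ import annotations

import math

import numpy as np

from strack.masks import LabeledMask, extract_regions
from strack.simulate import render_rod


def _place_rods(rng, specs, shape):
    grid = np.zeros(shape, dtype=np.int32)
    label = 0
    for cx, cy, ang, length, width in specs:
        pixels = render_rod((cx, cy), ang, length, width, shape)
        pixels = {(r, c) for r, c in pixels if grid[r, c] == 0}
        if len(pixels) < 3:
            continue
        label += 1
        rows, cols = zip(*pixels)
        grid[rows, cols] = label
    return grid


def random_two_frame_instance(rng: np.random.Generator, shape=(120, 120)):
    """Two frames of up to ~6 cells each: moved copies, divisions, entrants."""
    n_m = int(rng.integers(2, 5))
    mother_specs = []
    for _ in range(n_m):
        mother_specs.append((
            float(rng.uniform(20, shape[1] - 20)),
            float(rng.uniform(20, shape[0] - 20)),
            float(rng.uniform(0, 180)),
            float(rng.uniform(12, 24)),
            5.0,
        ))
    daughter_specs = []
    for cx, cy, ang, length, width in mother_specs:
        u = rng.random()
        if u < 0.4 and length > 16:  # divide along a perturbed axis
            d_ang = ang + float(rng.uniform(-25, 25))
            rad = math.radians(d_ang)
            off = length / 4.0
            for sign in (-1, 1):
                daughter_specs.append((
                    cx + sign * off * math.cos(rad),
                    cy + sign * off * math.sin(rad),
                    d_ang % 180.0,
                    length / 2.0 + 2.0,
                    width,
                ))
        elif u < 0.9:  # continue with a small move
            daughter_specs.append((
                cx + float(rng.uniform(-4, 4)),
                cy + float(rng.uniform(-4, 4)),
                (ang + float(rng.uniform(-10, 10))) % 180.0,
                length + float(rng.uniform(0, 4)),
                width,
            ))
        # else: the cell disappears
    for _ in range(int(rng.integers(0, 2))):  # entrant
        daughter_specs.append((
            float(rng.uniform(15, shape[1] - 15)),
            float(rng.uniform(15, shape[0] - 15)),
            float(rng.uniform(0, 180)),
            float(rng.uniform(10, 18)),
            5.0,
        ))
    g0 = _place_rods(rng, mother_specs, shape)
    g1 = _place_rods(rng, daughter_specs, shape)
    mothers = extract_regions(LabeledMask(frame_index=0, grid=g0), warn_disconnected=False)
    daughters = extract_regions(LabeledMask(frame_index=1, grid=g1), warn_disconnected=False)
    return mothers, daughters
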