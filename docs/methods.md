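# Methods

## Input model and conventions

A tracking problem is a time-ordered series of 2-D labeled masks: integer
images in which background is 0 and each segmented cell carries a distinct
positive label. Segmentation is upstream and is trusted as given; a label
whose pixel set is disconnected is kept as one object (with a logged
warning) rather than re-labeled, since splitting it would silently change
the cell identities the segmentation tool committed to. Time order is
lexicographic filename order; no metadata is parsed.

Coordinates are image-style: origin at the top-left pixel, `x` = column,
`y` = row, 0-based; exported X/Y use this convention. A cell's centroid is
the arithmetic mean of its pixel coordinates and its orientation is the
major axis of the equivalent ellipse (second central moments, computed via
`skimage.measure.regionprops` and converted to degrees in [0, 180)
measured from +x with y down). Orientation is an undirected axis, so all
angle comparisons are between lines and live in [0, 90]. For a region with
no preferred axis (a square or disk) the moment formula still returns a
deterministic value; nothing downstream depends on which one.

## The linker

Between consecutive frames, candidate mother–daughter pairs are all pairs
with centroid distance ≤ `max_dist` (Euclidean, centroid-to-centroid).
Assignment is greedy in two passes:

- Pass 1 processes pairs with positive pixel overlap in decreasing overlap
  order. A pair (m, d) is accepted iff d is unassigned, m has fewer than
  two daughters, and — if m already has a daughter d′ — the acute angle
  between m's major axis and the d′–d centroid line is strictly smaller
  than `max_angle`. Accepting a second daughter never revokes the first.
- Pass 2 processes the pairs of still-unassigned daughters in increasing
  centroid distance under the same constraints. In practice only
  zero-overlap pairs can be accepted here: any positive-overlap pair of a
  still-unassigned daughter was already rejected in pass 1 for a reason
  (mother full, or angle conflict with an existing daughter) that can only
  persist as the assignment grows.
- Every daughter still unassigned starts a new track. This is the only
  mechanism for cells entering the field mid-series.

The angle gate applies **only** to accepting a second daughter; single
continuation links are gated by distance alone. The daughter capacity is
hard-capped at two per mother per frame transition, and a mother that got
its first daughter in pass 1 may receive its second in pass 2 if the
constraints permit.

Tie-breaks make the order total and the output deterministic: equal
overlap is broken by smaller distance, then (mother label, daughter
label) ascending; equal distance in pass 2 by larger overlap, then labels.
Defaults `max_dist` = 50 px, `max_angle` = 45° suit the simulator's
geometry and typical high-magnification microcolony images, but both are
data-dependent knobs, not recommendations.

Correctness reference: because feasibility of a link set is downward
closed and a rejection is permanent, the two-pass greedy equals the
feasible assignment that lexicographically minimizes the sorted positions
of its links in the concatenated priority sequence (pass-1 positions for
positive-overlap pairs, pass-2 positions for zero-overlap pairs, absences
ranked last). The test suite exploits this: an exhaustive oracle
enumerates every daughter→mother assignment on small random instances,
filters by feasibility recomputed from first principles, selects the
lexicographic optimum, and must agree with the greedy linker exactly.

## Lineage forest and track IDs

Cells are nodes keyed by (frame, label); links are edges. A daughter has
at most one mother, frames strictly increase along edges, and a mother has
at most two daughters, so the graph is a forest. Track IDs are dense
positive integers assigned in (frame, label) order: a continuation
propagates the mother's ID; at a division **both** daughters get fresh IDs
(the mother's ID terminates). A track is therefore exactly an
inter-division segment, which makes `#IDs = #roots + 2·#divisions` an
invariant the tests assert. The alternative convention (one daughter
inherits) would need an arbitrary rule for choosing the heir.

Exports: one CSV per time point (`tracks_t{frame:04d}.csv`; columns
mother_label/x/y, daughter_label/x/y, link_method, track_id; coordinates
at two decimals; new-track rows with empty mother fields), combined
`tracks_all.csv` (plus explicit mother/daughter frame columns) and
`cells_all.csv` (frame, label, x, y, area, track_id), each mirrored as
.xlsx for spreadsheet users with CSV as the normative format, and a
two-column `source,target` edge list (`t{frame}_c{label}` identifiers)
importable into Cytoscape for manual curation. Export followed by
re-import is the identity on the edge set, which the tests check for every
format.

## Evaluation

Two trackings of the *same* segmentation are compared by the Jaccard index
over mother→daughter edges keyed by (frame, label) pairs: JI = |A ∩ B| /
|A ∪ B|. A division contributes two edges; new-track marks are excluded
(a track requires a mother); 0/0 raises an explicit error rather than
returning a conventional value. Comparing trackings of *different*
segmentations would require a cell-identity matching step and is out of
scope. The edge reader accepts any CSV with
mother_frame/mother_label/daughter_frame/daughter_label columns and
rejects non-consecutive edges and malformed rows with their line number.

`TrackLink.method` records assignment provenance (`overlap`, `distance`,
`new-track`; `truth` for simulator edges, `imported` for loaded tables);
only the edge keys enter any comparison.

## The simulator

Cells are spherocylinders (tip-to-tip length L, width W) on a continuous
plane, rendered by marking every pixel whose center lies within W/2 of the
cell's central segment; later cells never overwrite earlier pixels. Per
frame, each cell elongates by a fixed rate along its axis; a cell whose
length exceeds its division threshold splits at midcell into two
half-length daughters placed along the mother axis perturbed by a uniform
angle up to `division_axis_noise_deg` (newborns skip jitter in their birth
frame so the rendered division axis stays within the noise bound);
surviving cells jitter by a uniform displacement up to `jitter_px`;
overlaps are then removed by iterative pairwise repulsion — closest points
between the two central segments are computed (vectorized clamped
segment–segment solver) and both cells move half the separation deficit
apart, all pairs accumulated per sweep and applied at once, up to 200
sweeps (exact contacts within 1e-6 px count as separated), after which a
residual overlap is accepted with a warning. This push-apart is a
monolayer constraint, not mechanics: no forces, torques or axis
reorientation. Cells whose rendering is empty (pushed fully off the image)
are dropped and their tracks end.

All randomness comes from one `numpy` generator seeded by `seed`, drawn in
a fixed order (founder placement/orientation/length/threshold, then per
frame: division noise and daughter thresholds in cell order, jitter in
cell order), so a seed is bit-reproducible in masks and links.

### Default study conditions

256×256 px image, 2 founders, W = 7 px, initial length 18 px, elongation
6 px/frame, division at 36 px with ±8 % per-cell threshold noise (this
desynchronizes the colony), axis noise 10°, jitter 1 px, 10 frames. At
~14 px/µm these are 0.5 µm-wide rods doubling every ~3 frames, i.e. a
10–20 min imaging interval for a ~45–60 min doubling time — the regime of
slow-growing soil isolates on nutrient pads. A series reaches ~13–20 cells
in the final frame (~50–80 cell instances over the 10 frames) and its
continuation links move by ~2 px/frame (median; ~3 px at the 90th
percentile, the tail driven by colony shoving rather than by the imposed
jitter). Raising the elongation rate towards a doubling per 2 frames makes
shoving displace cells by 3–8 px/frame, where neighbour swaps begin to
defeat any overlap-prior tracker — a real phenomenon, but not the regime
the recovery guarantee targets.

### What passing on the simulator does and does not show

The simulator provides exact lineage truth, perfect segmentation, rigid
rods and small displacement. Recovery of JI = 1.0 there shows the linker's
logic and priorities are right under its own assumptions; it says nothing
about robustness to segmentation errors, motile or filamentous cells,
out-of-plane growth, or frame intervals long relative to the doubling
time, none of which the generator emulates.

## Numerical choices and degenerate inputs

- `max_angle` is compared strictly (`angle < max_angle`); `max_dist`
  inclusively (`dist ≤ max_dist`).
- Coincident daughter centroids make the division axis undefined: the
  candidate second daughter is rejected (and the angle helper raises a
  dedicated error for direct callers).
- A mask with no positive labels yields an empty region list; a series
  needs ≥ 2 frames; masks must share one shape and an integer dtype.
- Overlap is an exact pixel-set intersection; no sub-pixel reasoning
  anywhere.

## Known limitations

Tracking assumes near-static cells between frames; there is no gap
closing across missing frames, no track merging, no movement-vector
prediction. The Jaccard evaluation requires both trackings to share one
segmentation. The simulator's repulsion can leave residual overlaps in
extreme crowding (warned, and resolved at rendering by first-come pixel
priority).
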