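"""Scoring nucleus shape agreement by convex-polygon overlap.

Two matched nuclei are mapped into a shared centered frame; the overlap
index normalizes their intersection area by the two polygon areas.  Pairs
below the threshold (default 0.9 average) join nuclei of inconsistent shape
or size and are removed.
"""

import numpy as np

from nucalign import convex_hull, normalize_pair, overlap_decision, overlap_indexes

rng = np.random.default_rng(2)
base = rng.uniform(0, 12, (24, 2))
matched = convex_hull(base + (40, 25))           # same shape, translated
oversegmented = convex_hull(1.8 * base + (3, 9))  # merged nuclei: too large

reference = convex_hull(base)
for name, other in [("well matched", matched), ("over-segmented", oversegmented)]:
    a, b = normalize_pair(other, reference, scale=(1.0, 1.0))
    score = overlap_indexes(a, b)
    keep = overlap_decision(score, "average", 0.9)
    print(f"{name:>15}: intersection = {score.intersection_area:7.2f} px^2, "
          f"avg index = {score.index_avg:.3f}, min index = {score.index_min:.3f} "
          f"-> {'kept' if keep else 'removed'}")
# index 1.0 means identical centered polygons; the average index weighs the
# intersection against both areas, the minimum index against the larger one.
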