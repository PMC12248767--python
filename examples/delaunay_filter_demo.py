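"""Removing a mismatched correspondence by Delaunay edge consistency.

Twenty correspondences related by a similarity transform triangulate
identically on both sides; displacing one point breaks the topology on one
side only, and the filter removes it.
"""

import numpy as np

from nucalign import build_trigraph, consistency_filter

rng = np.random.default_rng(1)
pts = rng.uniform(0, 100, (20, 2))
theta = np.deg2rad(30)
rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
other = 1.4 * pts @ rot.T + 50.0

outlier = 13
other[outlier] += (70.0, -45.0)  # a gross mismatch on one side

ga = build_trigraph({i: tuple(p) for i, p in enumerate(pts)})
gb = build_trigraph({i: tuple(p) for i, p in enumerate(other)})
print(f"edges differ before filtering: {ga.edges != gb.edges}")

kept = consistency_filter(ga, gb)
removed = sorted(set(range(20)) - set(kept))
print(f"removed correspondences : {removed}")
print(f"outlier {outlier} removed     : {outlier in removed}")

surv_a = build_trigraph({i: tuple(pts[i]) for i in kept})
surv_b = build_trigraph({i: tuple(other[i]) for i in kept})
print(f"survivor edge sets equal: {surv_a.edges == surv_b.edges}")
# The filter also drops inliers whose local triangulation the outlier
# distorted; the survivors are guaranteed topologically consistent.
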