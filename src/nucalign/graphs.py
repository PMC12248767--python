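"""Delaunay edge-consistency filtering of correspondences.

Two triangulations are built over the same correspondence indices — one on
the H&E-side centers, one on the DAPI-side centers.  A geometrically
consistent correspondence set yields identical edge sets; an outlier
distorts the local topology on one side only.  The filter checks, node by
node in index order, whether each node's connected edges are identical in
the two graphs, removes the nodes with inconsistent connectivity from both
sides, rebuilds the triangulations, and iterates until every surviving
node has identical edge connectivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, QhullError

logger = logging.getLogger(__name__)


class DegenerateGraphError(ValueError):
    """Fewer than 3 points, or an all-collinear configuration."""


@dataclass
class TriGraph:
    """A Delaunay triangulation over indexed correspondence points.

    ``edges`` holds unordered pairs ``(i, j)`` with ``i < j`` referencing
    correspondence indices (node ids), not array positions.
    """

    node_ids: list
    points: dict
    edges: set


def build_trigraph(points: dict) -> TriGraph:
    """Delaunay-triangulate ``{node_id: (x, y)}`` into a TriGraph.

    Raises :class:`DegenerateGraphError` for fewer than 3 points or a
    collinear configuration; duplicate points raise ``ValueError``.
    """
    ids = sorted(points)
    if len(ids) < 3:
        raise DegenerateGraphError("need at least 3 points to triangulate")
    coords = np.array([points[i] for i in ids], dtype=np.float64)
    uniq = np.unique(coords, axis=0)
    if len(uniq) != len(coords):
        raise ValueError("duplicate points are not allowed")
    try:
        tri = Delaunay(coords)
    except QhullError as exc:
        raise DegenerateGraphError(f"degenerate point configuration: {exc}") from exc
    if tri.simplices.size == 0:
        raise DegenerateGraphError("collinear points admit no triangulation")
    edges: set = set()
    for simplex in tri.simplices:
        a, b, c = (ids[k] for k in simplex)
        for u, v in ((a, b), (a, c), (b, c)):
            edges.add((u, v) if u < v else (v, u))
    return TriGraph(node_ids=ids, points={i: tuple(points[i]) for i in ids}, edges=edges)


def _neighborhoods(edges: set) -> dict:
    nb: dict = {}
    for i, j in edges:
        nb.setdefault(i, set()).add(j)
        nb.setdefault(j, set()).add(i)
    return nb


def consistency_filter(ga: TriGraph, gb: TriGraph) -> list:
    """Iteratively remove nodes until both triangulations share one edge set.

    Each iteration scans the nodes in index order and compares each node's
    incident-edge set between the two graphs; every node with inconsistent
    edge connections is removed from *both* sides, the triangulations are
    rebuilt on the survivors, and the process repeats until all remaining
    nodes have identical connectivity.  Each iteration removes at least one
    node, so termination is guaranteed.  Returns the surviving
    correspondence indices (sorted).
    """
    if set(ga.node_ids) != set(gb.node_ids):
        raise ValueError("both graphs must share the same node ids")
    pts_a = dict(ga.points)
    pts_b = dict(gb.points)
    while True:
        ids = sorted(pts_a)
        if len(ids) < 3:
            logger.warning("consistency filter degenerated below 3 nodes")
            return ids
        try:
            ta = build_trigraph(pts_a)
            tb = build_trigraph(pts_b)
        except DegenerateGraphError:
            logger.warning("degenerate configuration during filtering; stopping")
            return ids
        if ta.edges == tb.edges:
            return ids
        na, nb = _neighborhoods(ta.edges), _neighborhoods(tb.edges)
        victims = [i for i in ids if na.get(i, set()) != nb.get(i, set())]
        logger.debug("inconsistent edge connections: removing nodes %s", victims)
        for v in victims:
            del pts_a[v]
            del pts_b[v]
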