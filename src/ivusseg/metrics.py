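"""Contour distance metrics: mean distance (MD) and relative mean distance (RMD).

For every vertex p of the detected contour, D(p) is the exact minimum
Euclidean distance to the reference polyline (segment-wise, not
vertex-only) and q the attaining foot point. Then

    MD  = mean_p D(p)                      [pixels]
    RMD = mean_p [ D(p) / d(q, O) ] * 100  [percent]

with O the vertex centroid of the reference contour. The metric is
one-directional (detected towards reference); a symmetric average of both
directions is offered separately as a convenience.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString, Point

__all__ = [
    "ContourComparison",
    "point_to_contour_distance",
    "md_rmd",
    "symmetric_md",
]


def _closed_ring(contour: np.ndarray) -> LineString:
    c = np.asarray(contour, dtype=np.float64)
    if c.ndim != 2 or c.shape[1] != 2 or len(c) < 3:
        raise ValueError("reference contour must be an (N>=3, 2) polygon")
    if not np.allclose(c[0], c[-1]):
        c = np.vstack([c, c[:1]])
    return LineString(c)


def point_to_contour_distance(p, reference) -> tuple[float, tuple[float, float]]:
    """Exact minimum distance from point ``p`` to the closed reference
    polyline, together with the attaining foot point ``q``."""
    ring = _closed_ring(reference)
    pt = Point(float(p[0]), float(p[1]))
    q = ring.interpolate(ring.project(pt))
    return float(pt.distance(ring)), (float(q.x), float(q.y))


@dataclass
class ContourComparison:
    """Per-point distances of a detected contour against a reference."""

    detected: np.ndarray
    reference: np.ndarray
    distances: np.ndarray        # D(p) per detected vertex
    relative: np.ndarray         # RD(p) = D(p) / d(q, O)
    center: tuple[float, float]  # O, vertex centroid of the reference
    MD: float
    RMD: float                   # percent


def md_rmd(detected, reference) -> ContourComparison:
    """Mean distance and relative mean distance of ``detected`` vs ``reference``."""
    det = np.asarray(detected, dtype=np.float64)
    if det.ndim != 2 or det.shape[1] != 2 or len(det) < 3:
        raise ValueError("detected contour must be an (N>=3, 2) polygon")
    ref = np.asarray(reference, dtype=np.float64)
    ring = _closed_ring(ref)
    if np.allclose(ref[0], ref[-1]):
        ref_vertices = ref[:-1]
    else:
        ref_vertices = ref
    O = ref_vertices.mean(axis=0)
    dists = np.empty(len(det))
    rel = np.empty(len(det))
    for i, p in enumerate(det):
        pt = Point(p)
        d = pt.distance(ring)
        q = ring.interpolate(ring.project(pt))
        dq = float(np.hypot(q.x - O[0], q.y - O[1]))
        if dq < 1e-9:
            raise ValueError("reference contour passes through its own centre")
        dists[i] = d
        rel[i] = d / dq
    return ContourComparison(
        detected=det,
        reference=ref,
        distances=dists,
        relative=rel,
        center=(float(O[0]), float(O[1])),
        MD=float(dists.mean()),
        RMD=float(rel.mean() * 100.0),
    )


def symmetric_md(a, b) -> float:
    """Average of the two one-directional mean distances (non-primary extra)."""
    return 0.5 * (md_rmd(a, b).MD + md_rmd(b, a).MD)
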