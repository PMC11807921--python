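"""Independent geometric oracles used by the test suite.

These deliberately avoid the package's own code paths: self-intersection
is detected by testing every candidate triangle edge for a transversal
crossing through another triangle's interior, and watertightness by
counting edge incidences directly.
"""

import numpy as np


def edge_counts_watertight(faces) -> bool:
    """Every undirected edge must be shared by exactly two faces."""
    faces = np.asarray(faces)
    edges = np.vstack(
        [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]
    )
    edges = np.sort(edges, axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return bool((counts == 2).all())


def _segment_crosses_triangle(p, q, tri, eps=1e-7):
    """True if open segment (p, q) passes through the open interior of the
    triangle (touching at the boundary does not count)."""
    v0, v1, v2 = tri
    e1 = v1 - v0
    e2 = v2 - v0
    d = q - p
    h = np.cross(d, e2)
    det = np.dot(e1, h)
    if abs(det) < 1e-14:
        return False  # parallel / coplanar: treated as touching
    inv = 1.0 / det
    s = p - v0
    u = inv * np.dot(s, h)
    if u <= eps or u >= 1.0 - eps:
        return False
    qv = np.cross(s, e1)
    v = inv * np.dot(d, qv)
    if v <= eps or u + v >= 1.0 - eps:
        return False
    t = inv * np.dot(e2, qv)
    return eps < t < 1.0 - eps


def _tris_cross(t1, t2, eps=1e-7):
    """Transversal triangle-triangle crossing: some edge of one passes
    through the interior of the other."""
    for tri_a, tri_b in ((t1, t2), (t2, t1)):
        for k in range(3):
            if _segment_crosses_triangle(
                tri_a[k], tri_a[(k + 1) % 3], tri_b, eps
            ):
                return True
    return False


def self_intersects(vertices, faces, eps=1e-7) -> bool:
    """Brute-force (AABB-pruned) self-intersection test of a triangle
    soup; face pairs sharing a vertex are skipped, boundary touching is
    not counted as intersection."""
    vertices = np.asarray(vertices, float)
    faces = np.asarray(faces)
    tris = vertices[faces]
    lo = tris.min(axis=1)
    hi = tris.max(axis=1)
    n = len(faces)
    pad = 1e-9
    for i in range(n):
        overlap = np.flatnonzero(
            (lo[i + 1 :] <= hi[i] + pad).all(axis=1)
            & (hi[i + 1 :] >= lo[i] - pad).all(axis=1)
        ) + (i + 1)
        if overlap.size == 0:
            continue
        fi = set(faces[i])
        for j in overlap:
            if fi & set(faces[j]):
                continue
            if _tris_cross(tris[i], tris[j], eps):
                return True
    return False
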