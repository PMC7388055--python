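"""Independent brute-force oracles used by the tests.

Deliberately naive: dense sampling and plain Python loops, no reuse of the
library's vectorised query code.
"""

from __future__ import annotations

import math

import numpy as np


def polyline_length_loop(vertices) -> float:
    total = 0.0
    for a, b in zip(vertices[:-1], vertices[1:]):
        total += math.dist(tuple(a), tuple(b))
    return total


def point_polyline_dense(q, vertices, n_per_segment: int = 10_000) -> float:
    """Min distance from q to a polyline by dense sampling of each segment."""
    q = np.asarray(q, dtype=float)
    best = math.inf
    for a, b in zip(vertices[:-1], vertices[1:]):
        a, b = np.asarray(a, float), np.asarray(b, float)
        ts = np.linspace(0.0, 1.0, n_per_segment)
        pts = a + ts[:, None] * (b - a)
        best = min(best, float(np.min(np.linalg.norm(pts - q, axis=1))))
    return best


def segment_segment_dense(a1, b1, a2, b2, n: int = 400) -> float:
    """Min distance between two segments by a dense parameter grid."""
    a1, b1, a2, b2 = (np.asarray(x, float) for x in (a1, b1, a2, b2))
    s = np.linspace(0.0, 1.0, n)
    p = a1 + s[:, None] * (b1 - a1)      # (n, 3)
    q = a2 + s[:, None] * (b2 - a2)      # (n, 3)
    d2 = ((p[:, None, :] - q[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min()))


def sphere_contains_direct(center, radius, q) -> bool:
    return math.dist(tuple(center), tuple(q)) <= radius


def weighted_sum_loop(counts: dict, weights: dict) -> float:
    total = 0.0
    for cls, n in counts.items():
        total += n * weights[cls]
    return 100.0 - total
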