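"""Hexagonal chaos-game representation (GCGR) of encoded protein sequences.

The walk lives inside a regular hexagon whose six vertices carry the
letters H, L, S, P, G, C.  The first point of a sequence is the hexagon
center; every later point is the midpoint between the previous point
and the vertex of the current letter — the standard chaos-game
recurrence.  The feature pair is the arithmetic mean of the x- and
y-coordinates of all points, (x̄, ȳ).

Vertex layout convention: center at the origin, circumradius 1 (equal
to the unit edge length of a regular hexagon), vertices at angles
0°, 60°, …, 300° counter-clockwise assigned in the order H, L, S, P,
G, C.  Any other rigid placement changes the features only by the same
rigid motion, which leaves both downstream classifiers unchanged; the
center is configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from gcgrloc.encoding import SixLetterSequence

VERTEX_ORDER = ("H", "L", "S", "P", "G", "C")


@dataclass(frozen=True)
class HexagonGeometry:
    """A regular unit-edge hexagon with labeled vertices."""

    center: tuple[float, float]
    vertex_of: dict[str, tuple[float, float]]

    def vertices(self) -> np.ndarray:
        return np.array([self.vertex_of[k] for k in VERTEX_ORDER])


@dataclass(frozen=True)
class GCGRTrace:
    """The ordered points of a chaos-game walk and their coordinate means."""

    points: np.ndarray  # shape (n, 2)
    x_mean: float
    y_mean: float

    def __len__(self) -> int:
        return len(self.points)


def make_hexagon(center: tuple[float, float] = (0.0, 0.0)) -> HexagonGeometry:
    """Build the labeled regular hexagon with unit edge (= circumradius)."""
    cx, cy = center
    vertex_of = {}
    for i, letter in enumerate(VERTEX_ORDER):
        angle = math.radians(60.0 * i)
        vertex_of[letter] = (cx + math.cos(angle), cy + math.sin(angle))
    return HexagonGeometry(center=(float(cx), float(cy)), vertex_of=vertex_of)


def gcgr_trace(encoded: SixLetterSequence, geometry: HexagonGeometry | None = None) -> GCGRTrace:
    """Run the midpoint chaos-game walk for a six-letter encoded sequence.

    The first point is the hexagon center regardless of the first
    letter; point i (i >= 2) is the midpoint of point i-1 and the vertex
    of letter i.
    """
    if geometry is None:
        geometry = make_hexagon()
    symbols = encoded.symbols
    if not symbols:
        raise ValueError("cannot trace an empty encoded sequence")
    n = len(symbols)
    pts = np.empty((n, 2))
    pts[0] = geometry.center
    for i in range(1, n):
        vx, vy = geometry.vertex_of[symbols[i]]
        pts[i, 0] = 0.5 * (pts[i - 1, 0] + vx)
        pts[i, 1] = 0.5 * (pts[i - 1, 1] + vy)
    return GCGRTrace(points=pts, x_mean=float(pts[:, 0].mean()), y_mean=float(pts[:, 1].mean()))


def gcgr_features(
    trace: GCGRTrace,
    summary: Callable[[np.ndarray], float] | None = None,
) -> np.ndarray:
    """Return the 2-D feature vector (x̄, ȳ) of a trace.

    ``summary`` may replace the mean with another per-axis statistic
    (e.g. the median); only the mean is used by the shipped models.
    """
    if summary is None:
        return np.array([trace.x_mean, trace.y_mean])
    return np.array([float(summary(trace.points[:, 0])), float(summary(trace.points[:, 1]))])


def trace_series(trace: GCGRTrace) -> tuple[Sequence[float], Sequence[float]]:
    """The x-series and y-series of a walk, for export or plotting."""
    return trace.points[:, 0].tolist(), trace.points[:, 1].tolist()
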