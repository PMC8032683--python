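"""Euclidean primitives on backbone-grain coordinates.

Everything operates on 3-vectors in nanometres.  The angle of interest is the
one formed *at* the middle point of a triple: for three points ``x``, ``y``,
``z`` it is ``arccos(v . w)`` with ``v = (x - y)/|x - y|`` and
``w = (z - y)/|z - y|``, which lies in ``[0, pi]`` and approaches ``pi`` when
``y`` sits between ``x`` and ``z`` on a straight line.  Near-collinear triples
therefore score *large* angles; the detection criterion is
``angle >= alpha * pi``.

Periodic boundary conditions are off by default; pass an orthorhombic ``box``
(three edge lengths) to route displacements through the minimum-image
convention.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "DegenerateGeometryError",
    "displacement",
    "distance",
    "angle_at_vertex",
]


class DegenerateGeometryError(ValueError):
    """Raised when an angle is requested with a zero-length arm."""


def displacement(a, b, box=None) -> np.ndarray:
    """Displacement vector from ``a`` to ``b``.

    With ``box`` (three positive orthorhombic edge lengths, nm) each component
    is wrapped into ``(-L/2, L/2]`` — the minimum-image convention.  Without a
    box this is simply ``b - a``.
    """
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    if box is None:
        return d
    box = np.asarray(box, dtype=float)
    # wrap into (-L/2, L/2]: subtract the nearest whole box image
    d -= box * np.floor(d / box + 0.5)
    # floor(x+0.5) maps exactly -L/2 to -L/2 (we want +L/2); fix the edge
    d = np.where(d <= -box / 2, d + box, d)
    return d


def distance(a, b, box=None) -> float:
    """Euclidean distance between two points (minimum-image if ``box``)."""
    return float(np.linalg.norm(displacement(a, b, box)))


def angle_at_vertex(x, y, z, box=None) -> float:
    """Angle in radians formed by ``x`` and ``z`` at the vertex ``y``.

    Returns ``arccos(v . w)`` for the unit arm vectors ``v`` (towards ``x``)
    and ``w`` (towards ``z``); the dot product is clamped to ``[-1, 1]`` so
    floating-point round-off never produces NaN.  Symmetric in ``(x, z)``.

    Raises
    ------
    DegenerateGeometryError
        If either arm has zero length (``x == y`` or ``z == y``).
    """
    v = displacement(y, x, box)
    w = displacement(y, z, box)
    nv = np.linalg.norm(v)
    nw = np.linalg.norm(w)
    if nv == 0.0 or nw == 0.0:
        raise DegenerateGeometryError("angle undefined: zero-length arm at vertex")
    c = float(np.dot(v, w) / (nv * nw))
    return float(np.arccos(min(1.0, max(-1.0, c))))
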