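"""Detection of (alpha, epsilon)-aligned triples of backbone grains.

A triple of grains (x, y, z) on three pairwise-distinct peptides is
*aligned* when both gaps |x-y| and |y-z| are at most ``epsilon`` (nm) and the
angle formed at the center grain y is at least ``alpha * pi`` — i.e. the
three grains are nearly collinear with y in the middle.  In a cross-beta
lattice the backbone beads of adjacent strands stack at regular spacing, so
such triples pick out beta-sheet columns while the distinct-peptide
constraint suppresses alpha-helix and random-coil segments, whose
near-collinear runs live on a single peptide.

Defaults alpha = 0.89 and epsilon = 0.7 nm are the operating point used for
MARTINI backbone beads.

Triples are stored canonically as ``(end_a, center, end_b)`` with
``end_a < end_b`` (grain ids): the geometric condition is symmetric under
swapping the two ends, so each alignment appears once.

Two interchangeable finders are provided: a neighbor-pruned one (default)
and a literal dense enumeration over all ordered triples
(:func:`find_aligned_triples_bruteforce`), kept as an independent oracle.
Both return identical sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.spatial import cKDTree

from .geometry import DegenerateGeometryError, angle_at_vertex, distance
from .gro_io import Frame, Grain

__all__ = [
    "DetectionParams",
    "AlignedTriple",
    "is_aligned",
    "find_aligned_triples",
    "find_aligned_triples_bruteforce",
    "neighbor_candidates",
]

DEFAULT_ALPHA = 0.89
DEFAULT_EPSILON = 0.7


@dataclass(frozen=True)
class DetectionParams:
    """Thresholds of the aligned-triple criterion.

    alpha : dimensionless in [0, 1]; angular threshold, condition is
        angle-at-center >= alpha * pi.  Larger alpha = stricter collinearity.
    epsilon : nm, > 0; maximum gap between the center grain and each end.
    use_pbc : apply the minimum-image convention using the frame's box.
    """

    alpha: float = DEFAULT_ALPHA
    epsilon: float = DEFAULT_EPSILON
    use_pbc: bool = False

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")


class AlignedTriple(NamedTuple):
    """Canonical aligned triple of grain ids, ends ordered end_a < end_b."""

    end_a: int
    center: int
    end_b: int

    @property
    def grain_ids(self) -> frozenset[int]:
        return frozenset(self)


def _frame_box(frame: Frame, params: DetectionParams):
    return frame.box_or_none() if params.use_pbc else None


def is_aligned(x: Grain, y: Grain, z: Grain, params: DetectionParams,
               box=None) -> bool:
    """Whether the ordered triple (x, y, z) meets the alignment criterion.

    Requires pairwise-distinct peptides, both gaps <= epsilon, and the angle
    at y >= alpha*pi.  Coincident grains (a zero-length arm) yield False
    rather than an error, so noisy frames never abort a run.
    """
    if len({x.peptide_id, y.peptide_id, z.peptide_id}) != 3:
        return False
    eps = params.epsilon
    if distance(x.position, y.position, box) > eps:
        return False
    if distance(y.position, z.position, box) > eps:
        return False
    try:
        ang = angle_at_vertex(x.position, y.position, z.position, box)
    except DegenerateGeometryError:
        return False
    return ang >= params.alpha * np.pi


def neighbor_candidates(frame: Frame, epsilon: float,
                        box=None) -> dict[int, set[int]]:
    """For each grain, the grains on *other* peptides within epsilon.

    Exactly the brute-force epsilon-neighborhood, computed with a
    fixed-radius spatial query (periodic when a box is given).
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    n = len(frame)
    out: dict[int, set[int]] = {g.grain_id: set() for g in frame.grains}
    if n < 2:
        return out
    pts = frame.positions
    pep = frame.peptide_ids
    if box is not None:
        b = np.asarray(box, dtype=float)
        tree = cKDTree(np.mod(pts, b), boxsize=b)
    else:
        tree = cKDTree(pts)
    for i, j in tree.query_pairs(epsilon):
        if pep[i] != pep[j]:
            gi, gj = frame.grains[i].grain_id, frame.grains[j].grain_id
            out[gi].add(gj)
            out[gj].add(gi)
    return out


def find_aligned_triples(frame: Frame,
                         params: DetectionParams = DetectionParams()
                         ) -> set[AlignedTriple]:
    """All canonical aligned triples in a frame (neighbor-pruned search).

    For each candidate center, only grains within epsilon on other peptides
    can be ends; angles over those end pairs are evaluated vectorized.  The
    result equals the dense enumeration over all ordered triples as a set.
    """
    n = len(frame)
    if n < 3:
        return set()
    box = _frame_box(frame, params)
    pts = frame.positions
    pep = frame.peptide_ids
    ids = np.array([g.grain_id for g in frame.grains], dtype=int)
    # index grains by row, neighbors per row
    nbrs = neighbor_candidates(frame, params.epsilon, box)
    row_of = {g.grain_id: i for i, g in enumerate(frame.grains)}
    cos_thresh = np.cos(params.alpha * np.pi)  # angle >= a*pi <=> cos <= cos(a*pi)
    bvec = np.asarray(box, dtype=float) if box is not None else None
    out: set[AlignedTriple] = set()
    for yi in range(n):
        cand = [row_of[g] for g in nbrs[ids[yi]]]
        if len(cand) < 2:
            continue
        cand = np.array(sorted(cand), dtype=int)
        arms = pts[cand] - pts[yi]
        if bvec is not None:
            arms -= bvec * np.floor(arms / bvec + 0.5)
            arms = np.where(arms <= -bvec / 2, arms + bvec, arms)
        norms = np.linalg.norm(arms, axis=1)
        ok = norms > 0.0
        cand, arms, norms = cand[ok], arms[ok], norms[ok]
        if len(cand) < 2:
            continue
        units = arms / norms[:, None]
        cosm = units @ units.T
        k = len(cand)
        iu, ju = np.triu_indices(k, 1)
        hits = cosm[iu, ju] <= cos_thresh + 1e-12
        # re-check borderline cosines with the scalar path so the accelerated
        # finder and the oracle agree bit-for-bit at the threshold
        for a, b in zip(iu[hits], ju[hits]):
            ra, rb = int(cand[a]), int(cand[b])
            if pep[ra] == pep[rb]:
                continue
            gx, gy, gz = frame.grains[ra], frame.grains[yi], frame.grains[rb]
            if is_aligned(gx, gy, gz, params, box):
                ea, eb = sorted((gx.grain_id, gz.grain_id))
                out.add(AlignedTriple(ea, gy.grain_id, eb))
    return out


def find_aligned_triples_bruteforce(frame: Frame,
                                    params: DetectionParams = DetectionParams()
                                    ) -> set[AlignedTriple]:
    """Literal enumeration over all ordered triples of grains.

    Evaluates the distance and angle conditions for every (x, y, z) with a
    dense vectorized sweep per center — no spatial pruning.  This is the
    independent oracle the accelerated finder is tested against.
    """
    n = len(frame)
    if n < 3:
        return set()
    box = _frame_box(frame, params)
    pts = frame.positions
    pep = frame.peptide_ids
    ids = np.array([g.grain_id for g in frame.grains], dtype=int)
    bvec = np.asarray(box, dtype=float) if box is not None else None
    out: set[AlignedTriple] = set()
    for yi in range(n):
        arms = pts - pts[yi]
        if bvec is not None:
            arms -= bvec * np.floor(arms / bvec + 0.5)
            arms = np.where(arms <= -bvec / 2, arms + bvec, arms)
        norms = np.linalg.norm(arms, axis=1)
        near = (norms <= params.epsilon) & (norms > 0.0) & (pep != pep[yi])
        rows = np.nonzero(near)[0]
        if len(rows) < 2:
            continue
        units = arms[rows] / norms[rows, None]
        cosm = units @ units.T
        cos_thresh = np.cos(params.alpha * np.pi)
        for a in range(len(rows)):
            for b in range(a + 1, len(rows)):
                ra, rb = rows[a], rows[b]
                if pep[ra] == pep[rb]:
                    continue
                if cosm[a, b] <= cos_thresh + 1e-12:
                    gx, gy, gz = frame.grains[ra], frame.grains[yi], frame.grains[rb]
                    if is_aligned(gx, gy, gz, params, box):
                        ea, eb = sorted((ids[ra], ids[rb]))
                        out.add(AlignedTriple(ea, ids[yi], eb))
    return out
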