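"""Distance matrices, the LoTRA code transform and recurrence matrices.

The LoTRA transform replaces the usual hard epsilon-threshold on the
pairwise-distance matrix ``D`` with a local-binary-pattern code: each interior
cell ``(i, j)`` is assigned the 8-bit integer

    code = sum_{n=1..8} s(g_n - g_0) * 2^(n-1),    s(u) = 1 iff u >= 0,

where ``g_0 = D[i, j]`` and ``g_1..g_8`` walk the 3x3 neighborhood of the
cell.  The code describes the inequality pattern of the neighborhood —
curvature and directionality of the phase-space trajectory — without
discarding any distance information.  Codes in the middle band (64–191 by
default) mark high-curvature structure and define a binary sparse matrix for
downstream recurrence statistics.

Neighbor enumeration is fixed as offsets relative to ``(i, j)``::

    g1=(i-1,j-1)  g2=(i-1,j)  g3=(i-1,j+1)  g4=(i,j+1)
    g5=(i+1,j+1)  g6=(i+1,j)  g7=(i+1,j-1)  g8=(i,j-1)

i.e. starting at the preceding-time corner and circling the center; bit ``n``
carries weight ``2^(n-1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .embedding import Trajectory

__all__ = [
    "NEIGHBOR_OFFSETS",
    "DistanceMatrix",
    "Neighborhood3x3",
    "CodeMatrix",
    "RecurrenceMatrix",
    "EpsilonCalibration",
    "distance_matrix",
    "lbp_code",
    "lotra_transform",
    "code_band_mask",
    "recurrence_matrix",
    "calibrate_epsilon",
    "HIGH_CURVATURE_BAND",
]

#: (row, col) offsets of neighbors g1..g8, in bit order (weights 2^0..2^7).
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1),
    (-1, 0),
    (-1, 1),
    (0, 1),
    (1, 1),
    (1, 0),
    (1, -1),
    (0, -1),
)

#: Default code band marking high-curvature trajectory structure.
HIGH_CURVATURE_BAND: tuple[int, int] = (64, 191)


@dataclass
class DistanceMatrix:
    """Symmetric ``N x N`` matrix of pairwise Euclidean norms, zero diagonal."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("distance matrix must be finite")
        if np.any(v < 0) or np.any(np.diagonal(v) != 0):
            raise ValueError("distances must be >= 0 with a zero diagonal")
        if not np.array_equal(v, v.T):
            raise ValueError("distance matrix must be exactly symmetric")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class Neighborhood3x3:
    """Center value ``g0`` and its 8 neighbors in ``NEIGHBOR_OFFSETS`` order."""

    center: float
    neighbors: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.neighbors) != 8:
            raise ValueError("exactly 8 neighbors required")


@dataclass
class CodeMatrix:
    """``(N-2) x (N-2)`` LoTRA codes; cell (i, j) maps to distance cell
    (i + index_offset, j + index_offset)."""

    codes: np.ndarray
    index_offset: int = 1

    def __post_init__(self) -> None:
        c = np.asarray(self.codes)
        if not np.issubdtype(c.dtype, np.integer):
            raise ValueError("codes must be integers")
        if c.size and (c.min() < 0 or c.max() > 255):
            raise ValueError("codes must lie in [0, 255]")
        self.codes = c

    @property
    def n(self) -> int:
        return self.codes.shape[0]


@dataclass
class RecurrenceMatrix:
    """Binary matrix of recurrences, from a threshold or a code band."""

    entries: np.ndarray
    epsilon: float | None = None
    source: str = "threshold"

    def __post_init__(self) -> None:
        e = np.asarray(self.entries)
        if not np.isin(e, (0, 1)).all():
            raise ValueError("entries must be 0/1")
        self.entries = e.astype(np.uint8)

    @property
    def n(self) -> int:
        return self.entries.shape[0]


class EpsilonCalibration(NamedTuple):
    """Result of recurrence-rate-targeted threshold calibration."""

    epsilon: float
    achieved_rr: float


def distance_matrix(traj: Trajectory) -> DistanceMatrix:
    """Pairwise Euclidean norms between trajectory points.

    Exact symmetry is enforced by mirroring the computed upper triangle, so
    code-symmetry properties of the LoTRA transform hold bit-exactly.
    """
    pts = np.atleast_2d(np.asarray(traj.points, dtype=float))
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 trajectory points")
    if not np.all(np.isfinite(pts)):
        raise ValueError("trajectory contains non-finite values")
    d = squareform(pdist(pts))
    d = np.triu(d, 1)
    d = d + d.T
    return DistanceMatrix(values=d)


def lbp_code(nb: Neighborhood3x3) -> int:
    """8-bit code of one neighborhood: bit ``n-1`` set iff ``g_n >= g_0``."""
    code = 0
    for n, g in enumerate(nb.neighbors, start=1):
        if g >= nb.center:
            code |= 1 << (n - 1)
    return code


def lotra_transform(D: DistanceMatrix) -> CodeMatrix:
    """LoTRA codes for every interior cell of the distance matrix.

    Border rows/columns have incomplete neighborhoods and produce no code,
    so the output is ``(N-2) x (N-2)`` with ``index_offset = 1``.  Codes on
    the image of the line of identity are always 255 (the center distance is
    0, every neighbor is >= 0).
    """
    v = D.values
    n = v.shape[0]
    if n < 3:
        raise ValueError("matrix too small for 3x3 neighborhoods")
    center = v[1:-1, 1:-1]
    codes = np.zeros((n - 2, n - 2), dtype=np.int16)
    for bit, (di, dj) in enumerate(NEIGHBOR_OFFSETS):
        nb = v[1 + di : n - 1 + di, 1 + dj : n - 1 + dj]
        codes |= (nb >= center).astype(np.int16) << bit
    return CodeMatrix(codes=codes, index_offset=1)


def code_band_mask(
    C: CodeMatrix,
    low: int = HIGH_CURVATURE_BAND[0],
    high: int = HIGH_CURVATURE_BAND[1],
) -> RecurrenceMatrix:
    """Binary mask of codes inside the inclusive band ``[low, high]``."""
    if not (0 <= low <= high <= 255):
        raise ValueError(f"invalid code band ({low}, {high}): need 0 <= low <= high <= 255")
    mask = (C.codes >= low) & (C.codes <= high)
    return RecurrenceMatrix(entries=mask.astype(np.uint8), epsilon=None, source="code_band")


def recurrence_matrix(D: DistanceMatrix, epsilon: float) -> RecurrenceMatrix:
    """Classical thresholded recurrence matrix: 1 iff ``D_ij <= epsilon``."""
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    entries = (D.values <= epsilon).astype(np.uint8)
    return RecurrenceMatrix(entries=entries, epsilon=float(epsilon), source="threshold")


def calibrate_epsilon(
    D: DistanceMatrix,
    target_rr: float,
    tol: float | None = None,
    theiler: int = 0,
) -> EpsilonCalibration:
    """Smallest threshold whose recurrence rate reaches ``target_rr``.

    The search runs over the sorted unique off-diagonal distances, so the
    achieved rate is exact (no bisection error) and is the smallest rate
    >= ``target_rr`` attainable on this distance spectrum.  The diagonal
    counts toward the rate; ``theiler`` > 0 additionally excludes the
    ``theiler`` sub/super-diagonals nearest the line of identity from the
    candidate off-diagonal pool.

    Parameters
    ----------
    target_rr
        Desired recurrence rate in (0, 1).
    tol
        Optional alert level: warn when ``|achieved - target| > tol``.
    """
    if not 0 < target_rr < 1:
        raise ValueError("target_rr must lie in (0, 1)")
    v = D.values
    n = v.shape[0]
    if target_rr < n / n**2:
        raise ValueError(
            f"target below attainable minimum: diagonal-only rate is {1 / n:.4g}"
        )
    iu, ju = np.triu_indices(n, k=1)
    if theiler > 0:
        keep = (ju - iu) > theiler
        iu, ju = iu[keep], ju[keep]
    offdiag = np.sort(v[iu, ju])
    # RR after admitting the first k+1 sorted pair distances (each pair
    # contributes two symmetric entries) plus the N diagonal cells.
    rr = (n + 2.0 * np.arange(1, offdiag.size + 1)) / n**2
    k = int(np.searchsorted(rr, target_rr, side="left"))
    if k >= offdiag.size:
        k = offdiag.size - 1
    # Ties in the distance spectrum: admitting a value admits all its copies.
    eps = float(offdiag[k])
    achieved = float((n + 2.0 * np.searchsorted(offdiag, eps, side="right")) / n**2)
    if tol is not None and abs(achieved - target_rr) > tol:
        warnings.warn(
            f"calibrated RR {achieved:.4f} misses target {target_rr:.4f} by more than {tol}",
            stacklevel=2,
        )
    return EpsilonCalibration(epsilon=eps, achieved_rr=achieved)
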