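"""Recurrence quantification on binary matrices.

Works on any 0/1 matrix — a classical epsilon-thresholded recurrence matrix
or a LoTRA code-band mask.  Statistics follow the classical RQA canon:

* RR — density of nonzero entries, ``(1/N^2) sum R_ij``.
* Diagonal-line measures — from the histogram ``P(l)`` of maximal diagonal
  runs of exact length ``l``: determinism DET, mean/max line length,
  divergence DIV = 1/Lmax, and the Shannon entropy
  ``ENT = -sum_{l >= l_min} p(l) ln p(l)`` with ``p(l) = P(l)/N_l``.
* Vertical-line measures — laminarity LAM, trapping time TT and the longest
  vertical line, from the analogous vertical-run histogram.

``l_min`` defaults to 2: it takes two points to define a line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import RecurrenceMatrix

__all__ = [
    "DiagonalHistogram",
    "RQAFeatures",
    "recurrence_rate",
    "diagonal_histogram",
    "vertical_histogram",
    "entropy",
    "rqa_features",
    "FEATURE_NAMES",
]

FEATURE_NAMES = (
    "rr",
    "det",
    "mean_diag_l",
    "max_diag_l",
    "div",
    "ent",
    "lam",
    "tt",
    "max_vert_l",
)


def _as_binary(B) -> np.ndarray:
    if isinstance(B, RecurrenceMatrix):
        return B.entries
    arr = np.asarray(B)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("matrix must be binary")
    return arr.astype(np.uint8)


@dataclass
class DiagonalHistogram:
    """Histogram of maximal run lengths along one scanning direction.

    ``lengths``/``counts`` cover every run length present (including those
    below ``l_min``); ``n_lines`` is the number of lines of length >=
    ``l_min``, the normalizer of the probabilities ``p(l)``.
    """

    lengths: np.ndarray
    counts: np.ndarray
    l_min: int = 2
    direction: str = "diagonal"

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=int)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.lengths.shape != self.counts.shape:
            raise ValueError("lengths and counts must match")
        if np.any(self.lengths < 1) or np.any(self.counts < 0):
            raise ValueError("lengths must be >= 1 and counts >= 0")

    @property
    def n_lines(self) -> int:
        """Number of lines with length >= l_min (N_l)."""
        return int(self.counts[self.lengths >= self.l_min].sum())

    def probabilities(self) -> tuple[np.ndarray, np.ndarray]:
        """Lengths >= l_min and their probabilities p(l); empty if N_l = 0."""
        sel = self.lengths >= self.l_min
        n_l = self.counts[sel].sum()
        if n_l == 0:
            return np.empty(0, dtype=int), np.empty(0)
        return self.lengths[sel], self.counts[sel] / n_l

    @property
    def total_points(self) -> int:
        """Recurrent points lying on any counted run (all lengths)."""
        return int((self.lengths * self.counts).sum())


@dataclass
class RQAFeatures:
    """The 9 recurrence statistics fed to the classifier, in a fixed order."""

    rr: float
    det: float
    mean_diag_l: float
    max_diag_l: float
    div: float
    ent: float
    lam: float
    tt: float
    max_vert_l: float
    notes: list[str] = field(default_factory=list)

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)


def recurrence_rate(B) -> float:
    """Density of nonzero entries: ``(1/N^2) sum B_ij``."""
    arr = _as_binary(B)
    return float(arr.sum() / arr.size)


def _run_lengths(line: np.ndarray) -> list[int]:
    # Maximal runs of 1s in a binary 1-D array.
    if line.size == 0 or not line.any():
        return []
    padded = np.concatenate(([0], line, [0]))
    edges = np.flatnonzero(np.diff(padded))
    return list(edges[1::2] - edges[::2])


def diagonal_histogram(B, l_min: int = 2, include_loi: bool = False) -> DiagonalHistogram:
    """Histogram of maximal diagonal runs over both triangles.

    The main diagonal (line of identity) is skipped unless ``include_loi``.
    Runs touching the matrix border count with their observed length.
    """
    if l_min < 1:
        raise ValueError("l_min must be >= 1")
    arr = _as_binary(B)
    n_rows, n_cols = arr.shape
    all_runs: list[int] = []
    for k in range(-(n_rows - 1), n_cols):
        if k == 0 and not include_loi:
            continue
        all_runs.extend(_run_lengths(np.diagonal(arr, offset=k)))
    if not all_runs:
        return DiagonalHistogram(
            lengths=np.empty(0, dtype=int), counts=np.empty(0, dtype=int), l_min=l_min
        )
    lengths, counts = np.unique(np.asarray(all_runs), return_counts=True)
    return DiagonalHistogram(lengths=lengths, counts=counts, l_min=l_min)


def vertical_histogram(B, v_min: int = 2) -> DiagonalHistogram:
    """Histogram of maximal vertical runs (column by column)."""
    if v_min < 1:
        raise ValueError("v_min must be >= 1")
    arr = _as_binary(B)
    all_runs: list[int] = []
    for j in range(arr.shape[1]):
        all_runs.extend(_run_lengths(arr[:, j]))
    if not all_runs:
        return DiagonalHistogram(
            lengths=np.empty(0, dtype=int),
            counts=np.empty(0, dtype=int),
            l_min=v_min,
            direction="vertical",
        )
    lengths, counts = np.unique(np.asarray(all_runs), return_counts=True)
    return DiagonalHistogram(lengths=lengths, counts=counts, l_min=v_min, direction="vertical")


def entropy(h: DiagonalHistogram) -> float:
    """Shannon entropy (nats) of the line-length distribution p(l), l >= l_min.

    Defined as 0 when no line reaches ``l_min`` or all mass sits on a single
    length, so feature vectors stay finite.
    """
    _, p = h.probabilities()
    if p.size == 0:
        return 0.0
    return float(-np.sum(p * np.log(p)))


def _line_stats(h: DiagonalHistogram) -> tuple[float, float, float]:
    """(fraction of run points on lines >= l_min, mean length, max length)."""
    total = h.total_points
    sel = h.lengths >= h.l_min
    long_points = int((h.lengths[sel] * h.counts[sel]).sum())
    n_l = h.n_lines
    frac = long_points / total if total > 0 else 0.0
    mean_l = long_points / n_l if n_l > 0 else 0.0
    max_l = float(h.lengths[sel].max()) if sel.any() else 0.0
    return frac, mean_l, max_l


def rqa_features(
    B,
    l_min: int = 2,
    v_min: int = 2,
    include_loi: bool | None = None,
) -> RQAFeatures:
    """The full 9-statistic recurrence feature vector.

    ``include_loi`` defaults to False (diagonal line counting excludes the
    line of identity, standard practice for thresholded matrices; code-band
    masks have no identity line in the high-curvature band, so the flag is
    moot there).  Ratios with empty denominators are reported as 0 and noted.
    """
    if include_loi is None:
        include_loi = False
    arr = _as_binary(B)
    if arr.size == 0:
        raise ValueError("matrix must be nonempty")
    notes: list[str] = []

    rr = recurrence_rate(arr)
    dh = diagonal_histogram(arr, l_min=l_min, include_loi=include_loi)
    det, mean_l, max_l = _line_stats(dh)
    if dh.total_points == 0:
        notes.append("no recurrent points off the LOI: DET set to 0")
    if dh.n_lines == 0:
        notes.append(f"no diagonal line of length >= {l_min}: mean/max/DIV/ENT set to 0")
    div = 1.0 / max_l if max_l > 0 else 0.0
    ent = entropy(dh)

    vh = vertical_histogram(arr, v_min=v_min)
    lam, tt, max_v = _line_stats(vh)
    if vh.n_lines == 0:
        notes.append(f"no vertical line of length >= {v_min}: LAM/TT/Vmax set to 0")

    return RQAFeatures(
        rr=rr,
        det=det,
        mean_diag_l=mean_l,
        max_diag_l=max_l,
        div=div,
        ent=ent,
        lam=lam,
        tt=tt,
        max_vert_l=max_v,
        notes=notes,
    )
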