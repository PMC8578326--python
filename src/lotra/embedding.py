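"""Phase-space reconstruction by time-delay embedding.

A scalar series ``x = (x_1, ..., x_n)`` is lifted to a trajectory of
``N = n - (m - 1) t`` points ``V_i = (x_i, x_{i+t}, ..., x_{i+(m-1)t})``,
where ``t`` is the embedding delay (in samples) and ``m`` the embedding
dimension.  The delay is conventionally chosen at the first local minimum of
the average mutual information (AMI) between the series and its lagged copy,
and the dimension at the point where the fraction of false nearest neighbors
(FNN) drops to the noise floor or levels off.

Multi-channel series that are already a state-space sample (e.g. tablet
x/y/pressure traces) skip embedding: ``delay_embed`` with ``dimension=1``
returns the channels unchanged.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "TimeSeries",
    "EmbeddingParams",
    "Trajectory",
    "LagProfile",
    "ami_profile",
    "fnn_profile",
    "select_params",
    "delay_embed",
]


@dataclass
class TimeSeries:
    """An ``n x d`` block of real-valued samples.

    Parameters
    ----------
    values
        Sample matrix, one row per time point, one column per channel.
        A 1-D array is treated as a single channel.
    sample_rate
        Optional sampling rate in Hz.
    channel_names
        Optional channel labels, length ``d``.
    """

    values: np.ndarray
    sample_rate: float | None = None
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 1:
            v = v[:, None]
        if v.ndim != 2:
            raise ValueError(f"values must be 1-D or 2-D, got ndim={v.ndim}")
        if v.shape[0] < 1 or v.shape[1] < 1:
            raise ValueError("values must contain at least one sample and one channel")
        if not np.all(np.isfinite(v)):
            raise ValueError("values must be finite")
        if self.channel_names is not None and len(self.channel_names) != v.shape[1]:
            raise ValueError("channel_names length must equal number of channels")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def channel(self, index: int = 0) -> np.ndarray:
        """Return one channel as a flat array."""
        return self.values[:, index]


@dataclass
class EmbeddingParams:
    """Delay ``t`` (samples) and dimension ``m`` of a delay embedding.

    ``delay_rule`` / ``dimension_rule`` record which selection rule fired
    when the parameters came out of :func:`select_params` ("local_minimum",
    "level_off" or "floor").
    """

    delay: int
    dimension: int
    delay_rule: str | None = None
    dimension_rule: str | None = None

    def __post_init__(self) -> None:
        if int(self.delay) != self.delay or self.delay < 1:
            raise ValueError("delay must be a positive integer")
        if int(self.dimension) != self.dimension or self.dimension < 1:
            raise ValueError("dimension must be an integer >= 1")
        self.delay = int(self.delay)
        self.dimension = int(self.dimension)


@dataclass
class Trajectory:
    """Phase-space point set: ``N x (m*d)`` matrix, one state per row."""

    points: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.points, dtype=float)
        if p.ndim == 1:
            p = p[:, None]
        if not np.all(np.isfinite(p)):
            raise ValueError("trajectory points must be finite")
        self.points = p

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass
class LagProfile:
    """A score per candidate lag (AMI, in nats) or per dimension (FNN fraction)."""

    lags: np.ndarray
    score: np.ndarray
    kind: str = "ami"

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=int)
        self.score = np.asarray(self.score, dtype=float)
        if self.lags.shape != self.score.shape:
            raise ValueError("lags and score must have the same length")
        if self.lags.size and np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")


def _mutual_information(a: np.ndarray, b: np.ndarray, bins: int) -> float:
    # Plug-in estimate from an equal-width 2-D histogram, natural log.
    counts, _, _ = np.histogram2d(a, b, bins=bins)
    total = counts.sum()
    p = counts / total
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    outer = np.outer(px, py)
    nz = p > 0
    return float(np.sum(p[nz] * (np.log(p[nz]) - np.log(outer[nz]))))


def ami_profile(
    x: TimeSeries,
    max_lag: int,
    bins: int | None = None,
    channel: int = 0,
) -> LagProfile:
    """Average mutual information between a channel and its lagged copy.

    The estimator is an equal-width 2-D histogram with ``bins`` bins per axis
    (default ``max(8, floor(cbrt(n)))`` — the cube-root rule keeps the
    plug-in bias of order ``bins^2 / n`` well below the score scale for
    independent data); scores are in nats.  Lag 0 yields the
    marginal-entropy estimate and upper-bounds the profile.

    Raises
    ------
    ValueError
        If the channel has zero variance or ``max_lag >= n``.
    """
    s = x.channel(channel)
    n = s.size
    if max_lag >= n:
        raise ValueError(f"max_lag must be < n (= {n})")
    if np.ptp(s) == 0:
        raise ValueError("zero-variance input")
    if bins is None:
        bins = max(8, int(np.cbrt(n)))
    if bins < 2:
        raise ValueError("bins must be >= 2")
    lags = np.arange(max_lag + 1)
    score = np.empty(lags.size)
    for k, lag in enumerate(lags):
        a = s[: n - lag] if lag else s
        b = s[lag:]
        score[k] = _mutual_information(a, b, bins)
    return LagProfile(lags=lags, score=score, kind="ami")


def fnn_profile(
    x: TimeSeries,
    delay: int,
    max_dim: int,
    r_tol: float = 15.0,
    a_tol: float = 2.0,
    channel: int = 0,
) -> LagProfile:
    """False-nearest-neighbor fraction for dimensions ``1..max_dim``.

    A neighbor pair in dimension ``m`` is false when the extra coordinate
    gained in dimension ``m + 1`` either blows up the pair distance by more
    than ``r_tol`` relative to the ``m``-dimensional distance, or makes the
    lifted distance exceed ``a_tol`` times the attractor size (the standard
    deviation of the series).
    """
    if max_dim < 2:
        raise ValueError("max_dim must be >= 2")
    s = x.channel(channel)
    n = s.size
    if max_dim * delay >= n:
        raise ValueError(
            f"series too short: need n > max_dim*delay = {max_dim * delay}, got n = {n}"
        )
    attractor_size = float(np.std(s))
    if attractor_size == 0:
        raise ValueError("zero-variance input")
    dims = np.arange(1, max_dim + 1)
    fracs = np.empty(dims.size)
    for k, m in enumerate(dims):
        # Restrict to points that remain valid once lifted to dimension m+1.
        n_pts = n - m * delay
        idx = np.arange(n_pts)
        emb = np.stack([s[idx + j * delay] for j in range(m)], axis=1)
        if np.allclose(emb, emb[0]):
            raise ValueError("degenerate neighborhoods")
        tree = cKDTree(emb)
        dist, nn = tree.query(emb, k=2)
        dist, nn = dist[:, 1], nn[:, 1]
        extra = np.abs(s[idx + m * delay] - s[nn + m * delay])
        lifted = np.hypot(dist, extra)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, extra / np.where(dist > 0, dist, 1.0), np.inf)
        ratio[(dist == 0) & (extra == 0)] = 0.0
        false = (ratio > r_tol) | (lifted / attractor_size > a_tol)
        fracs[k] = float(np.mean(false))
    return LagProfile(lags=dims, score=fracs, kind="fnn")


def _first_local_minimum(score: np.ndarray) -> int | None:
    for k in range(1, score.size - 1):
        if score[k] < score[k - 1] and score[k] < score[k + 1]:
            return k
    return None


def _first_level_off(score: np.ndarray, frac: float) -> int | None:
    for k in range(1, score.size):
        prev = abs(score[k - 1])
        change = abs(score[k] - score[k - 1])
        if (change / prev if prev > 0 else change) < frac:
            return k
    return None


def select_params(
    ami: LagProfile,
    fnn: LagProfile,
    level_off_frac: float = 0.05,
    fnn_floor: float = 0.05,
) -> EmbeddingParams:
    """Pick (delay, dimension) from AMI and FNN profiles.

    Delay: first strict local minimum of AMI, else the first lag whose
    relative change from the previous lag falls below ``level_off_frac``.
    Dimension: first dimension with FNN fraction below ``fnn_floor``, else
    the first level-off.  The rule that fired is recorded on the result.
    """
    if ami.lags.size == 0 or fnn.lags.size == 0:
        raise ValueError("profiles must be non-empty")

    k = _first_local_minimum(ami.score)
    if k is not None:
        delay, delay_rule = int(ami.lags[k]), "local_minimum"
    else:
        k = _first_level_off(ami.score, level_off_frac)
        if k is None:
            raise ValueError("no embedding parameter found: AMI has no minimum or level-off")
        delay, delay_rule = int(ami.lags[k]), "level_off"
    if delay < 1:
        raise ValueError("selected delay is not positive; extend the AMI lag range")

    below = np.nonzero(fnn.score < fnn_floor)[0]
    if below.size:
        dim, dim_rule = int(fnn.lags[below[0]]), "floor"
    else:
        k = _first_level_off(fnn.score, level_off_frac)
        if k is None:
            raise ValueError("no embedding parameter found: FNN has no floor crossing or level-off")
        dim, dim_rule = int(fnn.lags[k]), "level_off"

    return EmbeddingParams(
        delay=delay, dimension=dim, delay_rule=delay_rule, dimension_rule=dim_rule
    )


def delay_embed(x: TimeSeries, params: EmbeddingParams) -> Trajectory:
    """Delay-embed a series into an ``N x (m*d)`` trajectory.

    ``N = n - (m - 1) t``; row ``i`` concatenates, channel by channel, the
    lagged samples ``x[i], x[i + t], ..., x[i + (m-1) t]``.  With ``m = 1``
    the input channels are returned unchanged (the already-multi-dimensional
    case).
    """
    m, t = params.dimension, params.delay
    n = x.n
    if (m - 1) * t >= n:
        raise ValueError(
            f"series too short for embedding: need n > (m-1)*t = {(m - 1) * t}, got n = {n}"
        )
    if m == 1:
        return Trajectory(points=x.values.copy())
    n_pts = n - (m - 1) * t
    cols = [
        x.values[k * t : k * t + n_pts, ch]
        for ch in range(x.d)
        for k in range(m)
    ]
    return Trajectory(points=np.stack(cols, axis=1))
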