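"""Readers, preprocessing and visualization.

Covers the digitized spiral-drawing tablet files (semicolon-delimited
``X;Y;Z;Pressure;GripAngle;Timestamp;TestID`` by default, fully remappable),
generic CSV round-tripping of series and matrices, downsample + z-score
standardization, photometry bleaching correction (quadratic detrend followed
by baseline z-scoring), and the quartile rendering of LoTRA code matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import CodeMatrix
from .embedding import TimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "SpiralRecord",
    "DEFAULT_SPIRAL_SCHEMA",
    "DEFAULT_QUARTILE_PALETTE",
    "read_spiral_file",
    "standardize_series",
    "detrend_photometry",
    "render_code_quartiles",
    "write_series_csv",
    "read_series_csv",
    "write_matrix_csv",
    "read_matrix_csv",
    "write_sparse_coords",
]

#: Column order of the stock tablet export.
DEFAULT_SPIRAL_SCHEMA: dict[str, int] = {
    "x": 0,
    "y": 1,
    "z": 2,
    "pressure": 3,
    "grip_angle": 4,
    "timestamp": 5,
    "test_id": 6,
}

#: Quartile colors, code bins [0,63], [64,127], [128,191], [192,255]:
#: outer quartiles (shallow curvature / directionality) black & blue,
#: inner high-curvature band red & green.
DEFAULT_QUARTILE_PALETTE: tuple[str, str, str, str] = ("black", "red", "green", "blue")

QUARTILE_EDGES = (0, 64, 128, 192, 256)


@dataclass
class SpiralRecord:
    """One subject's spiral-drawing trace in device units."""

    x: np.ndarray
    y: np.ndarray
    pressure: np.ndarray
    timestamp: np.ndarray | None = None
    extra: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.x.size < 3:
            raise ValueError("need at least 3 samples")
        if self.timestamp is not None and np.any(np.diff(self.timestamp) < 0):
            raise ValueError("timestamps must be monotone nondecreasing")

    def to_time_series(self) -> TimeSeries:
        """The x, y, pressure channels as one TimeSeries."""
        return TimeSeries(
            values=np.column_stack([self.x, self.y, self.pressure]),
            channel_names=["x", "y", "pressure"],
        )


def read_spiral_file(
    path,
    schema: dict[str, int] | None = None,
    delimiter: str = ";",
    strict: bool = True,
    dynamic_only: bool = False,
    dynamic_test_id: float = 1,
) -> SpiralRecord:
    """Parse a tablet spiral-drawing text file.

    ``schema`` maps field names to zero-based column indices; ``x``, ``y``
    and ``pressure`` are required, other mapped fields are preserved.  In
    strict mode a malformed line raises with its line number; in lenient
    mode it is skipped with a logged warning.  With ``dynamic_only`` the
    rows are filtered to the dynamic spiral test via the ``test_id`` column.
    """
    schema = dict(DEFAULT_SPIRAL_SCHEMA if schema is None else schema)
    for required in ("x", "y", "pressure"):
        if required not in schema:
            raise ValueError(f"schema is missing required column {required!r}")
    path = Path(path)
    rows: list[list[float]] = []
    bad_lines: list[int] = []
    max_col = max(schema.values())
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(delimiter)
            if len(parts) <= max_col:
                parsed = None
            else:
                try:
                    parsed = [float(parts[idx]) for idx in schema.values()]
                except ValueError:
                    parsed = None
            if parsed is None:
                if strict:
                    raise ValueError(f"{path.name}: malformed line {lineno}: {line!r}")
                bad_lines.append(lineno)
                continue
            rows.append(parsed)
    if bad_lines:
        logger.warning("%s: skipped malformed lines %s", path.name, bad_lines)
    if not rows:
        raise ValueError(f"{path.name}: no parseable data rows")
    data = np.asarray(rows)
    columns = {name: data[:, k] for k, name in enumerate(schema)}
    if dynamic_only and "test_id" in columns:
        keep = columns["test_id"] == dynamic_test_id
        columns = {name: col[keep] for name, col in columns.items()}
        if not keep.any():
            raise ValueError(f"{path.name}: no rows with test_id == {dynamic_test_id}")
    extra = {
        name: col
        for name, col in columns.items()
        if name not in ("x", "y", "pressure", "timestamp")
    }
    return SpiralRecord(
        x=columns["x"],
        y=columns["y"],
        pressure=columns["pressure"],
        timestamp=columns.get("timestamp"),
        extra=extra,
    )


def standardize_series(x: TimeSeries, downsample_factor: int = 1) -> TimeSeries:
    """Keep every k-th sample, then z-score each channel to mean 0, sd 1."""
    if downsample_factor < 1:
        raise ValueError("downsample_factor must be >= 1")
    v = x.values[::downsample_factor]
    sd = v.std(axis=0)
    if np.any(sd == 0):
        bad = [k for k, s in enumerate(sd) if s == 0]
        raise ValueError(f"zero-variance input in channel(s) {bad}")
    out = (v - v.mean(axis=0)) / sd
    rate = None if x.sample_rate is None else x.sample_rate / downsample_factor
    return TimeSeries(values=out, sample_rate=rate, channel_names=x.channel_names)


def detrend_photometry(signal: TimeSeries, baseline_window: tuple[int, int]) -> TimeSeries:
    """Bleaching correction: quadratic detrend, then baseline z-score.

    A second-order polynomial in time is least-squares fitted to each
    channel and subtracted; the residual is z-scored with the mean and
    standard deviation of the ``baseline_window`` samples (half-open range).
    """
    start, stop = baseline_window
    n = signal.n
    if not (0 <= start < stop <= n):
        raise ValueError(f"baseline window ({start}, {stop}) must be inside [0, {n}]")
    t = np.arange(n, dtype=float)
    out = np.empty_like(signal.values)
    for ch in range(signal.d):
        y = signal.values[:, ch]
        coeffs = np.polyfit(t, y, deg=2)
        resid = y - np.polyval(coeffs, t)
        base = resid[start:stop]
        sd = base.std()
        # relative floor: an exactly-fitted (e.g. constant) channel leaves only
        # rounding noise behind, which must not masquerade as a baseline sd
        if sd <= 1e-12 * max(1.0, float(np.abs(y).max())):
            raise ValueError("baseline standard deviation is zero")
        out[:, ch] = (resid - base.mean()) / sd
    return TimeSeries(values=out, sample_rate=signal.sample_rate, channel_names=signal.channel_names)


def render_code_quartiles(
    C: CodeMatrix,
    path,
    palette: tuple[str, str, str, str] = DEFAULT_QUARTILE_PALETTE,
) -> Path:
    """Render a code matrix as a PNG, one palette color per code quartile.

    Codes are binned into [0,63], [64,127], [128,191], [192,255]; the image
    has exactly one pixel per code cell (no smoothing).  The bin boundaries
    and colors are also written to ``<path>.legend.txt``.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    from matplotlib.colors import ListedColormap
    from matplotlib.image import imsave

    if len(palette) != 4:
        raise ValueError("palette must contain exactly 4 colors")
    path = Path(path)
    quartile = np.asarray(C.codes) // 64
    imsave(path, quartile, cmap=ListedColormap(palette), vmin=-0.5, vmax=3.5, format="png")
    legend = path.with_suffix(path.suffix + ".legend.txt")
    with open(legend, "w") as fh:
        for k, color in enumerate(palette):
            fh.write(f"[{QUARTILE_EDGES[k]}, {QUARTILE_EDGES[k + 1] - 1}]\t{color}\n")
    return path


# -- plain-text round-tripping ------------------------------------------------

def write_series_csv(x: TimeSeries, path, header: bool = True) -> None:
    """Write a series as CSV, one row per sample, full float precision."""
    names = x.channel_names or [f"ch{k}" for k in range(x.d)]
    with open(path, "w") as fh:
        if header:
            fh.write(",".join(names) + "\n")
        np.savetxt(fh, x.values, delimiter=",", fmt="%.17g")


def read_series_csv(path, sample_rate: float | None = None) -> TimeSeries:
    """Read a CSV series; a non-numeric first row is treated as the header."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    names = None
    skip = 0
    try:
        [float(tok) for tok in first.split(",")]
    except ValueError:
        names = first.split(",")
        skip = 1
    values = np.loadtxt(path, delimiter=",", skiprows=skip, ndmin=2)
    return TimeSeries(values=values, sample_rate=sample_rate, channel_names=names)


def write_matrix_csv(matrix: np.ndarray, path) -> None:
    """Dense matrix (codes, masks, distances) as CSV."""
    arr = np.asarray(matrix)
    fmt = "%d" if np.issubdtype(arr.dtype, np.integer) else "%.17g"
    np.savetxt(path, arr, delimiter=",", fmt=fmt)


def read_matrix_csv(path, dtype=float) -> np.ndarray:
    return np.loadtxt(path, delimiter=",", dtype=dtype, ndmin=2)


def write_sparse_coords(mask: np.ndarray, path) -> None:
    """Sparse mask as a (row, col, value) coordinate list."""
    arr = np.asarray(mask)
    rows, cols = np.nonzero(arr)
    with open(path, "w") as fh:
        fh.write("row,col,value\n")
        for r, c in zip(rows, cols):
            fh.write(f"{r},{c},{arr[r, c]}\n")
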