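"""Simulated signals: sine wave, Lorenz attractor, and a synthetic two-class
spiral-drawing cohort.

The sine and Lorenz generators reproduce the standard benchmark conditions
(a 300-point sine over [0.1, 30] with step 0.1; the Lorenz system at r = 28,
sigma = 15, beta = 8/3 integrated at a fixed step of 0.025).  The cohort
generator is a synthetic stand-in for digitized Archimedean-spiral drawing
tests: a smooth spiral in x/y with stylus pressure, to which the "patient"
class adds a 4–6 Hz action-tremor oscillation and intermittent pressure
drops.  It exists so the full pipeline — distance matrix, LoTRA transform,
band mask, recurrence features, classifier — is testable end to end without
any external download; its traces are not real human recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .embedding import EmbeddingParams, TimeSeries

__all__ = [
    "LorenzParams",
    "CohortSpec",
    "sine_series",
    "lorenz_rhs",
    "lorenz_series",
    "synthetic_cohort",
    "SINE_DELAY_PRESETS",
]

#: The three benchmark 2-D sine embeddings of increasing eccentricity.
SINE_DELAY_PRESETS: dict[str, EmbeddingParams] = {
    "t15": EmbeddingParams(delay=15, dimension=2),
    "t20": EmbeddingParams(delay=20, dimension=2),
    "t3": EmbeddingParams(delay=3, dimension=2),
}


def sine_series(start: float = 0.1, stop: float = 30.0, step: float = 0.1) -> TimeSeries:
    """Sine wave sampled at ``u = start, start+step, ..., stop``.

    Defaults give the standard 300-point benchmark signal.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    if stop < start:
        raise ValueError("stop must be >= start")
    n = int(np.floor((stop - start) / step + 1e-9)) + 1
    u = start + step * np.arange(n)
    return TimeSeries(values=np.sin(u), sample_rate=1.0 / step)


@dataclass
class LorenzParams:
    """Lorenz-system parameters and fixed-step integration settings.

    Defaults follow the benchmark configuration r = 28, sigma = 15,
    beta = 8/3, dt = 0.025.  ``burn_in`` steps are discarded from the front
    of the returned series.
    """

    r: float = 28.0
    sigma: float = 15.0
    beta: float = 8.0 / 3.0
    dt: float = 0.025
    n_steps: int = 4000
    initial_state: tuple[float, float, float] = (1.0, 1.0, 1.0)
    burn_in: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if not 0 <= self.burn_in < self.n_steps:
            raise ValueError("burn_in must be in [0, n_steps)")


def lorenz_rhs(state: np.ndarray, p: LorenzParams) -> np.ndarray:
    """Vector field dx = sigma(y-x), dy = x(r-z)-y, dz = xy - beta z."""
    x, y, z = state
    return np.array(
        [p.sigma * (y - x), x * (p.r - z) - y, x * y - p.beta * z]
    )


def lorenz_series(p: LorenzParams | None = None) -> TimeSeries:
    """Integrate the Lorenz system with fixed-step 4th-order Runge–Kutta.

    Deterministic given the parameters: identical inputs give bit-identical
    output.  Raises on numerical blow-up, naming the failing step.
    """
    if p is None:
        p = LorenzParams()
    state = np.asarray(p.initial_state, dtype=float)
    out = np.empty((p.n_steps, 3))
    out[0] = state
    h = p.dt
    for k in range(1, p.n_steps):
        k1 = lorenz_rhs(state, p)
        k2 = lorenz_rhs(state + 0.5 * h * k1, p)
        k3 = lorenz_rhs(state + 0.5 * h * k2, p)
        k4 = lorenz_rhs(state + h * k3, p)
        state = state + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(state)):
            raise FloatingPointError(f"Lorenz integration blew up at step {k}")
        out[k] = state
    return TimeSeries(
        values=out[p.burn_in :],
        sample_rate=1.0 / p.dt,
        channel_names=["x", "y", "z"],
    )


@dataclass
class CohortSpec:
    """Parameters of the synthetic two-class spiral-drawing cohort.

    Class 0 ("control") traces a smooth Archimedean spiral (r = a*theta) in
    x/y with gently varying pressure plus Gaussian jitter.  Class 1
    ("patient") adds a tremor oscillation on x/y — amplitude
    ``tremor_amplitude`` (tablet units), frequency ``tremor_freq`` (Hz) —
    and intermittent pressure drops.  Defaults: 5 Hz tremor of amplitude 0.5
    on a spiral of radius ~19 units (~2.6% of the drawing extent, a clearly
    visible action tremor), 256 samples over ~10 s, jitter sd 0.05.
    """

    n_per_class: int = 20
    seed: int = 0
    tremor_amplitude: float = 0.5
    tremor_freq: float = 5.0
    jitter_sd: float = 0.05
    length: int = 256
    duration: float = 10.0
    spiral_pitch: float = 1.0
    n_turns: float = 3.0

    def __post_init__(self) -> None:
        if self.n_per_class < 2:
            raise ValueError("n_per_class must be >= 2")
        if self.tremor_amplitude < 0 or self.jitter_sd < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.length < 8:
            raise ValueError("length must be >= 8")


def _one_subject(spec: CohortSpec, rng: np.random.Generator, patient: bool) -> TimeSeries:
    t = np.linspace(0.0, spec.duration, spec.length)
    theta = np.linspace(0.0, 2 * np.pi * spec.n_turns, spec.length)
    radius = spec.spiral_pitch * theta
    x = radius * np.cos(theta)
    y = radius * np.sin(theta)
    # Smooth, subject-specific pressure profile around a mid-range plateau.
    pressure = 0.7 + 0.2 * np.sin(2 * np.pi * t / spec.duration + rng.uniform(0, 2 * np.pi))
    if patient:
        amp = spec.tremor_amplitude * rng.uniform(0.75, 1.25)
        phase = rng.uniform(0, 2 * np.pi)
        x = x + amp * np.cos(2 * np.pi * spec.tremor_freq * t + phase)
        y = y + amp * np.sin(2 * np.pi * spec.tremor_freq * t + phase)
        # Intermittent pressure drops, with depth scaled by the tremor effect
        # so a zero-amplitude cohort is distributionally identical to controls.
        effect = min(1.0, spec.tremor_amplitude / 0.5)
        for _ in range(rng.integers(2, 5)):
            start = rng.integers(0, max(1, spec.length - spec.length // 10))
            width = rng.integers(spec.length // 20, spec.length // 10 + 1)
            depth = 1.0 - effect * (1.0 - rng.uniform(0.3, 0.7))
            pressure[start : start + width] *= depth
    x = x + rng.normal(0.0, spec.jitter_sd, spec.length)
    y = y + rng.normal(0.0, spec.jitter_sd, spec.length)
    pressure = pressure + rng.normal(0.0, spec.jitter_sd * 0.2, spec.length)
    return TimeSeries(
        values=np.column_stack([x, y, pressure]),
        sample_rate=spec.length / spec.duration,
        channel_names=["x", "y", "pressure"],
    )


def synthetic_cohort(spec: CohortSpec | None = None) -> tuple[list[TimeSeries], np.ndarray]:
    """Generate a labeled cohort: ``n_per_class`` controls then patients.

    Returns ``(series, labels)`` with labels 0 (control) / 1 (patient).
    Deterministic for a given ``spec.seed``.
    """
    if spec is None:
        spec = CohortSpec()
    rng = np.random.default_rng(spec.seed)
    series: list[TimeSeries] = []
    labels: list[int] = []
    for label in (0, 1):
        for _ in range(spec.n_per_class):
            series.append(_one_subject(spec, rng, patient=bool(label)))
            labels.append(label)
    return series, np.asarray(labels, dtype=int)
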