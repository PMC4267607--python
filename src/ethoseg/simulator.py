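"""Synthetic annotated accelerometer bouts.

The simulator emulates the data the pipeline consumes: 10-second bouts of
tri-axial acceleration sampled at 20 Hz, each record carrying a
ground-truth behaviour label from the 8-class ethogram. A bout is a
semi-Markov sequence of behavioural dwells; within a dwell the signal on
each axis is

    baseline + periodic_amplitude * sin(2*pi*periodic_freq*t + phase) + noise,

with i.i.d. Gaussian noise and a phase drawn fresh per dwell. Dwell
durations follow a shifted (minimum-truncated) exponential, so behaviours
can switch after as little as 0.25 s. All magnitudes are in g.

The shipped default models are qualitative stand-ins for a foraging
shorebird repertoire (quiet inactive, 2.5 Hz walking gait, 6 Hz
heave-dominant wingbeat, irregular search/handle with handle at 1.5x the
variance of search, brief attack/peck transients); they are NOT estimates
for any real species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError
from .ethogram import BEHAVIORS, validate_behavior

__all__ = [
    "BehaviorModel",
    "SimConfig",
    "AnnotatedBout",
    "default_models",
    "sample_behavior_sequence",
    "synthesize_bout",
    "simulate_dataset",
]


@dataclass(frozen=True)
class BehaviorModel:
    """Signal and dwell model for one behavioural class.

    Parameters
    ----------
    behavior:
        Class name (one of the 8 ethogram classes).
    baseline:
        Mean acceleration per axis (x, y, z) in g.
    noise_sd:
        Gaussian noise standard deviation per axis in g (>= 0).
    periodic_amplitude:
        Sinusoid amplitude per axis in g; all zero for aperiodic classes.
    periodic_freq:
        Sinusoid frequency in Hz; must be < 10 Hz to stay below the
        Nyquist frequency of a 20 Hz recording.
    duration_mean, duration_min:
        Mean and minimum dwell duration in seconds; dwells are
        duration_min + Exp(duration_mean - duration_min), whose mean is
        exactly duration_mean.
    occupancy_weight:
        Target long-run fraction of recording time spent in this class
        (relative; weights are normalised across the model set).
    """

    behavior: str
    baseline: tuple[float, float, float]
    noise_sd: tuple[float, float, float]
    periodic_amplitude: tuple[float, float, float] = (0.0, 0.0, 0.0)
    periodic_freq: float = 0.0
    duration_mean: float = 1.0
    duration_min: float = 0.25
    occupancy_weight: float = 1.0

    def __post_init__(self) -> None:
        validate_behavior(self.behavior)
        if any(s < 0 for s in self.noise_sd):
            raise ValueError("noise_sd must be nonnegative elementwise")
        if not 0 < self.duration_min <= self.duration_mean:
            raise ValueError("need 0 < duration_min <= duration_mean")
        if not 0 <= self.periodic_freq < 10:
            raise ValueError("periodic_freq must lie in [0, 10) Hz")
        if self.occupancy_weight < 0:
            raise ValueError("occupancy_weight must be nonnegative")


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings: sampling, bout shape, and the behaviour models."""

    models: tuple[BehaviorModel, ...] = ()
    sample_rate: float = 20.0
    bout_duration: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.models:
            object.__setattr__(self, "models", default_models())
        n = self.sample_rate * self.bout_duration
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                "sample_rate * bout_duration must be an integer record count"
            )
        present = {m.behavior for m in self.models}
        missing = set(BEHAVIORS) - present
        if missing:
            raise ConfigurationError(
                f"models must cover all 8 classes; missing: {sorted(missing)}"
            )

    @property
    def n_records(self) -> int:
        return round(self.sample_rate * self.bout_duration)

    def model(self, behavior: str) -> BehaviorModel:
        for m in self.models:
            if m.behavior == behavior:
                return m
        raise KeyError(behavior)


@dataclass
class AnnotatedBout:
    """One bout: an (n, 3) array of x/y/z acceleration plus per-record labels.

    ``labels`` may be None for unannotated data read from file. ``start_time``
    is the absolute bout start in seconds (used only for time budgets).
    """

    bout_id: str
    xyz: np.ndarray
    labels: np.ndarray | None = None
    sample_rate: float = 20.0
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must be an (n, 3) array")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype="U16")
            if len(self.labels) != len(self.xyz):
                raise ValueError("labels must align with records")

    def __len__(self) -> int:
        return len(self.xyz)

    @property
    def x(self) -> np.ndarray:
        return self.xyz[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xyz[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.xyz[:, 2]


def default_models() -> tuple[BehaviorModel, ...]:
    """The shipped 8-class model set.

    Occupancy weights follow a realistic annotated-instance tally for a
    foraging shorebird (inactive and walk dominant; attack, fly and peck
    rare), except that fly is kept at ~3.5% of time rather than <1% so a
    dataset of ~100 bouts contains enough flight events to learn from.
    Behavioural changes must be visible on the surge (x)
    axis — the premise of x-driven segmentation — so class groups differ in
    x baseline (posture: probing forward-pitched, flight strongly pitched)
    and not just in variance. Handle shares search's posture and differs
    only by 1.5x the noise variance, so the pair is confusable by design;
    attack/peck are brief transients (0.25-0.75 s) distinguished by
    direction: attack surges forward (+x), peck drops the heave (z)
    baseline.
    """
    r15 = 1.5 ** 0.5  # handle sd = sqrt(1.5) * search sd
    return (
        BehaviorModel("inactive", (0.0, 0.0, 1.0), (0.02, 0.02, 0.02),
                      duration_mean=4.0, duration_min=0.5,
                      occupancy_weight=1177),
        BehaviorModel("walk", (0.10, 0.0, 1.0), (0.06, 0.05, 0.08),
                      periodic_amplitude=(0.25, 0.05, 0.20), periodic_freq=2.5,
                      duration_mean=2.5, duration_min=0.5,
                      occupancy_weight=853),
        BehaviorModel("fly", (0.45, 0.0, 1.0), (0.10, 0.08, 0.12),
                      periodic_amplitude=(0.30, 0.05, 0.50), periodic_freq=6.0,
                      duration_mean=3.0, duration_min=1.0,
                      occupancy_weight=100),
        BehaviorModel("search", (0.30, 0.0, 1.0), (0.08, 0.06, 0.08),
                      duration_mean=2.0, duration_min=0.3,
                      occupancy_weight=299),
        BehaviorModel("handle", (0.30, 0.0, 1.0),
                      (0.08 * r15, 0.06 * r15, 0.08 * r15),
                      duration_mean=3.0, duration_min=0.5,
                      occupancy_weight=169),
        BehaviorModel("body_care", (-0.10, 0.05, 1.0), (0.05, 0.07, 0.05),
                      duration_mean=2.0, duration_min=0.5,
                      occupancy_weight=67),
        BehaviorModel("attack", (0.80, 0.0, 1.0), (0.15, 0.10, 0.15),
                      duration_mean=0.5, duration_min=0.25,
                      occupancy_weight=37),
        BehaviorModel("peck", (0.35, 0.0, 0.60), (0.06, 0.04, 0.10),
                      duration_mean=0.6, duration_min=0.25,
                      occupancy_weight=47),
    )


def sample_behavior_sequence(
    total_duration: float,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[tuple[str, float]]:
    """Draw a semi-Markov behaviour sequence filling ``total_duration`` seconds.

    States are i.i.d. draws with probability proportional to
    occupancy_weight / duration_mean, so the expected fraction of TIME in a
    class equals its normalised occupancy weight. Dwells are shifted
    exponentials; the final dwell is truncated so the durations sum exactly
    to ``total_duration``.
    """
    if total_duration <= 0:
        raise ValueError("total_duration must be positive")
    models = config.models
    if not models:
        raise ConfigurationError("model set is empty")
    weights = np.array([m.occupancy_weight for m in models], dtype=float)
    if not np.any(weights > 0):
        raise ConfigurationError("occupancy weights must not all be zero")
    # per-dwell state probability: time share w_i requires draw rate w_i/mean_i
    draw_p = weights / np.array([m.duration_mean for m in models])
    draw_p /= draw_p.sum()

    sequence: list[tuple[str, float]] = []
    remaining = float(total_duration)
    while remaining > 1e-12:
        m = models[rng.choice(len(models), p=draw_p)]
        scale = m.duration_mean - m.duration_min
        dwell = m.duration_min + (rng.exponential(scale) if scale > 0 else 0.0)
        dwell = min(dwell, remaining)
        sequence.append((m.behavior, dwell))
        remaining -= dwell
    # close any float residue on the last dwell so the sum is exact
    drift = total_duration - sum(d for _, d in sequence)
    if sequence and drift != 0.0:
        name, d = sequence[-1]
        sequence[-1] = (name, d + drift)
    return sequence


def synthesize_bout(
    sequence: Sequence[tuple[str, float]],
    config: SimConfig,
    rng: np.random.Generator,
    bout_id: str = "bout",
    start_time: float = 0.0,
) -> AnnotatedBout:
    """Render a behaviour sequence into an annotated acceleration bout."""
    total = sum(d for _, d in sequence)
    if abs(total - config.bout_duration) > 1e-6:
        raise ValueError(
            f"sequence spans {total:.6f} s but the bout is "
            f"{config.bout_duration:.6f} s"
        )
    n = config.n_records
    rate = config.sample_rate
    xyz = np.empty((n, 3), dtype=float)
    labels = np.empty(n, dtype="U16")

    # map cumulative dwell times onto sample boundaries
    edges = np.rint(np.cumsum([0.0] + [d for _, d in sequence]) * rate).astype(int)
    edges[-1] = n
    edges = np.maximum.accumulate(edges)

    for (behavior, _), lo, hi in zip(sequence, edges[:-1], edges[1:]):
        if hi <= lo:  # dwell shorter than half a sample interval
            continue
        m = config.model(behavior)
        t = np.arange(hi - lo) / rate
        phase = rng.uniform(0.0, 2.0 * np.pi)
        for a in range(3):
            periodic = m.periodic_amplitude[a] * np.sin(
                2.0 * np.pi * m.periodic_freq * t + phase
            )
            noise = rng.normal(0.0, m.noise_sd[a], hi - lo)
            xyz[lo:hi, a] = m.baseline[a] + periodic + noise
        labels[lo:hi] = behavior
    return AnnotatedBout(bout_id, xyz, labels, sample_rate=rate,
                         start_time=start_time)


def simulate_dataset(
    config: SimConfig,
    n_bouts: int,
    seed: int,
    bout_spacing: float = 30.0,
) -> list[AnnotatedBout]:
    """Simulate ``n_bouts`` annotated bouts, reproducibly from ``seed``.

    Bout start times are spaced ``bout_spacing`` seconds apart (bouts in the
    field are separated by unmeasured gaps; the spacing only matters for
    time budgets).
    """
    if n_bouts < 1:
        raise ValueError("n_bouts must be >= 1")
    rng = np.random.default_rng(seed)
    bouts = []
    for i in range(n_bouts):
        seq = sample_behavior_sequence(config.bout_duration, config, rng)
        bouts.append(
            synthesize_bout(seq, config, rng, bout_id=f"bout{i:04d}",
                            start_time=i * bout_spacing)
        )
    return bouts
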