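"""Segmentation of acceleration bouts: sequential GLR change points or fixed windows.

Variable-time segmentation runs a sequential change-point monitor on the
surge (x) axis. Within the current stretch ``x[1..t]`` the generalized
likelihood ratio statistic for a split at ``k`` is

    D_k = t*log(s2_0) - k*log(s2_1) - (t-k)*log(s2_2),

where ``s2_0`` is the maximum-likelihood variance of the whole stretch and
``s2_1``/``s2_2`` those of the two sides; D_k is twice the Gaussian
log-likelihood ratio and responds to mean and/or variance changes. At each
new observation the monitor maximises D_k over admissible splits and raises
a boundary when the maximum exceeds a time-indexed threshold h_t.

Thresholds are calibrated by Monte-Carlo so that on change-free Gaussian
streams the conditional false-alarm hazard at every t is 1/ARL0 (constant
hazard), making the null run length approximately geometric with mean ARL0
— the detector's nominal average run length to a false positive. Monitoring
begins after ``startup`` observations of a stretch, and boundaries are
never placed closer than ``startup`` observations to the stretch start, so
every segment spans at least the startup interval.

Fixed-time segmentation simply tiles the bout with windows of constant
duration, keeping a shorter trailing window so the tiling is exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "EPS2",
    "SegmentationConfig",
    "Segment",
    "ThresholdTable",
    "glr_statistic",
    "calibrate_thresholds",
    "detect_change_points",
    "measure_run_lengths",
    "segment_bout_variable",
    "segment_bout_fixed",
    "segment_lengths",
]

#: Variance floor (g^2) applied inside every GLR evaluation so logs stay
#: finite on constant stretches. Used identically by the test oracles.
EPS2 = 1e-12


@dataclass(frozen=True)
class Segment:
    """Half-open record-index interval [start, end) within one bout."""

    bout_id: str
    start: int
    end: int
    label: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("need 0 <= start < end")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SegmentationConfig:
    """Which segmentation to run and with what parameters.

    ``mode='variable'`` needs ``arl0`` (nominal average run length, in
    observations) and ``startup``; ``mode='fixed'`` needs ``fixed_length``
    in seconds.
    """

    mode: str
    arl0: int | None = None
    startup: int = 20
    fixed_length: float | None = None
    sample_rate: float = 20.0

    def __post_init__(self) -> None:
        if self.mode not in ("variable", "fixed"):
            raise ConfigurationError("mode must be 'variable' or 'fixed'")
        if self.mode == "variable":
            if self.arl0 is None:
                raise ConfigurationError("variable mode requires arl0")
            if self.startup < 20:
                raise ConfigurationError("startup must be >= 20 observations")
        else:
            if self.fixed_length is None or self.fixed_length <= 0:
                raise ConfigurationError("fixed mode requires fixed_length > 0")

    @property
    def name(self) -> str:
        if self.mode == "variable":
            return f"variable_arl{self.arl0}"
        return f"fixed_{self.fixed_length:g}s"


def glr_statistic(sequence: Sequence[float], split: int) -> float:
    """GLR statistic for a mean/variance change at ``split`` (1-based count).

    ``split`` = k means the first k observations form the left side. Each
    side needs at least 2 points for a variance estimate, so
    2 <= k <= n - 2 and n >= 4.
    """
    x = np.asarray(sequence, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("sequence must have at least 4 observations")
    k = int(split)
    if not 2 <= k <= n - 2:
        raise ValueError(f"split must satisfy 2 <= k <= n-2, got {k} for n={n}")
    v0 = max(float(np.var(x)), EPS2)
    v1 = max(float(np.var(x[:k])), EPS2)
    v2 = max(float(np.var(x[k:])), EPS2)
    return n * np.log(v0) - k * np.log(v1) - (n - k) * np.log(v2)


def _prefix_sums(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    c1 = np.empty(x.shape[-1] + 1)
    c2 = np.empty_like(c1)
    c1[0] = c2[0] = 0.0
    np.cumsum(x, out=c1[1:])
    np.cumsum(x * x, out=c2[1:])
    return c1, c2


def _max_glr_prefix(c1: np.ndarray, c2: np.ndarray, t: int, kmin: int
                    ) -> tuple[float, int]:
    """Max-over-splits GLR of the first ``t`` observations, k in [kmin, t-2]."""
    k = np.arange(kmin, t - 1)
    if k.size == 0:
        return -np.inf, -1
    lv = np.maximum(c2[k] / k - (c1[k] / k) ** 2, EPS2)
    nk = t - k
    rv = np.maximum((c2[t] - c2[k]) / nk - ((c1[t] - c1[k]) / nk) ** 2, EPS2)
    cost = k * np.log(lv) + nk * np.log(rv)
    j = int(np.argmin(cost))
    v0 = max(c2[t] / t - (c1[t] / t) ** 2, EPS2)
    return t * np.log(v0) - cost[j], int(k[j])


def _max_glr_streams(c1: np.ndarray, c2: np.ndarray, rows: np.ndarray,
                     t: int, kmin: int) -> np.ndarray:
    """Vectorised max-over-splits GLR at prefix length ``t`` for many streams.

    ``c1``/``c2`` are (R, T+1) prefix-sum matrices; ``rows`` selects the
    streams still being monitored. Returns the max statistic per stream.
    """
    k = np.arange(kmin, t - 1)
    a1 = c1[np.ix_(rows, k)]
    a2 = c2[np.ix_(rows, k)]
    lv = a2 / k - (a1 / k) ** 2
    np.maximum(lv, EPS2, out=lv)
    tot1 = c1[rows, t][:, None]
    tot2 = c2[rows, t][:, None]
    nk = t - k
    rv = (tot2 - a2) / nk - ((tot1 - a1) / nk) ** 2
    np.maximum(rv, EPS2, out=rv)
    cost = k * np.log(lv) + nk * np.log(rv)
    cmin = cost.min(axis=1)
    v0 = np.maximum(tot2[:, 0] / t - (tot1[:, 0] / t) ** 2, EPS2)
    return t * np.log(v0) - cmin


def _null_threshold(g: np.ndarray, arl0: int, rng: np.random.Generator) -> float:
    """Threshold with expected null exceedance probability 1/arl0.

    If the sample is at least arl0 strong, return the (n+1-m)-th order
    statistic with m randomised so E[m] = (n+1)/arl0; by the probability
    integral transform its expected out-of-sample exceedance probability is
    exactly 1/arl0, with no distributional assumption. Otherwise anchor at
    the ~50th-from-top order statistic and extrapolate an exponential tail
    fitted to the mean excess above it.
    """
    n = g.size
    m_star = (n + 1) / arl0
    if m_star >= 1.0:
        m = int(m_star)
        if rng.random() < m_star - m:
            m += 1
        m = max(m, 1)
        return float(np.partition(g, n - m)[n - m])
    k = min(50, max(10, n // 10))
    u = float(np.partition(g, n - k - 1)[n - k - 1])
    exc = g[g > u] - u
    beta = float(exc.mean()) if exc.size else 0.0
    return u + beta * float(np.log(exc.size / n * arl0))


@dataclass
class ThresholdTable:
    """Detection thresholds h_t for the sequential GLR monitor.

    ``thresholds[t]`` is the alarm threshold at within-stretch observation
    count t, defined for t in [startup, max_length]; entries before the
    first possible alarm (t < startup + 2) are +inf. Beyond ``max_length``
    the table continues at the constant ``extrapolation[0]`` — the mean of
    the last calibrated stretch — because the survival-conditioned monitor
    reaches a quasi-stationary regime where the constant-hazard threshold
    no longer drifts.
    """

    arl0: int
    startup: int
    max_length: int
    thresholds: np.ndarray  # indexed by t, length max_length + 1
    extrapolation: tuple[float, float]
    n_reps: int
    seed: int

    def threshold_at(self, t: int) -> float:
        if t <= self.max_length:
            return float(self.thresholds[t])
        a, b = self.extrapolation
        return a + b * np.log(t)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "arl0": self.arl0,
            "startup": self.startup,
            "max_length": self.max_length,
            "thresholds": [None if not np.isfinite(v) else float(v)
                           for v in self.thresholds],
            "extrapolation": list(self.extrapolation),
            "n_reps": self.n_reps,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ThresholdTable":
        d = json.loads(Path(path).read_text())
        thr = np.array([np.inf if v is None else v for v in d["thresholds"]])
        return cls(d["arl0"], d["startup"], d["max_length"], thr,
                   tuple(d["extrapolation"]), d["n_reps"], d["seed"])


def calibrate_thresholds(
    arl0: int,
    max_length: int = 400,
    startup: int = 20,
    n_reps: int = 2000,
    seed: int = 0,
) -> ThresholdTable:
    """Calibrate h_t so the null false-alarm hazard is 1/arl0 at every t.

    ``n_reps`` i.i.d. standard-Gaussian streams of ``max_length``
    observations are monitored jointly. At each t the threshold is an
    upper order statistic of the max-GLR values among the n streams that
    have not yet alarmed: the (n+1-m)-th order statistic has out-of-sample
    exceedance probability m/(n+1) in expectation regardless of the
    underlying distribution (probability integral transform), so m is
    randomised between the two integers bracketing (n+1)/arl0 to make the
    expected false-alarm hazard exactly 1/arl0. Streams crossing the
    threshold are retired, so later thresholds are conditional on survival
    — the constant-hazard construction. When fewer than ~arl0 streams
    survive (always the case for very large arl0 such as 50000), the
    threshold extrapolates an exponential tail fitted to the top excesses,
    which keeps large-arl0 tables computable at desk scale at the cost of
    some tail-model bias there.
    """
    if arl0 < 100:
        raise ConfigurationError("arl0 must be >= 100")
    if n_reps < 100:
        raise ConfigurationError("n_reps must be >= 100 to estimate the tail")
    if startup < 20:
        raise ConfigurationError("startup must be >= 20")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_reps, max_length))
    c1 = np.zeros((n_reps, max_length + 1))
    c2 = np.zeros_like(c1)
    np.cumsum(x, axis=1, out=c1[:, 1:])
    np.cumsum(x * x, axis=1, out=c2[:, 1:])

    thresholds = np.full(max_length + 1, np.inf)
    alive = np.arange(n_reps)
    min_alive = 200
    t_first = startup + 2  # earliest t with an admissible split
    last_t = t_first - 1
    tail_pool: list[np.ndarray] = []  # alive G-samples of the last 100 steps
    for t in range(t_first, max_length + 1):
        if alive.size < min_alive:
            break
        g = _max_glr_streams(c1, c2, alive, t, kmin=startup)
        q = _null_threshold(g, arl0, rng)
        thresholds[t] = q
        alive = alive[g <= q]
        tail_pool.append(g)
        if len(tail_pool) > 100:
            tail_pool.pop(0)
        last_t = t

    # Constant continuation past the table: the monitor conditioned on
    # survival is quasi-stationary there, so a single level suffices. Pool
    # the surviving samples of the last 100 calibrated steps — a far larger
    # sample than any single step — and take its 1 - 1/arl0 level with the
    # same order-statistic / tail-fit rule.
    pooled = np.concatenate(tail_pool) if tail_pool else np.array([0.0])
    a = _null_threshold(pooled, arl0, rng)
    b = 0.0
    if last_t < max_length:
        thresholds[last_t + 1:] = a
    return ThresholdTable(arl0, startup, max_length, thresholds, (a, b),
                          n_reps, seed)


def detect_change_points(
    signal: Sequence[float],
    table: ThresholdTable,
    startup: int | None = None,
) -> list[int]:
    """Sequentially monitor ``signal`` and return detected boundary indices.

    Within the current stretch, once t >= startup the max-GLR over splits
    k in [startup, t-2] is compared against ``table.threshold_at(t)``; on
    an alarm the split argmax (mapped to an absolute index) is recorded and
    monitoring restarts from that boundary with a fresh startup count.
    Boundaries are therefore strictly increasing and at least ``startup``
    records apart.
    """
    x = np.asarray(signal, dtype=float)
    n = x.size
    if startup is None:
        startup = table.startup
    boundaries: list[int] = []
    s = 0
    while n - s >= startup + 2:
        c1, c2 = _prefix_sums(x[s:])
        m = n - s
        alarm = None
        for t in range(startup + 2, m + 1):
            g, khat = _max_glr_prefix(c1, c2, t, kmin=startup)
            if g > table.threshold_at(t):
                alarm = s + khat
                break
        if alarm is None:
            break
        boundaries.append(alarm)
        s = alarm
    return boundaries


def measure_run_lengths(
    table: ThresholdTable,
    n_streams: int,
    seed: int,
    max_t: int | None = None,
    block: int = 512,
) -> np.ndarray:
    """Observation count to first alarm on fresh null streams.

    Runs the same monitor as :func:`detect_change_points` on ``n_streams``
    i.i.d. N(0, 1) streams and returns the first alarm time of each (the
    run length). Streams still silent at ``max_t`` (default 8 * arl0, where
    under correct calibration < 0.05% of streams survive) are recorded at
    ``max_t``. Used for empirical ARL0 validation.
    """
    if max_t is None:
        max_t = 8 * table.arl0
    rng = np.random.default_rng(seed)
    startup = table.startup
    out = np.empty(n_streams, dtype=int)
    done = 0
    while done < n_streams:
        r = min(block, n_streams - done)
        x = rng.standard_normal((r, max_t))
        c1 = np.zeros((r, max_t + 1))
        c2 = np.zeros_like(c1)
        np.cumsum(x, axis=1, out=c1[:, 1:])
        np.cumsum(x * x, axis=1, out=c2[:, 1:])
        alarm = np.full(r, max_t, dtype=int)
        alive = np.arange(r)
        for t in range(startup + 2, max_t + 1):
            if alive.size == 0:
                break
            g = _max_glr_streams(c1, c2, alive, t, kmin=startup)
            hit = g > table.threshold_at(t)
            alarm[alive[hit]] = t
            alive = alive[~hit]
        out[done:done + r] = alarm
        done += r
    return out


def segment_bout_variable(bout, config: SegmentationConfig,
                          table: ThresholdTable) -> list[Segment]:
    """Variable-time segments of a bout from x-axis change points."""
    if config.mode != "variable":
        raise ConfigurationError("config.mode must be 'variable'")
    boundaries = detect_change_points(bout.x, table, startup=config.startup)
    edges = [0, *boundaries, len(bout)]
    return [Segment(bout.bout_id, lo, hi)
            for lo, hi in zip(edges[:-1], edges[1:])]


def segment_bout_fixed(bout, config: SegmentationConfig) -> list[Segment]:
    """Fixed-time windows tiling the bout; a shorter trailing window is kept."""
    if config.mode != "fixed":
        raise ConfigurationError("config.mode must be 'fixed'")
    if config.fixed_length is None or config.fixed_length <= 0:
        raise ValueError("fixed_length must be positive")
    w = round(config.fixed_length * bout.sample_rate)
    if w < 1:
        raise ValueError("fixed_length is below one sample interval")
    n = len(bout)
    return [Segment(bout.bout_id, lo, min(lo + w, n)) for lo in range(0, n, w)]


def segment_lengths(segments: Sequence[Segment]) -> list[int]:
    return [len(s) for s in segments]
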