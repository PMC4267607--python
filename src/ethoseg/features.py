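"""Segment summary statistics: 10 per axis plus ODBA, 31 in total.

Per axis a in {x, y, z}: mean, standard deviation, maximum, minimum,
skewness, kurtosis, dominant power spectrum value (dps), frequency at the
dominant power (fdps), trend, and dynamic body acceleration (dba). The
31st feature is ODBA, the sum of the three per-axis dba values — the
standard proxy for movement intensity.

Conventions (degenerate inputs must still yield finite features, so the
classifier never sees missing values):

* sd is the ddof-1 sample standard deviation (0 for a single sample).
* skewness = m3 / m2^1.5 and kurtosis = m4 / m2^2 with maximum-likelihood
  central moments; kurtosis is NON-excess (a Gaussian gives 3). A
  zero-variance segment reports skewness 0 and kurtosis 0.
* dps/fdps come from the periodogram |DFT(x - mean)|^2 / n of the demeaned
  signal, rectangular window, DC bin excluded; fdps is in Hz. A
  zero-variance (or single-sample) segment reports dps 0, fdps 0.
* trend is the least-squares slope of acceleration against time in
  seconds (g/s); 0 for fewer than 2 samples.
* dba is the mean absolute deviation from the segment mean (the "dynamic
  part" of the axis, with the static component taken as the per-segment
  mean).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .segmentation import Segment

__all__ = [
    "AXIS_STATS",
    "FEATURE_NAMES",
    "axis_summary",
    "odba",
    "compute_features",
    "features_dataframe",
]

AXIS_STATS = ("mean", "sd", "max", "min", "skew", "kurt", "dps", "fdps",
              "trend", "dba")

#: The fixed 31-name feature schema, in column order.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{stat}_{axis}" for axis in "xyz" for stat in AXIS_STATS
) + ("odba",)

_VAR_TOL = 1e-24  # below this m2 (g^2) a segment counts as constant


def axis_summary(samples: Sequence[float], sample_rate: float) -> dict[str, float]:
    """The 10 per-axis statistics of one segment's samples on one axis."""
    x = np.asarray(samples, dtype=float)
    n = x.size
    if n == 0:
        raise ValueError("axis_summary requires at least one sample")
    mean = float(x.mean())
    d = x - mean
    m2 = float(np.mean(d * d))
    out = {
        "mean": mean,
        "max": float(x.max()),
        "min": float(x.min()),
        "dba": float(np.mean(np.abs(d))),
    }
    out["sd"] = float(x.std(ddof=1)) if n > 1 else 0.0
    if m2 > _VAR_TOL:
        out["skew"] = float(np.mean(d ** 3)) / m2 ** 1.5
        out["kurt"] = float(np.mean(d ** 4)) / m2 ** 2
        dps, fdps = _dominant_power(d, sample_rate)
        out["dps"], out["fdps"] = dps, fdps
    else:
        out["skew"] = out["kurt"] = out["dps"] = out["fdps"] = 0.0
    if n > 1:
        t = np.arange(n) / sample_rate
        tc = t - t.mean()
        out["trend"] = float(np.dot(tc, d) / np.dot(tc, tc))
    else:
        out["trend"] = 0.0
    return out


def _dominant_power(demeaned: np.ndarray, sample_rate: float) -> tuple[float, float]:
    """(power, frequency) of the dominant non-DC periodogram bin."""
    n = demeaned.size
    if n < 2:
        return 0.0, 0.0
    p = np.abs(np.fft.rfft(demeaned)) ** 2 / n
    if p.size < 2:
        return 0.0, 0.0
    j = 1 + int(np.argmax(p[1:]))
    return float(p[j]), float(j * sample_rate / n)


def odba(x_dba: float, y_dba: float, z_dba: float) -> float:
    """Overall dynamic body acceleration: sum of the per-axis dba values."""
    if x_dba < 0 or y_dba < 0 or z_dba < 0:
        raise ValueError("per-axis dynamic body acceleration must be >= 0")
    return x_dba + y_dba + z_dba


def compute_features(bout, segment: Segment) -> dict[str, float]:
    """The 31-entry feature vector of one segment, keyed by FEATURE_NAMES."""
    n = len(bout)
    if not (0 <= segment.start < segment.end <= n):
        raise IndexError(
            f"segment [{segment.start}, {segment.end}) outside bout of {n} records"
        )
    out: dict[str, float] = {}
    dbas = []
    for col, axis in enumerate("xyz"):
        stats = axis_summary(bout.xyz[segment.start:segment.end, col],
                             bout.sample_rate)
        dbas.append(stats["dba"])
        for stat in AXIS_STATS:
            out[f"{stat}_{axis}"] = stats[stat]
    out["odba"] = odba(*dbas)
    return out


def features_dataframe(bouts: Iterable, segments: Iterable[Segment]) -> pd.DataFrame:
    """Feature table: one row per segment, id columns + the 31 features.

    Columns: bout_id, start, end, label (None when unassigned), then
    FEATURE_NAMES in order.
    """
    by_id = {b.bout_id: b for b in bouts}
    rows = []
    for seg in segments:
        bout = by_id[seg.bout_id]
        row = {"bout_id": seg.bout_id, "start": seg.start, "end": seg.end,
               "label": seg.label}
        row.update(compute_features(bout, seg))
        rows.append(row)
    cols = ["bout_id", "start", "end", "label", *FEATURE_NAMES]
    return pd.DataFrame(rows, columns=cols)
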