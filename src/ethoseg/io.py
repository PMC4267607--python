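"""CSV/JSON/INI file formats.

Tabular data are plain CSV:

* acceleration:  ``bout_id,sample_index,x,y,z``  (x/y/z in g, sample_index
  0-based and contiguous per bout)
* annotations:   ``bout_id,sample_index,behavior``
* segments:      ``bout_id,start,end,label``  (label empty before assignment)
* features:      segment id columns + the 31 feature columns

Threshold tables and performance reports are JSON (see their classes).
Simulator configurations are INI files with one section per behaviour
model plus a ``[simulation]`` section. Schema violations raise SchemaError
naming the offending content; absolute bout start times are not part of
the acceleration schema (bouts read from file start at time 0).
"""

from __future__ import annotations

import configparser
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError
from .ethogram import BEHAVIORS
from .features import FEATURE_NAMES
from .segmentation import Segment
from .simulator import AnnotatedBout, BehaviorModel, SimConfig

__all__ = [
    "read_acceleration_csv",
    "write_acceleration_csv",
    "write_annotation_csv",
    "read_segments_csv",
    "write_segments_csv",
    "read_features_csv",
    "write_features_csv",
    "read_sim_config",
    "write_sim_config",
]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing column(s): {', '.join(missing)}")


def write_acceleration_csv(bouts: Iterable[AnnotatedBout],
                           path: str | Path) -> None:
    frames = []
    for b in bouts:
        frames.append(pd.DataFrame({
            "bout_id": b.bout_id,
            "sample_index": np.arange(len(b)),
            "x": b.x, "y": b.y, "z": b.z,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_annotation_csv(bouts: Iterable[AnnotatedBout],
                         path: str | Path) -> None:
    frames = []
    for b in bouts:
        if b.labels is None:
            raise SchemaError(f"bout {b.bout_id} has no annotations to write")
        frames.append(pd.DataFrame({
            "bout_id": b.bout_id,
            "sample_index": np.arange(len(b)),
            "behavior": b.labels,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_acceleration_csv(
    path: str | Path,
    annotations: str | Path | None = None,
    sample_rate: float = 20.0,
) -> list[AnnotatedBout]:
    """Read bouts (and optionally join per-record behaviour annotations)."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ("bout_id", "sample_index", "x", "y", "z"),
                     "acceleration CSV")
    ann = None
    if annotations is not None:
        ann = pd.read_csv(annotations)
        _require_columns(ann, ("bout_id", "sample_index", "behavior"),
                         "annotation CSV")
        bad = ann.loc[~ann["behavior"].isin(BEHAVIORS), "behavior"]
        if len(bad):
            raise SchemaError(
                f"unknown behaviour {bad.iloc[0]!r} in annotations; valid "
                f"classes: {', '.join(BEHAVIORS)}")
    bouts = []
    for bout_id, grp in df.groupby("bout_id", sort=True):
        grp = grp.sort_values("sample_index")
        idx = grp["sample_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(idx))):
            gap = int(np.flatnonzero(idx != np.arange(len(idx)))[0])
            raise SchemaError(
                f"bout {bout_id}: sample_index not contiguous from 0 "
                f"(first problem at row with sample_index={idx[gap]})")
        labels = None
        if ann is not None:
            sub = ann[ann["bout_id"] == bout_id].sort_values("sample_index")
            if len(sub) != len(grp) or not np.array_equal(
                    sub["sample_index"].to_numpy(), idx):
                raise SchemaError(
                    f"bout {bout_id}: annotations do not cover every record")
            labels = sub["behavior"].to_numpy(dtype="U16")
        bouts.append(AnnotatedBout(str(bout_id),
                                   grp[["x", "y", "z"]].to_numpy(float),
                                   labels, sample_rate=sample_rate))
    return bouts


def write_segments_csv(segments: Iterable[Segment], path: str | Path) -> None:
    pd.DataFrame(
        [{"bout_id": s.bout_id, "start": s.start, "end": s.end,
          "label": "" if s.label is None else s.label} for s in segments]
    ).to_csv(path, index=False)


def read_segments_csv(path: str | Path) -> list[Segment]:
    df = pd.read_csv(path, keep_default_na=False)
    _require_columns(df, ("bout_id", "start", "end", "label"), "segment CSV")
    out = []
    for r in df.itertuples():
        label = None if r.label == "" else str(r.label)
        if label is not None and label not in BEHAVIORS:
            raise SchemaError(
                f"unknown behaviour {label!r} in segments; valid classes: "
                f"{', '.join(BEHAVIORS)}")
        out.append(Segment(str(r.bout_id), int(r.start), int(r.end), label))
    return out


def write_features_csv(features: pd.DataFrame, path: str | Path) -> None:
    features.to_csv(path, index=False)


def read_features_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False,
                     na_values=[], dtype={"label": str})
    _require_columns(df, ("bout_id", "start", "end", "label", *FEATURE_NAMES),
                     "feature CSV")
    df[list(FEATURE_NAMES)] = df[list(FEATURE_NAMES)].astype(float)
    return df


def write_sim_config(config: SimConfig, path: str | Path) -> None:
    cp = configparser.ConfigParser()
    cp["simulation"] = {
        "sample_rate": repr(config.sample_rate),
        "bout_duration": repr(config.bout_duration),
        "seed": repr(config.seed),
    }
    for m in config.models:
        cp[m.behavior] = {
            "baseline": " ".join(repr(v) for v in m.baseline),
            "noise_sd": " ".join(repr(v) for v in m.noise_sd),
            "periodic_amplitude": " ".join(repr(v) for v in
                                           m.periodic_amplitude),
            "periodic_freq": repr(m.periodic_freq),
            "duration_mean": repr(m.duration_mean),
            "duration_min": repr(m.duration_min),
            "occupancy_weight": repr(m.occupancy_weight),
        }
    with open(path, "w") as fh:
        cp.write(fh)


def read_sim_config(path: str | Path) -> SimConfig:
    cp = configparser.ConfigParser()
    if not cp.read(path):
        raise SchemaError(f"cannot read simulator config {path}")
    sim = cp["simulation"] if "simulation" in cp else {}
    models = []
    for section in cp.sections():
        if section == "simulation":
            continue
        s = cp[section]
        try:
            models.append(BehaviorModel(
                behavior=section,
                baseline=tuple(float(v) for v in s["baseline"].split()),
                noise_sd=tuple(float(v) for v in s["noise_sd"].split()),
                periodic_amplitude=tuple(
                    float(v) for v in s.get(
                        "periodic_amplitude", "0 0 0").split()),
                periodic_freq=float(s.get("periodic_freq", "0")),
                duration_mean=float(s["duration_mean"]),
                duration_min=float(s.get("duration_min", "0.25")),
                occupancy_weight=float(s.get("occupancy_weight", "1")),
            ))
        except (KeyError, ValueError) as exc:
            raise SchemaError(f"bad model section [{section}]: {exc}") from exc
    return SimConfig(
        models=tuple(models),
        sample_rate=float(sim.get("sample_rate", "20")),
        bout_duration=float(sim.get("bout_duration", "10")),
        seed=int(sim.get("seed", "0")),
    )
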