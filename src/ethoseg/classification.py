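"""Behaviour assignment, class rebalancing, random-forest evaluation.

Segments get the behaviour that covers most of their records (majority
rule). Rare classes are up-sampled with SMOTE — synthetic instances are
interpolated between a class member and one of its k nearest same-class
neighbours — with per-class factors (default: attack/fly/peck x6,
body_care/handle/search x2). A 500-tree random forest is trained on the 31
features and evaluated over repeated random 70/30 splits; performance is
scored at the level of individual acceleration records (each record
inherits its segment's predicted label), per class, with percentile
confidence intervals over the repetitions. Two segmentation settings are
compared per behaviour with a two-tailed Z-test on logit-transformed
per-repetition performance values.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special as spsp
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import NearestNeighbors

from .errors import ConfigurationError, DataError
from .ethogram import BEHAVIORS
from .features import FEATURE_NAMES, features_dataframe
from .segmentation import (
    Segment,
    SegmentationConfig,
    ThresholdTable,
    segment_bout_fixed,
    segment_bout_variable,
)

__all__ = [
    "OversamplingPlan",
    "EvaluationConfig",
    "PerformanceReport",
    "ComparisonResult",
    "assign_majority_label",
    "label_segments",
    "oversample",
    "train_classifier",
    "classify",
    "record_level_performance",
    "evaluate_resampling",
    "compare_performance",
    "time_budget",
]

#: Default per-class up-sampling factors (rare event classes x6,
#: intermediate classes x2, dominant classes untouched).
DEFAULT_FACTORS: dict[str, float] = {
    "attack": 6, "fly": 6, "peck": 6,
    "body_care": 2, "handle": 2, "search": 2,
    "inactive": 1, "walk": 1,
}


@dataclass(frozen=True)
class OversamplingPlan:
    factors: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FACTORS))
    k_neighbors: int = 5

    def __post_init__(self) -> None:
        if any(f < 1 for f in self.factors.values()):
            raise ConfigurationError("oversampling factors must be >= 1")
        if self.k_neighbors < 1:
            raise ConfigurationError("k_neighbors must be >= 1")


@dataclass(frozen=True)
class EvaluationConfig:
    train_fraction: float = 0.70
    n_reps: int = 1000
    seed: int = 0
    oversample_stage: str = "train_only"  # or "before_split"
    ci_level: float = 0.95
    split_unit: str = "segment"  # or "bout"

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ConfigurationError("train_fraction must be in (0, 1)")
        if self.n_reps < 2:
            raise ConfigurationError("n_reps must be >= 2")
        if self.oversample_stage not in ("train_only", "before_split"):
            raise ConfigurationError(
                "oversample_stage must be 'train_only' or 'before_split'")
        if self.split_unit not in ("segment", "bout"):
            raise ConfigurationError("split_unit must be 'segment' or 'bout'")


@dataclass
class PerformanceReport:
    """Per-class record-level performance samples over repetitions.

    ``samples[c]`` holds one value in [0, 1] per repetition in which class
    c had at least one true record in the test split. The summary gives the
    mean and the percentile confidence interval (2.5th/97.5th for the
    default 95% level); the band is widened to include the mean in the rare
    degenerate case where >97.5% of samples tie at one extreme.
    """

    samples: dict[str, list[float]]
    n_reps: int
    ci_level: float = 0.95
    meta: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        lo_q = (1 - self.ci_level) / 2
        rows = []
        for c in BEHAVIORS:
            vals = np.asarray(self.samples.get(c, ()), dtype=float)
            if vals.size == 0:
                continue
            mean = float(vals.mean())
            lo = min(float(np.quantile(vals, lo_q)), mean)
            hi = max(float(np.quantile(vals, 1 - lo_q)), mean)
            rows.append({"behavior": c, "n_valid_reps": int(vals.size),
                         "mean": mean, "ci_low": lo, "ci_high": hi})
        return pd.DataFrame(rows).set_index("behavior")

    def mean(self, behavior: str) -> float:
        return float(np.mean(self.samples[behavior]))

    def to_json(self, path: str | Path) -> None:
        payload = {"samples": self.samples, "n_reps": self.n_reps,
                   "ci_level": self.ci_level, "meta": self.meta}
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "PerformanceReport":
        d = json.loads(Path(path).read_text())
        return cls(d["samples"], d["n_reps"], d["ci_level"], d.get("meta", {}))


@dataclass(frozen=True)
class ComparisonResult:
    behavior: str
    z: float
    p: float
    n_a: int
    n_b: int


def assign_majority_label(segment: Segment, record_labels: np.ndarray) -> str:
    """The class covering most records of [start, end); ties go to the class
    occurring earliest within the segment."""
    if record_labels is None or len(record_labels) < segment.end:
        raise DataError(f"record labels do not cover segment {segment}")
    window = np.asarray(record_labels[segment.start:segment.end])
    classes, first_pos, counts = np.unique(window, return_index=True,
                                           return_counts=True)
    best = counts.max()
    tied = counts == best
    return str(classes[tied][np.argmin(first_pos[tied])])


def label_segments(bouts: Iterable, segments: Iterable[Segment]) -> list[Segment]:
    """Return segments with majority labels filled in from bout annotations."""
    by_id = {b.bout_id: b for b in bouts}
    out = []
    for seg in segments:
        bout = by_id[seg.bout_id]
        if bout.labels is None:
            raise DataError(f"bout {bout.bout_id} carries no annotations")
        out.append(Segment(seg.bout_id, seg.start, seg.end,
                           assign_majority_label(seg, bout.labels)))
    return out


def oversample(
    table: pd.DataFrame,
    plan: OversamplingPlan | None = None,
    seed: int = 0,
    strict: bool = True,
    return_provenance: bool = False,
):
    """SMOTE up-sampling of a labelled feature table.

    Each class count is multiplied by its plan factor (rounded to an
    integer): synthetic rows are drawn as parent + u * (neighbour - parent)
    with u ~ U(0, 1) and the neighbour one of the parent's k nearest
    same-class neighbours in feature space (k reduced to class size - 1
    when needed). Factor-1 classes pass through bitwise unchanged. Original
    rows keep ``synthetic = False``; synthetic rows get ``synthetic = True``
    and carry their parent's id columns.

    A class with factor > 1 but fewer than 2 instances raises DataError
    when ``strict``; with ``strict=False`` it is left as-is (used inside
    resampling loops where a rare class may reach a split as a singleton).
    """
    plan = plan or OversamplingPlan()
    rng = np.random.default_rng(seed)
    out = table.copy()
    out["synthetic"] = False
    feature_cols = [c for c in FEATURE_NAMES if c in table.columns]
    if not feature_cols:
        raise DataError("table contains no feature columns")
    parts = [out]
    prov_rows = []
    for cls in sorted(plan.factors):
        f = plan.factors[cls]
        if f <= 1:
            continue
        sub = out[out["label"] == cls]
        m = len(sub)
        if m == 0:
            continue
        if m < 2:
            if strict:
                raise DataError(
                    f"class {cls!r} has {m} instance(s); SMOTE with factor "
                    f"{f} needs at least 2")
            continue
        n_new = int(round(m * f)) - m
        if n_new <= 0:
            continue
        X = sub[feature_cols].to_numpy(dtype=float)
        k = min(plan.k_neighbors, m - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
        nbr = nn.kneighbors(X, return_distance=False)[:, 1:]  # drop self
        # every member parents floor(n_new/m) synthetics; remainder random
        parents = np.repeat(np.arange(m), n_new // m)
        rem = n_new - parents.size
        if rem:
            parents = np.concatenate(
                [parents, rng.choice(m, size=rem, replace=False)])
        pick = rng.integers(0, k, size=n_new)
        u = rng.random(n_new)
        neighbors = nbr[parents, pick]
        synth = X[parents] + u[:, None] * (X[neighbors] - X[parents])
        block = sub.iloc[parents].copy()
        block[feature_cols] = synth
        block["synthetic"] = True
        parts.append(block)
        if return_provenance:
            idx = sub.index.to_numpy()
            for p_i, n_i, u_i in zip(parents, neighbors, u):
                prov_rows.append({"label": cls, "parent": idx[p_i],
                                  "neighbor": idx[n_i], "u": u_i})
    result = pd.concat(parts, ignore_index=True)
    if return_provenance:
        return result, pd.DataFrame(prov_rows)
    return result


def train_classifier(table: pd.DataFrame, seed: int = 0) -> RandomForestClassifier:
    """Fit the 500-tree random forest (sqrt(31) = 5 features per split)."""
    if len(table) == 0:
        raise DataError("cannot train on an empty feature table")
    model = RandomForestClassifier(n_estimators=500, max_features="sqrt",
                                   random_state=seed, n_jobs=1)
    model.fit(table[list(FEATURE_NAMES)].to_numpy(),
              table["label"].to_numpy())
    return model


def classify(model: RandomForestClassifier, table: pd.DataFrame) -> np.ndarray:
    """Predicted behaviour per segment row (majority vote over trees)."""
    return model.predict(table[list(FEATURE_NAMES)].to_numpy())


def record_level_performance(
    segments: Sequence[Segment],
    predictions: Sequence[str],
    true_labels: Mapping[str, np.ndarray],
) -> dict[str, float]:
    """Per-class fraction of records whose segment-inherited predicted label
    matches the observed record label.

    ``true_labels`` maps bout_id to the per-record annotation array. Classes
    with no true records among the given segments are absent from the
    result.
    """
    if len(predictions) != len(segments):
        raise DataError("every segment needs exactly one prediction")
    true_count: dict[str, int] = {}
    hit_count: dict[str, int] = {}
    for seg, pred in zip(segments, predictions):
        if pred is None:
            raise DataError(f"segment {seg} has no prediction")
        labels = np.asarray(true_labels[seg.bout_id][seg.start:seg.end])
        classes, counts = np.unique(labels, return_counts=True)
        for c, n in zip(classes, counts):
            c = str(c)
            true_count[c] = true_count.get(c, 0) + int(n)
            if c == pred:
                hit_count[c] = hit_count.get(c, 0) + int(n)
    return {c: hit_count.get(c, 0) / n for c, n in true_count.items()}


def _config_hash(*objs) -> str:
    text = json.dumps([repr(o) for o in objs], sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def segment_dataset(
    bouts: Sequence,
    seg_config: SegmentationConfig,
    table: ThresholdTable | None = None,
) -> list[Segment]:
    """Segment every bout independently under one setting, with labels."""
    segments: list[Segment] = []
    for bout in bouts:
        if seg_config.mode == "variable":
            if table is None:
                raise ConfigurationError(
                    "variable-time segmentation needs a calibrated "
                    "ThresholdTable")
            segments.extend(segment_bout_variable(bout, seg_config, table))
        else:
            segments.extend(segment_bout_fixed(bout, seg_config))
    return label_segments(bouts, segments)


def evaluate_resampling(
    bouts: Sequence,
    seg_config: SegmentationConfig,
    eval_config: EvaluationConfig,
    plan: OversamplingPlan | None = None,
    table: ThresholdTable | None = None,
) -> PerformanceReport:
    """Record-level performance of one segmentation setting over repeated
    random train/test splits.

    Per repetition: split the labelled segments 70/30 (by segment, or by
    bout when ``split_unit='bout'``), SMOTE the training portion
    (``oversample_stage='train_only'``; 'before_split' instead augments the
    full table once, with only real segments ever scored), train the
    forest, classify the test segments, and tally record-level performance
    per class. Classes without true records in a repetition's test split
    contribute no sample for that repetition.
    """
    plan = plan or OversamplingPlan()
    labelled = segment_dataset(bouts, seg_config, table)
    if len(labelled) < 10:
        raise DataError(
            f"only {len(labelled)} labelled segments; need at least 10")
    feats = features_dataframe(bouts, labelled)
    true_labels = {b.bout_id: b.labels for b in bouts}

    if eval_config.oversample_stage == "before_split":
        feats = oversample(feats, plan, seed=eval_config.seed, strict=False)
    else:
        feats = feats.assign(synthetic=False)

    samples: dict[str, list[float]] = {c: [] for c in BEHAVIORS}
    n = len(feats)
    for rep in range(eval_config.n_reps):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=eval_config.seed, spawn_key=(rep,)))
        if eval_config.split_unit == "bout":
            ids = feats["bout_id"].unique()
            train_ids = set(rng.choice(
                ids, size=max(1, round(eval_config.train_fraction * len(ids))),
                replace=False))
            in_train = feats["bout_id"].isin(train_ids).to_numpy()
        else:
            n_train = max(1, round(eval_config.train_fraction * n))
            in_train = np.zeros(n, dtype=bool)
            in_train[rng.choice(n, size=n_train, replace=False)] = True
        train = feats[in_train]
        test = feats[~in_train & ~feats["synthetic"]]
        if len(test) == 0 or train["label"].nunique() == 0:
            continue
        if eval_config.oversample_stage == "train_only":
            train = oversample(train, plan,
                               seed=int(rng.integers(2 ** 31)), strict=False)
        model = train_classifier(train, seed=int(rng.integers(2 ** 31)))
        preds = classify(model, test)
        test_segments = [Segment(r.bout_id, r.start, r.end)
                         for r in test.itertuples()]
        perf = record_level_performance(test_segments, list(preds), true_labels)
        for c, v in perf.items():
            samples[c].append(v)

    samples = {c: v for c, v in samples.items() if v}
    meta = {
        "config_hash": _config_hash(seg_config, eval_config, plan),
        "seed": eval_config.seed,
        "segmentation": seg_config.name,
        "n_segments": len(labelled),
    }
    return PerformanceReport(samples, eval_config.n_reps,
                             eval_config.ci_level, meta)


def compare_performance(
    samples_a: Sequence[float],
    samples_b: Sequence[float],
    behavior: str = "",
    eps: float = 1e-3,
) -> ComparisonResult:
    """Two-tailed Z-test on logit-transformed performance samples.

    Values are clipped to [eps, 1 - eps] before the logit (exact 0% and
    100% performances otherwise have no logit). Z uses the two-sample
    unpooled (Welch) standard error; p = 2 * (1 - Phi(|Z|)). The statistic
    is antisymmetric in its arguments.
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DataError("both samples need at least 2 values")
    la = spsp.logit(np.clip(a, eps, 1 - eps))
    lb = spsp.logit(np.clip(b, eps, 1 - eps))
    diff = la.mean() - lb.mean()
    se = float(np.sqrt(la.var(ddof=1) / a.size + lb.var(ddof=1) / b.size))
    if se == 0.0:
        if diff == 0.0:
            return ComparisonResult(behavior, 0.0, 1.0, a.size, b.size)
        raise DataError("zero variance with unequal means: Z is undefined")
    z = float(diff / se)
    p = float(2 * sps.norm.sf(abs(z)))
    return ComparisonResult(behavior, z, p, a.size, b.size)


def time_budget(
    segments: Sequence[Segment],
    bouts: Sequence,
    bin_seconds: float = 3600.0,
) -> pd.DataFrame:
    """Per-time-bin proportion of classified time spent in each behaviour.

    Segment time spans (bout start_time + index / sample_rate) are split
    across bin edges proportionally; each bin's proportions sum to 1 over
    the behaviours present in it.
    """
    by_id = {b.bout_id: b for b in bouts}
    acc: dict[tuple[int, str], float] = {}
    for seg in segments:
        if seg.label is None:
            raise DataError(f"segment {seg} is unclassified")
        bout = by_id[seg.bout_id]
        t0 = bout.start_time + seg.start / bout.sample_rate
        t1 = bout.start_time + seg.end / bout.sample_rate
        while t0 < t1 - 1e-12:
            b = int(np.floor(t0 / bin_seconds))
            edge = (b + 1) * bin_seconds
            step = min(t1, edge) - t0
            acc[(b, seg.label)] = acc.get((b, seg.label), 0.0) + step
            t0 += step
    bins = sorted({b for b, _ in acc})
    classes = [c for c in BEHAVIORS if any((b, c) in acc for b in bins)]
    data = np.zeros((len(bins), len(classes)))
    for (b, c), v in acc.items():
        data[bins.index(b), classes.index(c)] = v
    data /= data.sum(axis=1, keepdims=True)
    return pd.DataFrame(data, columns=classes,
                        index=pd.Index([b * bin_seconds for b in bins],
                                       name="bin_start_s"))
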