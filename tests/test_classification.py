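"""Majority labels, SMOTE, random forest, record-level scoring, Z-test."""

import numpy as np
import pandas as pd
import pytest

from ethoseg import (
    FEATURE_NAMES,
    OversamplingPlan,
    assign_majority_label,
    classify,
    compare_performance,
    oversample,
    record_level_performance,
    time_budget,
    train_classifier,
)
from ethoseg.errors import ConfigurationError, DataError
from ethoseg.segmentation import Segment
from ethoseg.simulator import AnnotatedBout


def make_table(counts: dict[str, int], rng, shift=0.0) -> pd.DataFrame:
    rows = []
    for label, n in counts.items():
        for i in range(n):
            feats = dict(zip(FEATURE_NAMES, rng.normal(shift, 1.0, 31)))
            rows.append({"bout_id": f"{label}{i}", "start": 0, "end": 10,
                         "label": label, **feats})
    return pd.DataFrame(rows)


class TestMajorityLabel:
    def test_plain_majority(self):
        labels = np.array(["walk"] * 12 + ["search"] * 8)
        assert assign_majority_label(Segment("b", 0, 20), labels) == "walk"

    def test_tie_breaks_to_earliest_occurrence(self):
        labels = np.array(["walk"] * 10 + ["search"] * 10)
        assert assign_majority_label(Segment("b", 0, 20), labels) == "walk"
        labels = np.array(["search"] * 10 + ["walk"] * 10)
        assert assign_majority_label(Segment("b", 0, 20), labels) == "search"

    def test_homogeneous_and_missing(self):
        labels = np.array(["peck"] * 30)
        assert assign_majority_label(Segment("b", 5, 25), labels) == "peck"
        with pytest.raises(DataError):
            assign_majority_label(Segment("b", 0, 50), labels)


class TestOversample:
    def test_counts_multiply_exactly_by_factors(self, rng):
        table = make_table({"attack": 10, "walk": 30, "handle": 7}, rng)
        out = oversample(table, seed=1)
        counts = out["label"].value_counts()
        assert counts["attack"] == 60   # factor 6
        assert counts["handle"] == 14   # factor 2
        assert counts["walk"] == 30     # factor 1

    def test_factor_one_rows_pass_through_bitwise(self, rng):
        table = make_table({"walk": 12, "fly": 4}, rng)
        out = oversample(table, seed=3)
        walk_in = table[table.label == "walk"][list(FEATURE_NAMES)].to_numpy()
        walk_out = out[(out.label == "walk")][list(FEATURE_NAMES)].to_numpy()
        assert np.array_equal(walk_in, walk_out)

    def test_synthetics_lie_between_parent_and_neighbor(self, rng):
        table = make_table({"attack": 8}, rng)
        out, prov = oversample(table, seed=5, return_provenance=True)
        synth = out[out.synthetic][list(FEATURE_NAMES)].to_numpy()
        assert len(synth) == len(prov) == 8 * 5
        X = table[list(FEATURE_NAMES)].to_numpy()
        for row, (_, p) in zip(synth, prov.iterrows()):
            a, b, u = X[p.parent], X[p.neighbor], p.u
            assert np.allclose(row, a + u * (b - a), atol=1e-12)
            assert 0.0 <= u <= 1.0

    def test_neighbors_are_same_class_nearest(self, rng):
        table = make_table({"attack": 9, "walk": 9}, rng, shift=0.0)
        out, prov = oversample(table, seed=6, return_provenance=True)
        X = table[list(FEATURE_NAMES)].to_numpy()
        attack_idx = set(table.index[table.label == "attack"])
        for _, p in prov[prov.label == "attack"].iterrows():
            assert p.neighbor in attack_idx and p.parent in attack_idx
            # neighbor must rank among the parent's 5 nearest same-class rows
            others = sorted((i for i in attack_idx if i != p.parent),
                            key=lambda i: np.linalg.norm(X[i] - X[p.parent]))
            assert p.neighbor in others[:5]

    def test_singleton_minority_class_raises_named_error(self, rng):
        table = make_table({"attack": 1, "walk": 5}, rng)
        with pytest.raises(DataError, match="attack"):
            oversample(table, seed=1)
        out = oversample(table, seed=1, strict=False)
        assert (out.label == "attack").sum() == 1

    def test_reproducible(self, rng):
        table = make_table({"peck": 6, "search": 11}, rng)
        a = oversample(table, seed=42)
        b = oversample(table, seed=42)
        pd.testing.assert_frame_equal(a, b)


class TestForest:
    def test_separable_classes_interpolated_exactly(self, rng):
        table = pd.concat([make_table({"walk": 25}, rng, shift=0.0),
                           make_table({"fly": 25}, rng, shift=8.0)],
                          ignore_index=True)
        model = train_classifier(table, seed=0)
        assert (classify(model, table) == table["label"]).all()

    def test_single_class_degenerate_vote(self, rng):
        table = make_table({"peck": 10}, rng)
        model = train_classifier(table, seed=0)
        assert set(classify(model, table)) == {"peck"}

    def test_seeded_determinism(self, rng):
        table = make_table({"walk": 15, "search": 15}, rng, shift=0.3)
        p1 = classify(train_classifier(table, seed=9), table)
        p2 = classify(train_classifier(table, seed=9), table)
        assert np.array_equal(p1, p2)
        with pytest.raises(DataError):
            train_classifier(table.iloc[:0], seed=0)


class TestRecordLevelPerformance:
    def test_counting_rule_examples(self):
        labels = {"b": np.array(["walk"] * 10 + ["search"] * 10)}
        segs = [Segment("b", 0, 8), Segment("b", 8, 20)]
        perf = record_level_performance(segs, ["walk", "search"], labels)
        assert perf["walk"] == pytest.approx(8 / 10)
        assert perf["search"] == pytest.approx(1.0)
        perf = record_level_performance(segs, ["walk", "walk"], labels)
        assert perf == {"walk": 1.0, "search": 0.0}

    def test_agrees_with_brute_force_tally(self, rng):
        labels = {"b": rng.choice(["walk", "peck", "fly"], size=200)}
        edges = [0, 37, 80, 121, 150, 200]
        segs = [Segment("b", a, b) for a, b in zip(edges, edges[1:])]
        preds = list(rng.choice(["walk", "peck", "fly"], size=len(segs)))
        perf = record_level_performance(segs, preds, labels)
        # oracle: expand predictions to records, tally per class
        rec_pred = np.empty(200, dtype="U10")
        for s, p in zip(segs, preds):
            rec_pred[s.start:s.end] = p
        for c in ("walk", "peck", "fly"):
            mask = labels["b"] == c
            assert perf[c] == pytest.approx((rec_pred[mask] == c).mean())

    def test_missing_prediction_is_an_error(self):
        labels = {"b": np.array(["walk"] * 20)}
        with pytest.raises(DataError):
            record_level_performance([Segment("b", 0, 20)], [], labels)
        with pytest.raises(DataError):
            record_level_performance([Segment("b", 0, 20)], [None], labels)


class TestCompare:
    def test_identical_samples_null(self):
        r = compare_performance([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert r.z == pytest.approx(0.0, abs=1e-12)
        assert r.p == pytest.approx(1.0)

    def test_antisymmetry(self, rng):
        a, b = rng.uniform(0.2, 0.9, 40), rng.uniform(0.2, 0.9, 25)
        assert compare_performance(a, b).z == pytest.approx(
            -compare_performance(b, a).z, rel=1e-12)

    def test_matches_closed_form_on_logit_gaussian_samples(self, rng):
        from scipy.special import expit
        la = rng.normal(1.0, 0.4, 200)
        lb = rng.normal(0.7, 0.5, 150)
        r = compare_performance(expit(la), expit(lb))
        z_ref = (la.mean() - lb.mean()) / np.sqrt(
            la.var(ddof=1) / 200 + lb.var(ddof=1) / 150)
        assert r.z == pytest.approx(z_ref, rel=1e-9)
        import math
        p_ref = 2 * (1 - 0.5 * (1 + math.erf(abs(z_ref) / math.sqrt(2))))
        assert r.p == pytest.approx(p_ref, rel=1e-6)

    def test_exact_zero_and_one_are_clipped_not_fatal(self):
        r = compare_performance([0.0, 1.0, 0.5], [0.2, 0.4, 0.6])
        assert np.isfinite(r.z) and 0 <= r.p <= 1

    def test_degenerate_inputs(self):
        with pytest.raises(DataError):
            compare_performance([0.5], [0.4, 0.6])
        with pytest.raises(DataError):
            compare_performance([0.5, 0.5], [0.4, 0.4])


class TestTimeBudget:
    def _bouts(self):
        return [AnnotatedBout("b0", np.zeros((200, 3)), None,
                              start_time=0.0),
                AnnotatedBout("b1", np.zeros((200, 3)), None,
                              start_time=1800.0)]

    def test_single_class_bin_is_total(self):
        segs = [Segment("b0", 0, 200, "walk")]
        out = time_budget(segs, self._bouts())
        assert out.loc[0.0, "walk"] == pytest.approx(1.0)

    def test_even_split_is_half_half(self):
        segs = [Segment("b0", 0, 200, "walk"), Segment("b1", 0, 200, "inactive")]
        out = time_budget(segs, self._bouts(), bin_seconds=3600.0)
        assert out.loc[0.0, "walk"] == pytest.approx(0.5)
        assert out.loc[0.0, "inactive"] == pytest.approx(0.5)

    def test_bins_normalise_on_random_inputs(self, rng):
        bouts = [AnnotatedBout(f"b{i}", np.zeros((200, 3)), None,
                               start_time=float(rng.integers(0, 7200)))
                 for i in range(12)]
        segs = []
        for b in bouts:
            edges = sorted({0, 200, *rng.integers(1, 200, size=3)})
            for a, c in zip(edges, edges[1:]):
                segs.append(Segment(b.bout_id, a, c,
                                    str(rng.choice(["walk", "fly", "peck"]))))
        out = time_budget(segs, bouts, bin_seconds=600.0)
        assert np.allclose(out.sum(axis=1), 1.0)
        with pytest.raises(DataError):
            time_budget([Segment("b0", 0, 10)], bouts)


def test_plan_validation():
    with pytest.raises(ConfigurationError):
        OversamplingPlan(factors={"walk": 0.5})
    with pytest.raises(ConfigurationError):
        OversamplingPlan(k_neighbors=0)
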