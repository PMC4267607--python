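"""GLR statistic, sequential monitor, threshold tables, fixed windows."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ethoseg import (
    SegmentationConfig,
    SimConfig,
    calibrate_thresholds,
    detect_change_points,
    glr_statistic,
    segment_bout_fixed,
    segment_bout_variable,
    simulate_dataset,
)
from ethoseg.errors import ConfigurationError
from ethoseg.segmentation import EPS2, Segment


def glr_oracle(x, k):
    """Direct evaluation of the split statistic, shared variance floor."""
    x = np.asarray(x, float)
    n = len(x)
    v0 = max(np.var(x), EPS2)
    v1 = max(np.var(x[:k]), EPS2)
    v2 = max(np.var(x[k:]), EPS2)
    return n * np.log(v0) - k * np.log(v1) - (n - k) * np.log(v2)


class TestGlrStatistic:
    def test_identical_halves_give_zero(self):
        x = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        assert glr_statistic(x, 3) == pytest.approx(0.0, abs=1e-9)

    def test_known_two_level_sequence(self):
        # frozen from the direct-arithmetic oracle
        x = [0, 0, 1, 1, 0, 5, 5, 6, 6, 5]
        expected = glr_oracle(x, 5)
        assert expected == pytest.approx(32.9740, abs=1e-3)
        assert glr_statistic(x, 5) == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_sides_use_documented_floor(self):
        x = [1, 1, 1, 2, 2, 2]
        expected = 6 * np.log(0.25) - 6 * np.log(EPS2)
        assert glr_statistic(x, 3) == pytest.approx(expected, rel=1e-12)
        assert glr_statistic(x, 3) == pytest.approx(glr_oracle(x, 3))

    def test_agrees_with_oracle_on_random_sequences(self, rng):
        for _ in range(30):
            n = int(rng.integers(6, 60))
            x = rng.normal(size=n) * rng.uniform(0.5, 3)
            k = int(rng.integers(2, n - 1))
            assert glr_statistic(x, k) == pytest.approx(glr_oracle(x, k),
                                                        rel=1e-10, abs=1e-9)

    def test_invalid_split_rejected(self):
        with pytest.raises(ValueError):
            glr_statistic([1, 2, 3], 2)
        with pytest.raises(ValueError):
            glr_statistic([1, 2, 3, 4], 1)
        with pytest.raises(ValueError):
            glr_statistic([1, 2, 3, 4], 3)


class TestThresholdCalibration:
    def test_reproducible_from_seed(self):
        a = calibrate_thresholds(500, max_length=60, n_reps=300, seed=7)
        b = calibrate_thresholds(500, max_length=60, n_reps=300, seed=7)
        assert np.array_equal(a.thresholds, b.thresholds)
        assert a.extrapolation == b.extrapolation

    def test_higher_arl0_demands_pointwise_larger_thresholds(self):
        tables = [calibrate_thresholds(a, max_length=120, n_reps=2000, seed=3)
                  for a in (500, 5000, 50000)]
        t = np.arange(22, 121)
        for lo, hi in zip(tables, tables[1:]):
            assert all(hi.thresholds[i] >= lo.thresholds[i] for i in t)
            assert hi.threshold_at(500) >= lo.threshold_at(500)

    def test_parameter_validation(self):
        with pytest.raises(ConfigurationError):
            calibrate_thresholds(50, n_reps=500)
        with pytest.raises(ConfigurationError):
            calibrate_thresholds(500, n_reps=50)

    def test_json_round_trip(self, tmp_path, table50k):
        path = tmp_path / "thr.json"
        table50k.to_json(path)
        back = type(table50k).from_json(path)
        assert back.arl0 == table50k.arl0
        assert np.allclose(back.thresholds[22:], table50k.thresholds[22:])
        assert back.threshold_at(9999) == table50k.threshold_at(9999)


class TestDetection:
    def test_short_signal_returns_no_boundaries(self, table500):
        assert detect_change_points(np.zeros(21), table500) == []

    def test_boundaries_never_precede_startup(self, table500, rng):
        """Even an immediate large shift cannot be flagged before the
        monitor's startup count."""
        x = rng.normal(size=200)
        x[2:] += 8.0  # shift right after the stream begins
        boundaries = detect_change_points(x, table500)
        assert boundaries, "an 8 SD shift must be detected"
        assert boundaries[0] >= 20
        assert all(b2 - b1 >= 20 for b1, b2 in zip(boundaries, boundaries[1:]))

    def test_clear_shift_located_near_truth(self, table500, rng):
        x = rng.normal(size=200)
        x[100:] += 5.0
        hits = [b for b in detect_change_points(x, table500)
                if 95 <= b <= 110]
        assert len(hits) == 1

    def test_monotone_first_detection_in_arl0(self, rng):
        """Pointwise-larger thresholds cannot alarm earlier."""
        lo = calibrate_thresholds(500, max_length=250, n_reps=1200, seed=3)
        hi = calibrate_thresholds(50000, max_length=250, n_reps=1200, seed=3)
        for _ in range(10):
            x = rng.normal(size=200)
            x[60:] += 3.0
            b_lo = detect_change_points(x, lo)
            b_hi = detect_change_points(x, hi)
            t_lo = b_lo[0] if b_lo else 200
            t_hi = b_hi[0] if b_hi else 200
            assert t_hi >= t_lo - 20  # hi may localise the same change


class TestSegmentTiling:
    def test_fixed_windows_exact_arithmetic(self, small_dataset):
        bout = small_dataset[0]
        segs = segment_bout_fixed(
            bout, SegmentationConfig("fixed", fixed_length=1.0))
        assert [len(s) for s in segs] == [20] * 10
        segs = segment_bout_fixed(
            bout, SegmentationConfig("fixed", fixed_length=3.0))
        assert [len(s) for s in segs] == [60, 60, 60, 20]
        segs = segment_bout_fixed(
            bout, SegmentationConfig("fixed", fixed_length=0.5))
        assert len(segs) == 20

    @given(st.floats(min_value=0.25, max_value=7.0))
    def test_fixed_windows_partition_any_bout(self, length):
        bouts = simulate_dataset(SimConfig(), 1, seed=8)
        segs = segment_bout_fixed(
            bouts[0], SegmentationConfig("fixed", fixed_length=length))
        assert segs[0].start == 0 and segs[-1].end == 200
        for a, b in zip(segs, segs[1:]):
            assert a.end == b.start

    def test_variable_segments_tile_every_bout(self, small_dataset, table50k):
        config = SegmentationConfig("variable", arl0=50000)
        for bout in small_dataset:
            segs = segment_bout_variable(bout, config, table50k)
            assert segs[0].start == 0 and segs[-1].end == len(bout)
            assert all(a.end == b.start for a, b in zip(segs, segs[1:]))
            assert sum(len(s) for s in segs) == 200

    def test_boundaries_force_segment_edges(self, small_dataset, table500):
        bout = small_dataset[0]
        config = SegmentationConfig("variable", arl0=500)
        segs = segment_bout_variable(bout, config, table500)
        boundaries = detect_change_points(bout.x, table500)
        assert [s.start for s in segs] == [0, *boundaries]

    def test_segment_validation(self):
        with pytest.raises(ValueError):
            Segment("b", 5, 5)
        with pytest.raises(ConfigurationError):
            SegmentationConfig("variable")  # arl0 missing
        with pytest.raises(ConfigurationError):
            SegmentationConfig("fixed", fixed_length=-1.0)
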