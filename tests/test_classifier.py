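"""Fuzzy decision stage: memberships, point labeling, event extraction,
and the composed detector."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gammaspike import (
    BandPassSpec,
    ECoGRecord,
    FLCParams,
    SweepSpec,
    classify_points,
    detect,
    extract_events,
    match_events,
    membership_band,
    membership_raw,
    sweep,
)

FS = 1024.0


class TestMemberships:
    @pytest.mark.parametrize(
        "x,expected", [(20.0, 1.0), (-20.0, 1.0), (10.0, 0.0), (14.0, 1.0)]
    )
    def test_raw_step_rule(self, x, expected):
        assert membership_raw(x, 14.0) == expected

    @pytest.mark.parametrize(
        "y,lam2,expected", [(0.5, 0.1, 1.0), (0.05, 0.1, 0.0), (-0.95, 0.95, 1.0)]
    )
    def test_band_step_rule(self, y, lam2, expected):
        assert membership_band(y, lam2) == expected

    def test_graded_ramp_variant(self):
        # optional linear ramp: halfway at the threshold itself
        assert membership_raw(14.0, 14.0, transition_uv=2.0) == 0.5
        assert membership_raw(16.0, 14.0, transition_uv=2.0) == 1.0
        assert membership_raw(12.0, 14.0, transition_uv=2.0) == 0.0


class TestClassifyPoints:
    def _records(self, raw, band):
        return (
            ECoGRecord(np.asarray(raw, dtype=float), fs=FS),
            ECoGRecord(np.asarray(band, dtype=float), fs=FS),
        )

    @pytest.mark.parametrize(
        "raw,band,expected",
        [(20.0, 0.5, True), (20.0, 0.05, False), (10.0, 0.9, False)],
    )
    def test_if_and_then_rule(self, raw, band, expected):
        r, b = self._records([raw], [band])
        params = FLCParams(lambda1=14.0, lambda2=0.1)
        assert classify_points(r, b, params)[0] == expected

    @given(
        raw=st.lists(st.floats(-100, 100), min_size=1, max_size=50),
        lam2=st.floats(0.05, 0.95),
    )
    def test_equals_boolean_expression(self, raw, lam2):
        rng = np.random.default_rng(0)
        band = rng.uniform(-1, 1, len(raw))
        r, b = self._records(raw, band)
        params = FLCParams(lambda1=14.0, lambda2=lam2)
        mask = classify_points(r, b, params)
        expected = (np.abs(r.samples) >= 14.0) & (np.abs(b.samples) >= lam2)
        np.testing.assert_array_equal(mask, expected)

    def test_product_tnorm_same_for_crisp(self):
        rng = np.random.default_rng(1)
        r, b = self._records(rng.uniform(-30, 30, 200), rng.uniform(-1, 1, 200))
        pmin = FLCParams(tnorm="min")
        pprod = FLCParams(tnorm="product")
        np.testing.assert_array_equal(
            classify_points(r, b, pmin), classify_points(r, b, pprod)
        )

    def test_length_mismatch(self):
        r, b = self._records([1.0, 2.0], [0.5])
        with pytest.raises(ValueError):
            classify_points(r, b, FLCParams())


class TestExtractEvents:
    def test_single_run_peaks_at_max(self):
        n = 1024
        x = np.zeros(n)
        mask = np.zeros(n, dtype=bool)
        mask[100:108] = True  # ~8 ms run
        x[100:108] = [15, 16, 30, 22, 18, 16, 15, 14]
        result = extract_events(mask, ECoGRecord(x, fs=FS), FLCParams())
        assert len(result) == 1
        assert result.events[0].center_sample == 102
        assert result.events[0].peak_amplitude == 30.0
        assert result.events[0].duration_ms == pytest.approx(8 * 1000 / FS)

    def test_nearby_runs_merge(self):
        n = 1024
        x = np.abs(np.random.default_rng(2).normal(20, 2, n))
        mask = np.zeros(n, dtype=bool)
        mask[100:105] = True
        mask[110:115] = True  # ~5 ms gap < 10 ms merge gap
        result = extract_events(mask, ECoGRecord(x, fs=FS), FLCParams())
        assert len(result) == 1

    def test_distant_runs_stay_separate(self):
        n = 2048
        x = np.ones(n) * 20
        mask = np.zeros(n, dtype=bool)
        mask[100:105] = True
        mask[400:405] = True
        result = extract_events(mask, ECoGRecord(x, fs=FS), FLCParams())
        assert len(result) == 2

    def test_empty_mask(self):
        result = extract_events(
            np.zeros(100, dtype=bool), ECoGRecord(np.ones(100), fs=FS), FLCParams()
        )
        assert len(result) == 0

    def test_overlong_group_split_at_largest_gap(self):
        n = 2048
        x = np.ones(n) * 20
        mask = np.zeros(n, dtype=bool)
        # two 40 ms runs separated by an 8 ms gap: merged span ~88 ms > 70 ms
        mask[100 : 100 + 41] = True
        mask[149 : 149 + 41] = True
        result = extract_events(mask, ECoGRecord(x, fs=FS), FLCParams())
        assert len(result) == 2
        assert all(e.duration_ms <= 70.0 + 1e-9 for e in result.events)

    def test_gapless_overlong_run_truncated(self):
        n = 2048
        x = np.ones(n) * 20
        x[200] = 50.0
        mask = np.zeros(n, dtype=bool)
        mask[120:300] = True  # ~176 ms gapless
        result = extract_events(mask, ECoGRecord(x, fs=FS), FLCParams())
        assert all(e.duration_ms <= 70.0 + 1e-9 for e in result.events)


class TestDetect:
    def test_recovers_planted_spikes(self, small_scene):
        spec, record, annotations = small_scene
        result = detect(record)
        truth = annotations.spikes()
        m = match_events(result, truth, fs=record.fs)
        assert m.tp == len(truth)  # every planted spike recovered
        assert m.fp <= 1

    def test_monotone_in_lambda2(self, small_scene):
        _, record, _ = small_scene
        n_low = len(detect(record, params=FLCParams(lambda2=0.10)))
        n_high = len(detect(record, params=FLCParams(lambda2=0.95)))
        assert n_high <= n_low

    def test_pure_mains_artifact_yields_nothing(self):
        # λ1 passes everywhere, but the 80-120 Hz band holds no energy:
        # the band-isolation oracle (exact-bin tone -> zero band signal)
        # guarantees the AND rule never fires
        t = np.arange(int(10 * FS)) / FS
        rec = ECoGRecord(30.0 * np.sin(2 * np.pi * 50 * t), fs=FS)
        from gammaspike import fft_bandpass

        assert np.max(np.abs(fft_bandpass(rec).samples)) < 1e-9
        result = detect(rec)
        assert len(result) == 0

    def test_constant_offset_invariance(self, small_scene):
        _, record, _ = small_scene
        shifted = record.with_samples(record.samples + 123.4)
        a = detect(record)
        b = detect(shifted)
        assert list(a.centers()) == list(b.centers())

    def test_deterministic(self, small_scene):
        _, record, _ = small_scene
        assert detect(record) == detect(record)


class TestSweep:
    def test_grid_size_and_monotone_sensitivity(self, small_scene):
        _, record, annotations = small_scene
        result = sweep(record, annotations)
        assert len(result) == 18
        sens = [r.sensitivity for r in result]
        assert all(a >= b - 1e-9 for a, b in zip(sens, sens[1:]))

    def test_best_threshold_on_default_snr(self, small_scene):
        _, record, annotations = small_scene
        result = sweep(record, annotations)
        assert 0.10 <= result.best_lambda2 <= 0.20

    def test_custom_grid(self, small_scene):
        _, record, annotations = small_scene
        result = sweep(record, annotations, sweep_spec=SweepSpec((0.1, 0.5, 0.9)))
        assert len(result) == 3
        assert [r.lambda2 for r in result] == [0.1, 0.5, 0.9]
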