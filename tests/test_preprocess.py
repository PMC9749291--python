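import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctgmorse import (
    CTGRecord,
    FHRSignal,
    Stage,
    check_invariants,
    clean,
    find_missing_runs,
    interpolate_outliers_and_small_gaps,
    linear_interpolate,
    preprocess_pipeline,
    remove_long_gaps,
    remove_spikes,
    segment,
    trim_edges,
)
from ctgmorse.errors import EmptySignalError, SegmentTooShortError


def sig(values, fs=4.0) -> FHRSignal:
    return FHRSignal(np.asarray(values, dtype=float), fs=fs)


class TestMissingRuns:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([120, 0, 0, 0, 130], [(1, 3)]),
            ([120, 130, 140], []),
            ([0, 0, 120, 0], [(0, 2), (3, 1)]),
        ],
    )
    def test_maximal_runs(self, values, expected):
        assert find_missing_runs(np.asarray(values, float)) == expected


class TestLongGaps:
    def test_strictly_longer_than_15s_excised(self):
        body = [130.0] * 100 + [0.0] * 61 + [131.0] * 100
        out = remove_long_gaps(sig(body))
        assert len(out) == 200
        assert out.provenance.long_gaps_removed == 1
        assert out.provenance.samples_removed == 61

    def test_exactly_15s_retained(self):
        body = [130.0] * 100 + [0.0] * 60 + [131.0] * 100
        out = remove_long_gaps(sig(body))
        assert len(out) == 260
        assert out.provenance.long_gaps_removed == 0

    def test_identity_without_zeros(self):
        x = np.linspace(120, 150, 50)
        out = remove_long_gaps(sig(x))
        np.testing.assert_array_equal(out.samples, x)

    def test_never_alters_nonzero_values(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(60, 190, 400)
        x[50:150] = 0.0
        x[300:310] = 0.0
        out = remove_long_gaps(sig(x))
        np.testing.assert_array_equal(out.samples[out.samples != 0], x[x != 0])

    def test_all_missing_errors(self):
        with pytest.raises(EmptySignalError):
            remove_long_gaps(sig(np.zeros(400)))


class TestTrimEdges:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([0, 0, 140, 141, 0], [140, 141]),
            ([140, 141], [140, 141]),
            ([0] * 100 + [135, 136, 137] + [0] * 3, [135, 136, 137]),
        ],
    )
    def test_edge_runs_removed(self, values, expected):
        out = trim_edges(sig(values))
        np.testing.assert_array_equal(out.samples, expected)

    def test_all_zero_errors(self):
        with pytest.raises(EmptySignalError):
            trim_edges(sig(np.zeros(10)))


class TestLinearInterpolate:
    @pytest.mark.parametrize(
        "args,expected",
        [((0, 100, 2, 120, 1), 110.0), ((0, 100, 4, 100, 3), 100.0),
         ((10, 80, 14, 120, 11), 90.0)],
    )
    def test_examples(self, args, expected):
        assert linear_interpolate(*args) == pytest.approx(expected)

    def test_degenerate_anchor(self):
        with pytest.raises(ValueError):
            linear_interpolate(3, 100, 3, 120, 3)

    @given(
        x0=st.integers(0, 50),
        span=st.integers(2, 50),
        y0=st.floats(50, 200),
        y1=st.floats(50, 200),
        frac=st.floats(0.01, 0.99),
    )
    @settings(deadline=None)
    def test_agrees_with_numpy_interp(self, x0, span, y0, y1, frac):
        x1 = x0 + span
        x = x0 + frac * span
        ours = linear_interpolate(x0, y0, x1, y1, x)
        ref = np.interp(x, [x0, x1], [y0, y1])
        assert ours == pytest.approx(ref, abs=1e-9)


class TestOutlierInterpolation:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([120, 210, 124], [120, 122, 124]),
            ([100, 0, 0, 130], [100, 110, 120, 130]),
            ([60, 49, 61], [60, 60.5, 61]),
        ],
    )
    def test_examples(self, values, expected):
        out = interpolate_outliers_and_small_gaps(sig(values))
        np.testing.assert_allclose(out.samples, expected)
        assert out.provenance.samples_interpolated_linear == sum(
            1 for v in values if v == 0 or v < 50 or v > 200
        )

    def test_bounds_are_physiologic(self):
        # samples equal to 50 or 200 bpm are valid and untouched
        x = [50.0, 120.0, 200.0]
        out = interpolate_outliers_and_small_gaps(sig(x))
        np.testing.assert_array_equal(out.samples, x)

    def test_edge_outlier_extended_constantly(self):
        out = interpolate_outliers_and_small_gaps(sig([220, 120, 130]))
        np.testing.assert_allclose(out.samples, [120, 120, 130])


class TestSpikeRemoval:
    def test_isolated_spike_pulled_to_neighbors(self):
        x = np.full(40, 130.0)
        x[20] = 180.0
        out = remove_spikes(sig(x))
        assert abs(out.samples[20] - 130.0) <= 25.0
        assert out.provenance.samples_interpolated_spline >= 1

    def test_clean_signal_identity(self):
        x = 130.0 + 10 * np.sin(np.linspace(0, 6, 200))
        out = remove_spikes(sig(x))
        np.testing.assert_array_equal(out.samples, x)
        assert out.provenance.samples_interpolated_spline == 0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_output_has_no_large_deltas(self, seed):
        rng = np.random.default_rng(seed)
        x = 140.0 + np.cumsum(rng.uniform(-3, 3, 600))
        x = np.clip(x, 60, 190)
        for pos in rng.integers(10, 590, 6):
            x[pos] += rng.choice([-1, 1]) * rng.uniform(30, 55)
        x = np.clip(x, 50, 200)
        out = remove_spikes(sig(x))
        assert np.all(np.abs(np.diff(out.samples)) <= 25.0)

    def test_run_reaching_signal_end(self):
        x = np.full(30, 120.0)
        x[25:] = 170.0
        out = remove_spikes(sig(x))
        assert np.all(np.abs(np.diff(out.samples)) <= 25.0)


class TestSegmentation:
    def test_stage_windows(self):
        x = 130.0 + np.zeros(21000)
        s1 = segment(sig(x), Stage.STAGE1)
        s2 = segment(sig(x), Stage.STAGE2)
        assert len(s1) == 4800 and s1.start_index == 0
        assert len(s2) == 3600 and s2.start_index == 21000 - 3600

    def test_too_short_rejected(self):
        with pytest.raises(SegmentTooShortError):
            segment(sig(np.full(4000, 130.0)), Stage.STAGE1)


class TestPipeline:
    def test_clean_record_passes_through(self, clean_record):
        seg = preprocess_pipeline(clean_record, Stage.STAGE1)
        assert len(seg) == 4800
        out = clean(clean_record)
        prov = out.provenance
        assert (
            prov.long_gaps_removed,
            prov.samples_interpolated_linear,
            prov.samples_interpolated_spline,
            prov.edge_samples_trimmed,
        ) == (0, 0, 0, 0)
        np.testing.assert_array_equal(out.samples, clean_record.fhr)

    def test_invariants_and_idempotence(self, small_cohort):
        for rec, _label, _ledger in small_cohort[:6]:
            out = clean(rec)
            assert check_invariants(out.samples)
            again = clean(CTGRecord(rec.record_id, out.samples, fs=rec.fs, ph=rec.ph))
            np.testing.assert_array_equal(again.samples, out.samples)

    def test_all_zero_record_errors(self):
        rec = CTGRecord("z", np.zeros(100), fs=4.0)
        with pytest.raises(EmptySignalError):
            preprocess_pipeline(rec, Stage.STAGE1)
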