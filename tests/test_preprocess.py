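"""Conversion, filtering, segmentation and baseline correction contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirspace import (
    CONVERSION_MATRIX,
    EventList,
    FormatError,
    OpticalDensitySeries,
    bandpass,
    baseline_correct,
    od_to_chromophores,
    segment,
)
from nirspace.containers import ChromophoreSeries
from nirspace.preprocess import SegmentationError, SignalLengthError

FS = 13.3


def make_od(data):
    return OpticalDensitySeries(data=np.asarray(data, dtype=float), sample_rate=FS)


class TestConversion:
    def test_zero_od_gives_zero_chromophores(self):
        out = od_to_chromophores(make_od(np.zeros((2, 3, 4))))
        assert np.all(out.data == 0.0)

    def test_printed_first_column(self):
        # a unit OD change at 780 nm only
        data = np.zeros((1, 3, 1))
        data[0, 0, 0] = 1.0
        out = od_to_chromophores(make_od(data))
        assert out.data[0, 0, 0] == pytest.approx(1.8545, abs=1e-12)  # HbR
        assert out.data[0, 1, 0] == pytest.approx(-1.4887, abs=1e-12)  # HbO

    def test_matches_hand_rolled_matrix_product(self, rng):
        od = make_od(rng.standard_normal((3, 3, 7)))
        out = od_to_chromophores(od)
        # brute-force oracle: explicit loops, no linear-algebra calls
        for ch in range(3):
            for s in range(7):
                for row in range(2):
                    expected = 0.0
                    for w in range(3):
                        expected += CONVERSION_MATRIX[row, w] * od.data[ch, w, s]
                    assert abs(out.data[ch, row, s] - expected) <= 1e-12

    def test_wrong_wavelength_order_rejected(self):
        od = OpticalDensitySeries(
            data=np.zeros((1, 3, 2)), sample_rate=FS, wavelengths=(830, 805, 780)
        )
        with pytest.raises(FormatError):
            od_to_chromophores(od)

    @given(
        a=st.floats(-5, 5, allow_nan=False),
        b=st.floats(-5, 5, allow_nan=False),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_conversion_is_linear(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((2, 3, 5))
        y = rng.standard_normal((2, 3, 5))
        combo = od_to_chromophores(make_od(a * x + b * y)).data
        parts = a * od_to_chromophores(make_od(x)).data + b * od_to_chromophores(
            make_od(y)
        ).data
        assert np.allclose(combo, parts, atol=1e-9)


def _sinusoid_series(freq, duration=600.0, fs=FS):
    t = np.arange(0.0, duration, 1.0 / fs)
    data = np.sin(2 * np.pi * freq * t)[None, None, :] * np.ones((1, 2, 1))
    return ChromophoreSeries(data=data, sample_rate=fs), t


def _fitted_amplitude(x, t, freq):
    """Least-squares amplitude of a sinusoid of known frequency."""
    design = np.column_stack(
        [np.sin(2 * np.pi * freq * t), np.cos(2 * np.pi * freq * t)]
    )
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    return float(np.hypot(*coef))


class TestBandpass:
    @pytest.mark.parametrize(
        "freq, bound, kind",
        [(0.05, 0.05, "pass"), (1.0, 0.05, "stop")],
        ids=["in-band-0.05Hz", "cardiac-1.0Hz"],
    )
    def test_attenuation_contract(self, freq, bound, kind):
        series, t = _sinusoid_series(freq)
        out = bandpass(series)
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        amp = _fitted_amplitude(out.data[0, 0, mid], t[mid], freq)
        if kind == "pass":
            assert amp > 1.0 - bound  # < 5% attenuation
        else:
            assert amp < bound  # > 95% attenuation

    def test_dc_rejection(self):
        data = np.full((1, 2, 8000), 3.7)
        out = bandpass(ChromophoreSeries(data=data, sample_rate=FS))
        mid = slice(2000, 6000)
        assert np.abs(out.data[0, 0, mid]).max() < 1e-6 * 3.7

    def test_zero_phase_no_lag(self):
        series, t = _sinusoid_series(0.05, duration=800.0)
        out = bandpass(series)
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        x, y = series.data[0, 0, mid], out.data[0, 0, mid]
        lags = np.arange(-20, 21)
        xc = [np.dot(x, np.roll(y, lag)) for lag in lags]
        assert lags[np.argmax(xc)] == 0

    def test_output_length_equals_input(self):
        series, _ = _sinusoid_series(0.05, duration=120.0)
        assert bandpass(series).n_samples == series.n_samples

    def test_too_short_series_rejected(self):
        short = ChromophoreSeries(data=np.zeros((1, 2, 50)), sample_rate=FS)
        with pytest.raises(SignalLengthError):
            bandpass(short)


def _ramp_series(n=3000):
    data = np.arange(n, dtype=float)[None, None, :] * np.ones((2, 2, 1))
    return ChromophoreSeries(data=data, sample_rate=FS)


class TestSegment:
    def test_default_session_gives_sixty_epochs(self, default_session):
        od, events = default_session
        epochs = segment(od_to_chromophores(od), events)
        assert epochs.n_trials == 60
        assert epochs.data.shape[-1] == 213  # round(16 s * 13.3 Hz)
        assert abs(epochs.time_axis[0] - (-1.0)) < 1.0 / FS

    def test_degenerate_window_rejected(self):
        series = _ramp_series()
        events = EventList(onsets=[50.0], labels=["idle"])
        with pytest.raises(SegmentationError):
            segment(series, events, window=(0.0, 0.0))

    def test_out_of_bounds_event_named_in_error(self):
        series = _ramp_series(500)
        events = EventList(onsets=[5.0, 37.0], labels=["idle", "idle"])
        with pytest.raises(SegmentationError, match="37"):
            segment(series, events)

    def test_integer_sample_shift_equivariance(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal((1, 2, 4000))
        shift = 40  # samples
        shifted = np.roll(base, shift, axis=-1)
        onsets = np.array([30.0, 70.0, 110.0])
        ev = EventList(onsets=onsets, labels=["idle"] * 3)
        ev_shifted = EventList(onsets=onsets + shift / FS, labels=["idle"] * 3)
        a = segment(ChromophoreSeries(data=base, sample_rate=FS), ev)
        b = segment(ChromophoreSeries(data=shifted, sample_rate=FS), ev_shifted)
        assert np.array_equal(a.data, b.data)


class TestBaseline:
    def test_reference_mean_is_zero(self, default_epochs):
        mask = (default_epochs.time_axis >= -1.0) & (default_epochs.time_axis < 0.0)
        ref_means = default_epochs.data[:, :, :, mask].mean(axis=-1)
        assert np.abs(ref_means).max() < 1e-12

    def test_constant_epoch_becomes_zero(self):
        from nirspace.containers import ChromophoreEpochs

        n = 213
        time_axis = (np.arange(n) - 13) / FS
        epochs = ChromophoreEpochs(
            data=np.full((2, 1, 2, n), 5.0),
            time_axis=time_axis,
            labels=np.array(["idle", "idle"], dtype=object),
            sample_rate=FS,
        )
        out = baseline_correct(epochs)
        assert np.all(out.data == 0.0)

    def test_matches_manual_subtraction(self, rng):
        from nirspace.containers import ChromophoreEpochs

        n = 213
        time_axis = (np.arange(n) - 13) / FS
        data = rng.standard_normal((3, 2, 2, n))
        epochs = ChromophoreEpochs(
            data=data,
            time_axis=time_axis,
            labels=np.array(["idle"] * 3, dtype=object),
            sample_rate=FS,
        )
        out = baseline_correct(epochs)
        mask = (time_axis >= -1.0) & (time_axis < 0.0)
        manual = data - data[:, :, :, mask].mean(axis=-1, keepdims=True)
        assert np.allclose(out.data, manual, atol=1e-14)

    def test_reference_outside_epoch_rejected(self, default_epochs):
        with pytest.raises(ValueError):
            baseline_correct(default_epochs, ref=(20.0, 21.0))


def test_pipeline_preserves_trial_count_and_labels(default_session, default_epochs):
    od, events = default_session
    assert default_epochs.n_trials == len(events)
    assert np.array_equal(
        default_epochs.labels.astype(str), events.labels.astype(str)
    )
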