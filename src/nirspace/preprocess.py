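"""Preprocessing: Beer-Lambert conversion, band-pass, epoching, baseline.

The stage order is fixed: the continuous optical-density series is converted
to hemoglobin concentration changes, band-pass filtered on the continuous
record (a 0.01 Hz cutoff is meaningless on 16 s segments), segmented into
peri-onset epochs, and baseline-corrected against the pre-onset interval.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .containers import (
    WAVELENGTHS,
    ChromophoreEpochs,
    ChromophoreSeries,
    EventList,
    FormatError,
    OpticalDensitySeries,
)

__all__ = [
    "CONVERSION_MATRIX",
    "od_to_chromophores",
    "bandpass",
    "segment",
    "baseline_correct",
    "preprocess_session",
    "SegmentationError",
    "SignalLengthError",
]

#: Modified Beer-Lambert conversion for the (780, 805, 830) nm triple of the
#: Shimadzu LIGHTNIRS device (Matcher-style tabulated coefficients), mapping
#: the delta-OD triple to (delta-HbR, delta-HbO) in mM*cm.  Row order is
#: (HbR, HbO); column order is (780, 805, 830) nm.
CONVERSION_MATRIX = np.array(
    [
        [1.8545, -0.2394, -1.0947],
        [-1.4887, 0.5970, 1.4847],
    ]
)


class SignalLengthError(ValueError):
    """Series too short for stable zero-phase filtering."""


class SegmentationError(ValueError):
    """One or more event windows fall outside the recording."""


def od_to_chromophores(od: OpticalDensitySeries) -> ChromophoreSeries:
    """Convert optical-density changes to hemoglobin concentration changes.

    Applies the fixed 2x3 conversion matrix per sample:
    ``(dHbR, dHbO) = M @ (dOD_780, dOD_805, dOD_830)``, in mM*cm.

    Raises
    ------
    FormatError
        If the wavelength axis is not the ordered (780, 805, 830) triple.
    """
    if tuple(od.wavelengths) != WAVELENGTHS:
        raise FormatError(
            f"expected wavelengths {WAVELENGTHS}, got {tuple(od.wavelengths)}"
        )
    data = np.einsum("cw,kws->kcs", CONVERSION_MATRIX, od.data)
    return ChromophoreSeries(
        data=data, sample_rate=od.sample_rate, channel_ids=list(od.channel_ids)
    )


def _bandpass_sos(low: float, high: float, order: int, fs: float) -> np.ndarray:
    if not 0 < low < high < fs / 2:
        raise ValueError("need 0 < low < high < Nyquist")
    if order < 1:
        raise ValueError("order must be >= 1")
    return butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass(
    series: ChromophoreSeries,
    low: float = 0.01,
    high: float = 0.09,
    order: int = 6,
) -> ChromophoreSeries:
    """Zero-phase Butterworth band-pass on the continuous series.

    The ``order``-th order design is applied forward and backward
    (``sosfiltfilt``), giving zero phase distortion and an effective
    magnitude response of the squared design.  The default 0.01-0.09 Hz
    band isolates the task-locked hemodynamics while rejecting DC/drift,
    Mayer waves, respiration and cardiac pulsation.

    Raises
    ------
    SignalLengthError
        If the series is shorter than three times the filter's edge
        (startup) extension.
    """
    sos = _bandpass_sos(low, high, order, series.sample_rate)
    # same edge extension sosfiltfilt uses by default
    n_zero = min((sos[:, 2] == 0).sum(), (sos[:, 5] == 0).sum())
    padlen = 3 * (2 * len(sos) + 1 - n_zero)
    if series.n_samples <= 3 * padlen:
        raise SignalLengthError(
            f"series has {series.n_samples} samples; need more than "
            f"{3 * padlen} for stable zero-phase filtering"
        )
    filtered = sosfiltfilt(sos, series.data, axis=-1)
    return ChromophoreSeries(
        data=filtered,
        sample_rate=series.sample_rate,
        channel_ids=list(series.channel_ids),
    )


def segment(
    series: ChromophoreSeries,
    events: EventList,
    window: tuple[float, float] = (-1.0, 15.0),
) -> ChromophoreEpochs:
    """Cut one fixed-length epoch per event around its onset.

    The onset maps to the nearest sample (``round(onset * fs)``); the epoch
    covers ``[onset + window[0], onset + window[1])`` in a half-open sample
    convention with a length of ``round((window[1] - window[0]) * fs)``
    samples, identical for every trial (213 samples for the default 16 s
    window at 13.3 Hz).

    Raises
    ------
    SegmentationError
        Listing the offending events if any epoch extends outside the
        recording, or if the window is degenerate.
    """
    fs = series.sample_rate
    start_off = round(window[0] * fs)
    n_ep = round((window[1] - window[0]) * fs)
    if n_ep <= 0:
        raise SegmentationError(f"degenerate epoch window {window}")

    onset_idx = np.round(events.onsets * fs).astype(int)
    starts = onset_idx + start_off
    bad = np.flatnonzero((starts < 0) | (starts + n_ep > series.n_samples))
    if bad.size:
        raise SegmentationError(
            "epoch windows outside the recording for events at "
            f"onsets {events.onsets[bad].tolist()} (s)"
        )

    data = np.stack(
        [series.data[:, :, s : s + n_ep] for s in starts], axis=0
    )
    time_axis = (np.arange(n_ep) + start_off) / fs
    return ChromophoreEpochs(
        data=data,
        time_axis=time_axis,
        labels=events.labels.copy(),
        sample_rate=fs,
        channel_ids=list(series.channel_ids),
    )


def baseline_correct(
    epochs: ChromophoreEpochs, ref: tuple[float, float] = (-1.0, 0.0)
) -> ChromophoreEpochs:
    """Subtract the per-trial/channel/chromophore mean over the reference interval.

    ``ref`` is half-open ``[start, end)`` on the epoch time axis; after
    correction the reference-interval mean is zero to numerical precision.
    """
    mask = (epochs.time_axis >= ref[0]) & (epochs.time_axis < ref[1])
    if not mask.any():
        raise ValueError(
            f"reference interval {ref} contains no samples of the epoch "
            f"time axis [{epochs.time_axis[0]:.3f}, {epochs.time_axis[-1]:.3f}]"
        )
    baseline = epochs.data[:, :, :, mask].mean(axis=-1, keepdims=True)
    return ChromophoreEpochs(
        data=epochs.data - baseline,
        time_axis=epochs.time_axis.copy(),
        labels=epochs.labels.copy(),
        sample_rate=epochs.sample_rate,
        channel_ids=list(epochs.channel_ids),
    )


def preprocess_session(
    od: OpticalDensitySeries,
    events: EventList,
    low: float = 0.01,
    high: float = 0.09,
    order: int = 6,
    window: tuple[float, float] = (-1.0, 15.0),
    ref: tuple[float, float] = (-1.0, 0.0),
) -> ChromophoreEpochs:
    """Full preprocessing chain: convert, filter, segment, baseline-correct."""
    chromo = od_to_chromophores(od)
    filtered = bandpass(chromo, low=low, high=high, order=order)
    epochs = segment(filtered, events, window=window)
    return baseline_correct(epochs, ref=ref)
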