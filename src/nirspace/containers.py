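"""In-memory containers shared across the pipeline stages.

All arrays are plain :class:`numpy.ndarray` with fixed, documented axis
orders.  Axis conventions:

* optical density: ``(channels, wavelengths, samples)`` with the wavelength
  axis ordered ``(780, 805, 830)`` nm,
* chromophores: ``(channels, chromophores, samples)`` with the chromophore
  axis ordered ``(HbR, HbO)``,
* epochs: ``(trials, channels, chromophores, samples)``.

The HbR-first chromophore ordering mirrors the left-hand side of the
modified Beer-Lambert conversion used throughout (reduced hemoglobin above
oxygenated), so the conversion matrix can be applied without any axis
shuffling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical wavelength triple (nm) of the three-wavelength CW device the
#: synthetic sessions emulate.  The conversion matrix columns follow this
#: order.
WAVELENGTHS: tuple[float, float, float] = (780.0, 805.0, 830.0)

#: Chromophore axis order used everywhere: reduced then oxygenated hemoglobin.
CHROMOPHORES: tuple[str, str] = ("HbR", "HbO")

#: The two trial classes of the mental-arithmetic vs. rest paradigm.
CLASSES: tuple[str, str] = ("mental_arithmetic", "idle")


class FormatError(ValueError):
    """Raised when a series or file does not match the expected layout."""


@dataclass
class EventList:
    """Trial onsets (seconds from recording start) with class labels."""

    onsets: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.onsets.ndim != 1 or self.onsets.shape != self.labels.shape:
            raise FormatError("onsets and labels must be 1-D and equal length")
        if self.onsets.size and np.any(np.diff(self.onsets) <= 0):
            raise FormatError("onsets must be strictly increasing")
        unknown = set(self.labels) - set(CLASSES)
        if unknown:
            raise FormatError(f"unknown trial labels: {sorted(unknown)}")

    def __len__(self) -> int:
        return self.onsets.size


@dataclass
class OpticalDensitySeries:
    """Multi-channel, three-wavelength optical-density change time series.

    ``data`` is dimensionless delta-OD, shape ``(channels, wavelengths,
    samples)``; the wavelength axis must be ordered (780, 805, 830) nm so the
    hemoglobin conversion matrix applies directly.
    """

    data: np.ndarray
    sample_rate: float
    wavelengths: tuple[float, ...] = WAVELENGTHS
    channel_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.wavelengths = tuple(float(w) for w in self.wavelengths)
        if self.data.ndim != 3:
            raise FormatError("OD data must be (channels, wavelengths, samples)")
        if self.data.shape[1] != len(self.wavelengths):
            raise FormatError(
                f"wavelength axis has {self.data.shape[1]} entries for "
                f"{len(self.wavelengths)} wavelengths"
            )
        if not np.all(np.isfinite(self.data)):
            raise FormatError("OD data contains non-finite values")
        if self.sample_rate <= 0:
            raise FormatError("sample_rate must be positive")
        if not self.channel_ids:
            self.channel_ids = [f"CH{i + 1:02d}" for i in range(self.data.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds from recording start."""
        return np.arange(self.n_samples) / self.sample_rate


@dataclass
class ChromophoreSeries:
    """Continuous hemoglobin concentration changes, unit mM*cm.

    ``data`` has shape ``(channels, 2, samples)`` with the chromophore axis
    ordered ``(HbR, HbO)``.
    """

    data: np.ndarray
    sample_rate: float
    channel_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[1] != 2:
            raise FormatError("chromophore data must be (channels, 2, samples)")
        if self.sample_rate <= 0:
            raise FormatError("sample_rate must be positive")
        if not self.channel_ids:
            self.channel_ids = [f"CH{i + 1:02d}" for i in range(self.data.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate


@dataclass
class ChromophoreEpochs:
    """Trial-locked hemoglobin epochs on a common peri-onset time axis.

    ``data`` has shape ``(trials, channels, 2, samples)``; ``time_axis`` is in
    seconds relative to task onset and is shared by all trials.
    """

    data: np.ndarray
    time_axis: np.ndarray
    labels: np.ndarray
    sample_rate: float
    channel_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.data.ndim != 4 or self.data.shape[1:3][1] != 2:
            raise FormatError("epoch data must be (trials, channels, 2, samples)")
        if self.time_axis.shape != (self.data.shape[3],):
            raise FormatError("time_axis length must equal the sample axis")
        if self.labels.shape != (self.data.shape[0],):
            raise FormatError("labels length must equal the trial count")
        if not self.channel_ids:
            self.channel_ids = [f"CH{i + 1:02d}" for i in range(self.data.shape[1])]

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]
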