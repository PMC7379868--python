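"""Windowed temporal features: mean amplitude (AVG) and slope (SLP).

Features are computed per trial, chromophore, channel and time window on
the post-onset 0-15 s segment of each epoch.  Four window schemes tile that
interval: one 15 s window (TYPE 1), three 5 s windows (TYPE 2), five 3 s
windows (TYPE 3) and fifteen 1 s windows (TYPE 4).  The feature-vector
dimensionality is the product

    D = n_type * n_chrm * n_ch * n_win

of the number of feature types (1 or 2), chromophores (2), channels (16)
and windows, e.g. 1 * 2 * 16 * 15 = 480 for a single feature at TYPE 4.

Window membership uses a half-open ``[start, end)`` convention on sample
times so adjacent windows never share a sample despite the non-integer
13.3 Hz sampling rate.  Column order is fixed and documented
(feature-major, then chromophore, channel, window) so feature indices are
reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .containers import CHROMOPHORES, ChromophoreEpochs

__all__ = [
    "WindowScheme",
    "FeatureDescriptor",
    "FeatureMatrix",
    "avg_feature",
    "slp_feature",
    "feature_dimension",
    "build_feature_matrix",
]

#: Window counts of the four schemes over the 0-15 s post-onset interval.
_TYPE_WINDOWS = {1: 1, 2: 3, 3: 5, 4: 15}


@dataclass(frozen=True)
class WindowScheme:
    """A tiling of the post-onset interval into equal windows."""

    type_id: int
    boundaries: tuple[tuple[float, float], ...]

    @classmethod
    def from_type(cls, type_id: int, span: tuple[float, float] = (0.0, 15.0)) -> "WindowScheme":
        """Build the canonical TYPE 1-4 scheme tiling ``span``."""
        if type_id not in _TYPE_WINDOWS:
            raise ValueError(f"type_id must be one of {sorted(_TYPE_WINDOWS)}")
        n_win = _TYPE_WINDOWS[type_id]
        edges = np.linspace(span[0], span[1], n_win + 1)
        bounds = tuple((float(a), float(b)) for a, b in zip(edges[:-1], edges[1:]))
        return cls(type_id=type_id, boundaries=bounds)

    @property
    def n_windows(self) -> int:
        return len(self.boundaries)


class FeatureDescriptor(NamedTuple):
    """Provenance of one feature-matrix column."""

    feature: str  # "AVG" or "SLP"
    chromophore: str  # "HbR" or "HbO"
    channel: str
    window: tuple[float, float]

    def __str__(self) -> str:
        w0, w1 = self.window
        return f"{self.feature}:{self.chromophore}:{self.channel}:[{w0:g},{w1:g})"


@dataclass
class FeatureMatrix:
    """Trials x D feature table with per-column provenance."""

    values: np.ndarray
    columns: list[FeatureDescriptor]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be trials x D")
        if self.values.shape[1] != len(self.columns):
            raise ValueError("column descriptor count must equal D")
        if self.values.shape[0] != self.labels.size:
            raise ValueError("labels length must equal the trial count")
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("duplicate feature descriptors")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[str(c) for c in self.columns])
        df.insert(0, "label", self.labels)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _window_mask(time_axis: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    mask = (time_axis >= window[0]) & (time_axis < window[1])
    if not mask.any():
        raise ValueError(f"window {window} contains no samples")
    return mask


def avg_feature(series: np.ndarray, time_axis: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Mean amplitude over the samples whose times fall in ``[start, end)``.

    ``series`` may have any leading shape; the last axis is time.  Unit is
    that of the input (mM*cm for chromophore epochs).
    """
    mask = _window_mask(np.asarray(time_axis), window)
    return np.asarray(series)[..., mask].mean(axis=-1)


def slp_feature(
    series: np.ndarray,
    time_axis: np.ndarray,
    window: tuple[float, float],
    method: str = "ols",
) -> np.ndarray:
    """Rate of amplitude change over a window, in input units per second.

    ``method="ols"`` (default) returns the ordinary least-squares slope of
    value against time; ``method="endpoints"`` returns
    ``(last - first) / (t_last - t_first)``, a cruder alternative kept
    behind this switch for comparison.
    """
    mask = _window_mask(np.asarray(time_axis), window)
    t = np.asarray(time_axis)[mask]
    y = np.asarray(series)[..., mask]
    if t.size < 2:
        raise ValueError(f"window {window} contains fewer than 2 samples")
    if method == "endpoints":
        return (y[..., -1] - y[..., 0]) / (t[-1] - t[0])
    if method != "ols":
        raise ValueError("method must be 'ols' or 'endpoints'")
    tc = t - t.mean()
    return (y * tc).sum(axis=-1) / (tc * tc).sum()


def feature_dimension(n_type: int, n_chrm: int, n_ch: int, n_win: int) -> int:
    """Feature-vector dimensionality D = n_type * n_chrm * n_ch * n_win."""
    counts = (n_type, n_chrm, n_ch, n_win)
    if any(int(c) != c or c < 1 for c in counts):
        raise ValueError(f"all counts must be positive integers, got {counts}")
    return int(n_type) * int(n_chrm) * int(n_ch) * int(n_win)


_FEATURE_FUNCS = {"AVG": avg_feature, "SLP": slp_feature}


def build_feature_matrix(
    epochs: ChromophoreEpochs,
    features: Sequence[str] = ("AVG",),
    scheme: WindowScheme | int = 4,
    slope_method: str = "ols",
) -> FeatureMatrix:
    """Assemble the trials x D feature matrix for a window scheme.

    Columns are ordered feature-major, then chromophore (HbR, HbO), channel
    and window, and carry full provenance descriptors.  ``scheme`` may be a
    :class:`WindowScheme` or a TYPE id 1-4.
    """
    if isinstance(scheme, int):
        scheme = WindowScheme.from_type(scheme)
    features = list(features)
    if not features:
        raise ValueError("feature set must be non-empty")
    unknown = set(features) - set(_FEATURE_FUNCS)
    if unknown:
        raise ValueError(f"unknown features: {sorted(unknown)}")
    lo = epochs.time_axis[0]
    hi = epochs.time_axis[-1] + 1.0 / epochs.sample_rate
    for w0, w1 in scheme.boundaries:
        if w0 < lo or w1 > hi + 1e-9:
            raise ValueError(f"window ({w0}, {w1}) outside epoch range")

    blocks: list[np.ndarray] = []
    columns: list[FeatureDescriptor] = []
    for feat in features:
        for ci, chrom in enumerate(CHROMOPHORES):
            for ki, ch_id in enumerate(epochs.channel_ids):
                for window in scheme.boundaries:
                    kwargs = {"method": slope_method} if feat == "SLP" else {}
                    col = _FEATURE_FUNCS[feat](
                        epochs.data[:, ki, ci, :], epochs.time_axis, window, **kwargs
                    )
                    blocks.append(col)
                    columns.append(FeatureDescriptor(feat, chrom, ch_id, window))
    values = np.column_stack(blocks)
    expected = feature_dimension(
        len(features), len(CHROMOPHORES), epochs.n_channels, scheme.n_windows
    )
    assert values.shape[1] == expected
    return FeatureMatrix(values=values, columns=columns, labels=epochs.labels.copy())
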