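"""Synthetic two-class fNIRS sessions.

The generator emulates a block-design mental-arithmetic vs. idle paradigm
recorded by a 16-channel, three-wavelength (780/805/830 nm) continuous-wave
device sampled at 13.3 Hz: 30 task and 30 idle trials, 10 s task periods
followed by 24-26 s rest.  Task trials evoke a canonical hemodynamic
response (HbO increase, smaller HbR decrease) on a seeded subset of
"responsive" channels; every channel additionally carries slow physiological
oscillations (Mayer waves ~0.1 Hz, respiration ~0.3 Hz, cardiac ~1.0 Hz),
a linear drift and white noise.  Ground truth is generated in chromophore
space (mM*cm) and projected to optical density with the minimum-norm right
inverse of the hemoglobin conversion matrix, so the analysis pipeline's
conversion step recovers the simulated chromophores exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaln

from .containers import (
    CLASSES,
    WAVELENGTHS,
    ChromophoreSeries,
    EventList,
    OpticalDensitySeries,
)

__all__ = [
    "NoiseSpec",
    "SessionParams",
    "canonical_hrf",
    "simulate_chromophores",
    "forward_project",
    "simulate_session",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Amplitudes (mM*cm) of the nuisance components added to every channel.

    ``cardiac``, ``respiration`` and ``mayer`` are peak amplitudes of
    narrow-band oscillations at ~1.0, ~0.3 and ~0.1 Hz.  Each oscillation
    has a random initial phase per channel and a slowly diffusing phase
    (random walk of ``phase_diffusion`` rad per sqrt-second), giving the
    finite coherence time of real physiological rhythms rather than a
    session-long pure tone.  ``drift`` is the peak-to-peak magnitude bound
    of a linear trend over the session; ``white`` is the per-sample Gaussian
    standard deviation.
    ``hbr_scale`` scales all nuisance amplitudes on the HbR trace relative
    to HbO, reflecting the smaller magnitude of deoxygenated-hemoglobin
    fluctuations.
    """

    cardiac: float = 0.03
    respiration: float = 0.02
    mayer: float = 0.015
    drift: float = 0.05
    white: float = 0.01
    hbr_scale: float = 0.3

    cardiac_freq: float = 1.0
    respiration_freq: float = 0.3
    mayer_freq: float = 0.1
    phase_diffusion: float = 0.4


@dataclass(frozen=True)
class SessionParams:
    """Everything that defines one synthetic session.

    Amplitudes are in mM*cm (concentration change times path length, the
    native unit of the modified Beer-Lambert conversion).
    ``hrf_amplitude_hbo`` / ``hrf_amplitude_hbr`` are the peak evoked
    responses on responsive channels during mental-arithmetic trials; idle
    trials evoke nothing.
    """

    n_channels: int = 16
    sample_rate: float = 13.3
    wavelengths: tuple[float, float, float] = WAVELENGTHS
    n_trials_per_class: int = 30
    task_duration: float = 10.0
    rest_range: tuple[float, float] = (24.0, 26.0)
    hrf_amplitude_hbo: float = 0.05
    hrf_amplitude_hbr: float = -0.02
    trial_gain_sd: float = 0.2
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    responsive_channel_fraction: float = 0.5
    pre_session_rest: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.n_trials_per_class < 1:
            raise ValueError("need at least one trial per class")
        if self.sample_rate <= 0 or self.task_duration <= 0:
            raise ValueError("sample_rate and task_duration must be positive")
        lo, hi = self.rest_range
        if lo <= 0 or hi < lo:
            raise ValueError("rest_range must be a positive interval")
        if self.hrf_amplitude_hbo < 0 or self.hrf_amplitude_hbr > 0:
            raise ValueError("HbO amplitude must be >= 0 and HbR amplitude <= 0")
        if not 0 < self.responsive_channel_fraction <= 1:
            raise ValueError("responsive_channel_fraction must be in (0, 1]")

    def with_null_effect(self) -> "SessionParams":
        """Copy with evoked responses removed (class-exchangeable session)."""
        return replace(self, hrf_amplitude_hbo=0.0, hrf_amplitude_hbr=0.0)


def _gamma_pdf(t: np.ndarray, shape: float) -> np.ndarray:
    """Gamma density with unit rate, safe at t = 0 for shape > 1."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    out[pos] = np.exp(
        (shape - 1.0) * np.log(t[pos]) - t[pos] - gammaln(shape)
    )
    return out


def canonical_hrf(
    t: np.ndarray | float,
    peak_time: float = 6.0,
    undershoot_time: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Double-gamma hemodynamic impulse response, peak-normalized to 1.

    The response is zero at ``t = 0``, peaks near ``peak_time`` and shows a
    small undershoot around ``undershoot_time`` before decaying to ~0.
    Shapes are gamma densities with unit rate whose modes sit at the
    requested times, the conventional parameterization for task-evoked
    cortical hemodynamics.

    Parameters
    ----------
    t
        Time(s) in seconds, >= 0.
    peak_time, undershoot_time
        Positions (s) of the positive peak and the undershoot trough.
    undershoot_ratio
        Relative depth of the undershoot.
    """
    if peak_time <= 0 or undershoot_time <= 0 or undershoot_ratio < 0:
        raise ValueError("timing parameters must be positive")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    # mode of a unit-rate gamma with shape a is a - 1
    h = _gamma_pdf(t, peak_time + 1.0) - undershoot_ratio * _gamma_pdf(
        t, undershoot_time + 1.0
    )
    peak = _gamma_pdf(np.array([peak_time]), peak_time + 1.0)[0]
    return h / peak


def _evoked_kernel(params: SessionParams) -> np.ndarray:
    """Single-trial evoked waveform: boxcar(task) * HRF, peak-normalized."""
    fs = params.sample_rate
    hrf_t = np.arange(0.0, 32.0, 1.0 / fs)
    hrf = canonical_hrf(hrf_t)
    boxcar = np.ones(max(1, round(params.task_duration * fs)))
    resp = np.convolve(boxcar, hrf)
    return resp / np.max(np.abs(resp))


def simulate_chromophores(
    params: SessionParams,
) -> tuple[ChromophoreSeries, EventList]:
    """Simulate ground-truth HbR/HbO concentration changes plus events.

    Equal numbers of mental-arithmetic and idle trials are laid out in a
    seeded random order; each task onset is followed
    by ``task_duration`` seconds of stimulation and a rest interval drawn
    uniformly from ``rest_range``.  Only mental-arithmetic trials evoke a
    response, on the seeded responsive-channel subset, with a per-trial
    multiplicative gain jitter.  All channels carry the nuisance components
    of ``params.noise``.

    Returns
    -------
    series, events
        The noiseless-plus-noise chromophore series (channels x (HbR, HbO)
        x samples, mM*cm) and the trial onsets/labels.
    """
    rng = np.random.default_rng(params.seed)
    fs = params.sample_rate
    n_trials = 2 * params.n_trials_per_class

    rests = rng.uniform(*params.rest_range, size=n_trials)
    onsets = np.empty(n_trials)
    t = params.pre_session_rest
    for i in range(n_trials):
        onsets[i] = t
        t += params.task_duration + rests[i]
    # seeded random class order: under a null effect the two classes must be
    # exchangeable with respect to the slow noise, which a deterministic
    # alternation would violate (temporal neighbours always opposite-class)
    labels = np.array(
        [CLASSES[0]] * params.n_trials_per_class
        + [CLASSES[1]] * params.n_trials_per_class,
        dtype=object,
    )
    rng.shuffle(labels)
    events = EventList(onsets=onsets, labels=labels)

    duration = onsets[-1] + params.task_duration + 25.0
    n_samples = int(np.ceil(duration * fs))

    n_resp = max(1, round(params.responsive_channel_fraction * params.n_channels))
    responsive = rng.choice(params.n_channels, size=n_resp, replace=False)

    kernel = _evoked_kernel(params)
    evoked = np.zeros(n_samples)
    for onset, label in zip(onsets, labels):
        if label != "mental_arithmetic":
            continue
        gain = max(0.0, 1.0 + params.trial_gain_sd * rng.standard_normal())
        start = round(onset * fs)
        stop = min(n_samples, start + kernel.size)
        evoked[start:stop] += gain * kernel[: stop - start]

    data = np.zeros((params.n_channels, 2, n_samples))
    data[responsive, 0, :] += params.hrf_amplitude_hbr * evoked
    data[responsive, 1, :] += params.hrf_amplitude_hbo * evoked

    spec = params.noise
    times = np.arange(n_samples) / fs
    osc = (
        (spec.cardiac, spec.cardiac_freq),
        (spec.respiration, spec.respiration_freq),
        (spec.mayer, spec.mayer_freq),
    )
    dt = 1.0 / fs
    for ch in range(params.n_channels):
        for chrom, scale in ((0, spec.hbr_scale), (1, 1.0)):
            noise = np.zeros(n_samples)
            for amp, freq in osc:
                phase0 = rng.uniform(0.0, 2.0 * np.pi)
                # phase random walk: finite coherence time, as in real rhythms
                wander = np.cumsum(
                    spec.phase_diffusion * np.sqrt(dt) * rng.standard_normal(n_samples)
                )
                noise += amp * np.sin(2.0 * np.pi * freq * times + phase0 + wander)
            slope = spec.drift * rng.uniform(-1.0, 1.0)
            noise += slope * (times / max(times[-1], 1.0))
            noise += spec.white * rng.standard_normal(n_samples)
            data[ch, chrom, :] += scale * noise

    series = ChromophoreSeries(data=data, sample_rate=fs)
    return series, events


def forward_project(chromophores: ChromophoreSeries) -> OpticalDensitySeries:
    """Project chromophore concentrations to three-wavelength optical density.

    Uses the Moore-Penrose right inverse of the 2x3 hemoglobin conversion
    matrix, i.e. the minimum-norm delta-OD triple consistent with each
    (HbR, HbO) pair, so that converting the result back recovers the input
    to numerical precision.
    """
    from .preprocess import CONVERSION_MATRIX

    pinv = np.linalg.pinv(CONVERSION_MATRIX)  # 3 x 2
    od = np.einsum("wc,kcs->kws", pinv, chromophores.data)
    return OpticalDensitySeries(
        data=od,
        sample_rate=chromophores.sample_rate,
        wavelengths=WAVELENGTHS,
        channel_ids=list(chromophores.channel_ids),
    )


def simulate_session(
    params: SessionParams | None = None,
) -> tuple[OpticalDensitySeries, EventList]:
    """Simulate a full session as the device would deliver it: delta-OD."""
    params = params or SessionParams()
    chromo, events = simulate_chromophores(params)
    return forward_project(chromo), events
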