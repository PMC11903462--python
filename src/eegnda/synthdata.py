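"""Synthetic multi-channel EEG with embedded hand-action events.

Emulates the statistical structure of grasp-and-lift style recordings:
32 channels sampled at 500 Hz, six partially overlapping binary trigger
series marking ~0.3 s actions, class-specific spatiotemporal signatures
with configurable pre-onset lead and post-offset lag, and a 1/f-type
background. Also provides an exact fractional-Gaussian-noise generator
used to validate the Hurst-exponent estimator in :mod:`eegnda.dfa`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, NumericError, SizingError

#: Canonical order of the six action classes; the single source of truth
#: for every module that touches a trigger matrix or an events CSV.
CLASS_NAMES: tuple[str, ...] = (
    "HandStart",
    "FirstDigitTouch",
    "BothStartLoadPhase",
    "LiftOff",
    "Replace",
    "BothReleased",
)

N_CLASSES = len(CLASS_NAMES)

#: Default pre-onset signal extent (s) per class. HandStart, Replace and
#: BothReleased show anticipatory cortical activity well before movement
#: onset; the grasp/touch classes much less so.
DEFAULT_LEAD_TIMES: tuple[float, ...] = (0.4, 0.1, 0.1, 0.1, 0.4, 0.4)


@dataclass
class EEGRecording:
    """A channels x time voltage-like matrix with its sampling rate."""

    data: np.ndarray  # [n_channels, n_samples]
    sampling_rate: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ConfigurationError("recording data must be 2-D [channels, samples]")
        if not np.isfinite(self.data).all():
            raise ConfigurationError("recording contains non-finite values")
        if not self.channel_names:
            self.channel_names = [f"ch{i:02d}" for i in range(self.data.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EventTimeline:
    """Six binary trigger series aligned sample-for-sample with a recording."""

    triggers: np.ndarray  # [6, n_samples] in {0, 1}
    class_names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self) -> None:
        self.triggers = np.asarray(self.triggers)
        if self.triggers.ndim != 2 or self.triggers.shape[0] != len(self.class_names):
            raise ConfigurationError(
                f"trigger matrix must be [{len(self.class_names)}, n_samples]"
            )
        if not np.isin(self.triggers, (0, 1)).all():
            raise ConfigurationError("trigger values must be binary")
        self.triggers = self.triggers.astype(np.int8)

    @property
    def n_samples(self) -> int:
        return self.triggers.shape[1]

    def onsets(self, class_id: int) -> np.ndarray:
        """Start indices of the active runs of one trigger series."""
        t = self.triggers[class_id]
        d = np.diff(np.concatenate(([0], t)))
        return np.flatnonzero(d == 1)


@dataclass
class SynthConfig:
    """Parameters of the synthetic recording generator.

    ``snr`` is the peak amplitude of the injected class signature relative
    to the unit-variance background; 0 disables signal injection entirely.
    ``lead_time``/``lag_time`` may be scalars or per-class sequences (s).
    """

    n_channels: int = 32
    sampling_rate: float = 500.0
    duration: float = 120.0
    n_trials_per_class: int = 18
    action_duration: float = 0.3
    lead_time: float | Sequence[float] | None = None
    lag_time: float | Sequence[float] = 0.1
    snr: float = 1.0
    overlap_classes: tuple[int, int] | None = (1, 2)
    background_exponent: float = 1.0
    min_gap: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ConfigurationError("n_channels must be >= 1")
        if self.sampling_rate <= 0 or self.duration <= 0:
            raise ConfigurationError("sampling_rate and duration must be positive")
        if self.snr < 0:
            raise ConfigurationError("snr must be >= 0")
        if self.n_trials_per_class < 1:
            raise ConfigurationError("n_trials_per_class must be >= 1")
        if round(self.action_duration * self.sampling_rate) < 1:
            raise ConfigurationError(
                "action_duration must round to at least one sample"
            )
        if self.overlap_classes is not None:
            a, b = self.overlap_classes
            if not (0 <= a < N_CLASSES and 0 <= b < N_CLASSES) or a == b:
                raise ConfigurationError(
                    f"overlap_classes must be two distinct class indices in "
                    f"[0, {N_CLASSES - 1}], got {self.overlap_classes}"
                )

    # -- resolved (per-class, in samples) views ---------------------------

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))

    @property
    def action_samples(self) -> int:
        return int(round(self.action_duration * self.sampling_rate))

    def _per_class(self, value, default) -> np.ndarray:
        if value is None:
            value = default
        arr = np.atleast_1d(np.asarray(value, dtype=float))
        if arr.size == 1:
            arr = np.repeat(arr, N_CLASSES)
        if arr.size != N_CLASSES:
            raise ConfigurationError(
                f"per-class value must be scalar or length {N_CLASSES}"
            )
        if (arr < 0).any():
            raise ConfigurationError("lead/lag times must be >= 0")
        return arr

    @property
    def lead_samples(self) -> np.ndarray:
        secs = self._per_class(self.lead_time, DEFAULT_LEAD_TIMES)
        return np.round(secs * self.sampling_rate).astype(int)

    @property
    def lag_samples(self) -> np.ndarray:
        secs = self._per_class(self.lag_time, 0.1)
        return np.round(secs * self.sampling_rate).astype(int)


def _pink_background(
    rng: np.random.Generator, n_channels: int, n_samples: int, beta: float
) -> np.ndarray:
    """Spectrally shaped Gaussian noise, ~1/f^beta power, unit variance."""
    white = rng.standard_normal((n_channels, n_samples))
    if beta == 0:
        return white
    spectrum = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = freqs[nonzero] ** (-beta / 2.0)
    scale[0] = 0.0  # drop DC: EEG is high-pass filtered by acquisition
    shaped = np.fft.irfft(spectrum * scale, n=n_samples, axis=1)
    sd = shaped.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


def _place_onsets(config: SynthConfig, rng: np.random.Generator) -> list[list[int]]:
    """Schedule trial onsets per class, interleaving classes in time.

    Classes forced to overlap share onsets and occupy one scheduling slot.
    Returns a list of onset sample indices per class.
    """
    fs = config.sampling_rate
    lead = config.lead_samples
    lag = config.lag_samples
    act = config.action_samples

    groups: list[list[int]] = []
    if config.overlap_classes is not None:
        pair = sorted(config.overlap_classes)
        groups.append(list(pair))
        groups.extend([c] for c in range(N_CLASSES) if c not in pair)
    else:
        groups = [[c] for c in range(N_CLASSES)]

    head = int(lead.max())
    tail = act + int(lag.max())
    gap = int(round(config.min_gap * fs))
    n_events = len(groups) * config.n_trials_per_class
    usable = config.n_samples - head - tail
    slot = usable / n_events if n_events else 0
    if usable <= 0 or slot < gap + 1:
        raise SizingError(
            f"duration {config.duration}s cannot hold {n_events} trials with "
            f"min_gap {config.min_gap}s and lead/lag margins"
        )

    onsets: list[list[int]] = [[] for _ in range(N_CLASSES)]
    jitter_span = slot - gap
    for i in range(n_events):
        group = groups[i % len(groups)]
        onset = head + int(i * slot + rng.uniform(0, jitter_span))
        for c in group:
            onsets[c].append(onset)
    return onsets


def generate_eeg(config: SynthConfig) -> tuple[EEGRecording, EventTimeline]:
    """Generate a synthetic recording plus its aligned event timeline.

    The signal is a unit-variance 1/f^beta background plus, for each trial
    of each class, a damped-oscillation (Hann-windowed sinusoid) signature
    spanning ``[onset - lead, onset + action + lag)`` projected onto a
    class-specific channel-weight vector with peak amplitude ``snr``.
    Triggers mark ``[onset, onset + action)``. Deterministic given
    ``config.seed``; with ``snr = 0`` the random stream is consumed
    identically but no signature is added, so the injected field equals the
    difference between runs at two snr values.
    """
    rng = np.random.default_rng(config.seed)
    n_samples = config.n_samples
    act = config.action_samples
    lead = config.lead_samples
    lag = config.lag_samples
    fs = config.sampling_rate

    data = _pink_background(
        rng, config.n_channels, n_samples, config.background_exponent
    )

    # Class parameter draws happen unconditionally so the stream does not
    # depend on snr (keeps snr=0 runs background-identical).
    freqs = rng.uniform(6.0, 28.0, size=N_CLASSES)
    phases = rng.uniform(0, 2 * np.pi, size=N_CLASSES)
    weights = rng.standard_normal((N_CLASSES, config.n_channels))
    weights /= np.abs(weights).max(axis=1, keepdims=True)

    onsets = _place_onsets(config, rng)

    triggers = np.zeros((N_CLASSES, n_samples), dtype=np.int8)
    for c in range(N_CLASSES):
        span = lead[c] + act + lag[c]
        t = (np.arange(span) - lead[c]) / fs
        envelope = np.hanning(span)
        template = np.sin(2 * np.pi * freqs[c] * t + phases[c]) * envelope
        for onset in onsets[c]:
            triggers[c, onset : onset + act] = 1
            if config.snr > 0:
                lo = onset - lead[c]
                hi = lo + span
                data[:, lo:hi] += config.snr * np.outer(weights[c], template)

    recording = EEGRecording(data, fs)
    timeline = EventTimeline(triggers)
    return recording, timeline


def class_signature(config: SynthConfig, class_id: int) -> tuple[np.ndarray, int]:
    """The exact injected per-trial field for one class.

    Returns ``(field, lead_samples)`` where ``field`` is the
    [n_channels, span] matrix added at each trial (zero when snr = 0),
    anchored ``lead_samples`` before the trigger onset. Replays the
    generator's random stream, so it is an oracle for the injection.
    """
    rng = np.random.default_rng(config.seed)
    _pink_background(rng, config.n_channels, config.n_samples,
                     config.background_exponent)
    freqs = rng.uniform(6.0, 28.0, size=N_CLASSES)
    phases = rng.uniform(0, 2 * np.pi, size=N_CLASSES)
    weights = rng.standard_normal((N_CLASSES, config.n_channels))
    weights /= np.abs(weights).max(axis=1, keepdims=True)

    act = config.action_samples
    lead = int(config.lead_samples[class_id])
    span = lead + act + int(config.lag_samples[class_id])
    t = (np.arange(span) - lead) / config.sampling_rate
    envelope = np.hanning(span)
    template = np.sin(2 * np.pi * freqs[class_id] * t + phases[class_id]) * envelope
    return config.snr * np.outer(weights[class_id], template), lead


def fgn_autocovariance(hurst: float, lags: np.ndarray) -> np.ndarray:
    """Closed-form autocovariance of unit-variance fractional Gaussian noise.

    gamma(k) = 0.5 (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H}).
    """
    k = np.abs(np.asarray(lags, dtype=float))
    h2 = 2.0 * hurst
    return 0.5 * ((k + 1) ** h2 - 2 * k**h2 + np.abs(k - 1) ** h2)


def generate_fgn(hurst: float, length: int, seed: int) -> np.ndarray:
    """Exact fractional Gaussian noise via circulant embedding (Davies-Harte).

    Produces a zero-mean, unit-variance (in expectation) stationary Gaussian
    series whose autocovariance is exactly the fGn form for the requested
    Hurst exponent. ``hurst = 0.5`` reduces to i.i.d. Gaussian white noise.
    """
    if length < 2:
        raise SizingError("length must be >= 2")
    if not 0 < hurst <= 1:
        raise ConfigurationError("hurst must lie in (0, 1]")

    rng = np.random.default_rng(seed)
    m = 2 * length
    gamma = fgn_autocovariance(hurst, np.arange(length + 1))
    row = np.concatenate([gamma, gamma[-2:0:-1]])  # circulant first row, len m
    eigenvalues = np.fft.fft(row).real
    # fGn embeddings are nonnegative-definite; clip only float round-off.
    if eigenvalues.min() < -1e-8:  # pragma: no cover - theoretical impossibility
        raise NumericError("circulant embedding produced negative eigenvalues")
    eigenvalues = np.clip(eigenvalues, 0.0, None)

    w = np.zeros(m, dtype=complex)
    w[0] = np.sqrt(eigenvalues[0] / m) * rng.standard_normal()
    w[length] = np.sqrt(eigenvalues[length] / m) * rng.standard_normal()
    half = np.arange(1, length)
    a = rng.standard_normal(length - 1)
    b = rng.standard_normal(length - 1)
    w[half] = np.sqrt(eigenvalues[half] / (2 * m)) * (a + 1j * b)
    w[m - half] = np.conj(w[half])
    series = np.fft.fft(w).real[:length]
    return series
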