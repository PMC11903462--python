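"""Window extraction, offset labeling, normalization, noise injection, splits.

The "natural" noise augmentation enlarges the input window to N samples so
signal from neighboring, action-irrelevant regions enters each example;
the window's 6-bit label is read from the trigger matrix at a single index
controlled by ``offset`` (0 = window start, 0.5 = middle, 1 = end). The
"synthetic" augmentation adds i.i.d. Gaussian noise of standard deviation
sigma to the normalized signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, SizingError
from .synthdata import EEGRecording, EventTimeline

SPLIT_NAMES = ("train", "val", "test")


@dataclass
class WindowSpec:
    """How many windows of which length to draw, and where labels are read."""

    n_samples: int
    offset: float = 0.5
    count: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ConfigurationError("window length must be >= 1")
        if not 0.0 <= self.offset <= 1.0:
            raise ConfigurationError("offset must lie in [0, 1]")
        if self.count < 1:
            raise ConfigurationError("count must be >= 1")


@dataclass
class NoiseSpec:
    """Additive Gaussian noise: N(0, sigma^2) i.i.d. per channel and sample.

    By default the noise models the acquisition environment and is applied
    to all three splits; restrict ``apply_to`` for conventional train-only
    augmentation comparisons.
    """

    sigma: float
    apply_to: tuple[str, ...] = SPLIT_NAMES
    seed: int = 0
    mean: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ConfigurationError("sigma must be >= 0")
        if self.mean != 0.0:
            raise ConfigurationError("noise mean is fixed at 0")
        unknown = set(self.apply_to) - set(SPLIT_NAMES)
        if unknown:
            raise ConfigurationError(f"unknown split names in apply_to: {unknown}")


@dataclass
class WindowBatch:
    """Stacked windows with their labels and provenance."""

    data: np.ndarray  # [count, n_channels, N]
    labels: np.ndarray  # [count, 6] in {0, 1}
    starts: np.ndarray  # [count] start sample indices
    offset: float
    sigma: float = 0.0
    recording_length: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.starts = np.asarray(self.starts, dtype=np.int64)

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def window_length(self) -> int:
        return self.data.shape[2]

    def take(self, idx: np.ndarray) -> "WindowBatch":
        return replace(
            self, data=self.data[idx], labels=self.labels[idx], starts=self.starts[idx]
        )


def normalize(
    recording: EEGRecording,
    stats_from: np.ndarray | slice | None = None,
    stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[EEGRecording, tuple[np.ndarray, np.ndarray]]:
    """Per-channel z-scoring.

    Statistics (mean, std) are computed over ``stats_from`` sample indices
    only (all samples by default), or reused verbatim when ``stats`` is
    given — apply the training-set statistics to held-out data that way.
    Channels with zero standard deviation map to all-zeros.
    """
    if stats is None:
        idx = slice(None) if stats_from is None else stats_from
        ref = recording.data[:, idx]
        if ref.size == 0:
            raise ConfigurationError("stats_from selects no samples")
        mu = ref.mean(axis=1)
        sd = ref.std(axis=1)
    else:
        mu, sd = (np.asarray(s, dtype=float) for s in stats)
    safe_sd = np.where(sd == 0, 1.0, sd)
    out = (recording.data - mu[:, None]) / safe_sd[:, None]
    out[sd == 0, :] = 0.0
    return (
        EEGRecording(out, recording.sampling_rate, list(recording.channel_names)),
        (mu, sd),
    )


def label_index(start: int, n_samples_window: int, offset: float) -> int:
    """Sample index at which a window's ground-truth label is read.

    ``start + floor(offset * (N - 1))``: offset 0 labels the first sample,
    0.5 the middle, 1 the last.
    """
    if not 0.0 <= offset <= 1.0:
        raise ConfigurationError("offset must lie in [0, 1]")
    return int(start) + math.floor(offset * (n_samples_window - 1))


def sample_windows(
    recording: EEGRecording,
    timeline: EventTimeline,
    spec: WindowSpec,
    min_positive_fraction: float | None = None,
    dtype=np.float32,
) -> WindowBatch:
    """Draw windows uniformly at random from the whole timeline.

    Start indices are uniform over ``[0, n_samples - N]``; each window's
    label vector is the six trigger values at
    ``label_index(start, N, offset)``. With ``min_positive_fraction`` set,
    extra draws replace all-negative windows until at least that fraction
    of windows carries >= 1 positive label (off by default; the study draws
    uniformly, so negatives dominate).
    """
    n_total = recording.n_samples
    if timeline.n_samples != n_total:
        raise ConfigurationError("recording and timeline lengths differ")
    n = spec.n_samples
    if n > n_total:
        raise SizingError(f"window length {n} exceeds recording length {n_total}")

    rng = np.random.default_rng(spec.seed)
    starts = rng.integers(0, n_total - n + 1, size=spec.count)

    if min_positive_fraction is not None:
        label_at = starts + math.floor(spec.offset * (n - 1))
        positive = timeline.triggers[:, label_at].any(axis=0)
        need = math.ceil(min_positive_fraction * spec.count)
        attempts = 0
        while positive.sum() < need and attempts < 1000:
            redraw = np.flatnonzero(~positive)
            new = rng.integers(0, n_total - n + 1, size=redraw.size)
            starts[redraw] = new
            label_at = starts + math.floor(spec.offset * (n - 1))
            positive = timeline.triggers[:, label_at].any(axis=0)
            attempts += 1

    label_at = starts + math.floor(spec.offset * (n - 1))
    labels = timeline.triggers[:, label_at].T

    idx = starts[:, None] + np.arange(n)[None, :]
    data = recording.data[:, idx].transpose(1, 0, 2).astype(dtype)
    return WindowBatch(
        data=data,
        labels=labels,
        starts=starts,
        offset=spec.offset,
        sigma=0.0,
        recording_length=n_total,
    )


def add_gaussian_noise(batch: WindowBatch, noise: NoiseSpec) -> WindowBatch:
    """Return the batch with i.i.d. N(0, sigma^2) added to every entry.

    Labels and starts are untouched; sigma = 0 returns an identical copy.
    """
    if noise.sigma == 0:
        return replace(batch, data=batch.data.copy(), sigma=0.0)
    rng = np.random.default_rng(noise.seed)
    perturbed = batch.data + rng.normal(
        0.0, noise.sigma, size=batch.data.shape
    ).astype(batch.data.dtype)
    return replace(batch, data=perturbed, sigma=noise.sigma)


def _fold_sizes(n: int, fractions: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n items to the fractions."""
    raw = [f * n for f in fractions]
    sizes = [math.floor(r) for r in raw]
    remainder = n - sum(sizes)
    order = np.argsort([s - r for s, r in zip(sizes, raw)])  # most-short first
    for i in range(remainder):
        sizes[order[i]] += 1
    return sizes


def split(
    batch: WindowBatch,
    fractions: tuple[float, float, float] = (0.82, 0.09, 0.09),
    mode: str = "random",
    seed: int = 0,
) -> tuple[WindowBatch, WindowBatch, WindowBatch]:
    """Partition a batch into train/validation/test.

    ``random`` permutes windows before cutting (the study's protocol;
    overlapping windows may then span folds). ``time-blocked`` cuts the
    recording timeline into three contiguous segments proportional to the
    fractions and assigns each window to the segment holding its start —
    a leakage-safe alternative for synthetic validation.
    """
    if min(fractions) <= 0:
        raise ConfigurationError("split fractions must be positive")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError("split fractions must sum to 1")
    n = len(batch)
    if n < 3:
        raise SizingError("need at least 3 windows to split")

    if mode == "random":
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        sizes = _fold_sizes(n, fractions)
        cuts = np.cumsum(sizes)[:-1]
        parts = np.split(perm, cuts)
    elif mode == "time-blocked":
        total = batch.recording_length or int(batch.starts.max()) + batch.window_length
        bounds = np.cumsum([f * total for f in fractions])[:-1]
        fold = np.searchsorted(bounds, batch.starts, side="right")
        parts = [np.flatnonzero(fold == k) for k in range(3)]
    else:
        raise ConfigurationError(f"unknown split mode: {mode!r}")
    return tuple(batch.take(p) for p in parts)  # type: ignore[return-value]
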