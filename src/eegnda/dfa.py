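"""Detrended fluctuation analysis (DFA) and Hurst-exponent fits.

DFA characterizes long-range correlation in a series: integrate the
mean-centered series into a profile, split the profile into non-overlapping
windows of length n, remove a local polynomial trend in each window, and
measure the RMS residual F(n). For a self-affine process F(n) ~ n^H with H
the Hurst exponent: H = 0.5 for an uncorrelated process, H < 0.5
anti-persistent ("noisy"), H > 0.5 persistent long-range correlation.
Besides the full-range fit, slopes are fit separately for scales below and
above a band split (default 1000 samples = 2 s at 500 Hz), because short
EEG fragments scale differently from long ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, FitError, SizingError
from .sampling import NoiseSpec
from .synthdata import EEGRecording, EventTimeline


@dataclass
class DFAConfig:
    """Scale grid and detrending order for the fluctuation function.

    Scales are log-spaced (about ``scales_per_decade`` per decade) between
    ``min_scale`` and ``max_scale`` (default: series length / 4, capped at
    10000). ``detrend_order`` 1 is classic DFA-1.
    """

    min_scale: int = 8
    max_scale: int | None = None
    n_scales: int | None = None
    scales_per_decade: int = 20
    detrend_order: int = 1
    band_split: int = 1000

    def __post_init__(self) -> None:
        if self.detrend_order < 0:
            raise ConfigurationError("detrend_order must be >= 0")
        if self.min_scale < self.detrend_order + 2:
            raise ConfigurationError(
                "min_scale must be >= detrend_order + 2 for a defined residual"
            )

    def resolve_scales(self, length: int) -> np.ndarray:
        max_scale = self.max_scale
        if max_scale is None:
            max_scale = min(length // 4, 10000)
        if max_scale <= self.min_scale:
            raise SizingError(
                f"series of length {length} leaves no scales between "
                f"{self.min_scale} and {max_scale}"
            )
        n_scales = self.n_scales
        if n_scales is None:
            decades = np.log10(max_scale / self.min_scale)
            n_scales = max(int(round(decades * self.scales_per_decade)), 2)
        grid = np.geomspace(self.min_scale, max_scale, n_scales)
        return np.unique(np.round(grid).astype(int))


@dataclass
class DFAResult:
    """Fluctuation function and the three band-restricted Hurst fits."""

    scales: np.ndarray
    fluctuations: np.ndarray
    hurst_full: float
    hurst_low: float  # scales < band_split; NaN when the band is unusable
    hurst_high: float  # scales > band_split; NaN when the band is unusable
    intercept_full: float
    intercept_low: float
    intercept_high: float
    band_split: int

    def rounded(self) -> dict[str, float]:
        """H values rounded to 2 decimals, the precision reported in tables."""
        return {
            "hurst_full": round(self.hurst_full, 2),
            "hurst_low": round(self.hurst_low, 2),
            "hurst_high": round(self.hurst_high, 2),
        }


def profile(series) -> np.ndarray:
    """Cumulative sum of the mean-centered series (the DFA 'profile').

    The final value is always 0 (the centered series sums to zero), and the
    profile is invariant to adding a constant to the raw series.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise SizingError("series must be 1-D with length >= 2")
    return np.cumsum(x - x.mean())


def fluctuation_function(
    prof: np.ndarray, cfg: DFAConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """F(n) over the configured scale grid.

    For each scale n the profile is cut into floor(len/n) non-overlapping
    windows twice — once from the start and once from the end, so trailing
    samples are used when n does not divide the length — a polynomial of
    degree ``detrend_order`` is removed per window, and F(n) is the RMS of
    the residuals over all windows of both passes.
    """
    cfg = cfg or DFAConfig()
    prof = np.asarray(prof, dtype=float)
    length = prof.size
    scales = cfg.resolve_scales(length)

    kept_scales = []
    fluctuations = []
    for n in scales:
        n_win = length // n
        if n_win < 2:
            warnings.warn(f"scale {n} leaves fewer than 2 windows; dropped")
            continue
        used = n_win * n
        segments = np.concatenate(
            [
                prof[:used].reshape(n_win, n),
                prof[length - used :].reshape(n_win, n),
            ]
        )
        t = np.arange(n, dtype=float)
        design = np.vander(t, cfg.detrend_order + 1)
        # One pseudoinverse per scale; residuals for all windows at once.
        coef = segments @ np.linalg.pinv(design).T
        residuals = segments - coef @ design.T
        f2 = (residuals**2).mean(axis=1)
        kept_scales.append(n)
        fluctuations.append(np.sqrt(f2.mean()))
    if not kept_scales:
        raise ConfigurationError("every scale was dropped; check the scale grid")
    return np.array(kept_scales), np.array(fluctuations)


def hurst_fit(
    scales: np.ndarray,
    fluctuations: np.ndarray,
    fit_range: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """OLS slope (H) and intercept of log F(n) vs log n over ``fit_range``.

    Scales with F = 0 carry no information on a log scale and are excluded
    with a warning.
    """
    scales = np.asarray(scales, dtype=float)
    fluctuations = np.asarray(fluctuations, dtype=float)
    mask = np.ones_like(scales, dtype=bool)
    if fit_range is not None:
        lo, hi = fit_range
        mask &= (scales >= lo) & (scales <= hi)
    zero = fluctuations <= 0
    if (zero & mask).any():
        warnings.warn("zero fluctuation values excluded from the log-log fit")
        mask &= ~zero
    if mask.sum() < 2:
        raise FitError("fewer than 2 usable (n, F) points in the fit range")
    slope, intercept = np.polyfit(np.log(scales[mask]), np.log(fluctuations[mask]), 1)
    return float(slope), float(intercept)


def hurst_bands(series, cfg: DFAConfig | None = None) -> DFAResult:
    """Full DFA of a series: F(n) plus Hurst fits over three scale bands.

    ``hurst_full`` uses every computed scale; ``hurst_low`` only scales
    strictly below ``band_split``; ``hurst_high`` only scales strictly
    above it. A band with fewer than 2 usable scales is reported NaN while
    the others are still returned.
    """
    cfg = cfg or DFAConfig()
    scales, flucts = fluctuation_function(profile(series), cfg)
    h_full, b_full = hurst_fit(scales, flucts)

    def _band(lo: float, hi: float) -> tuple[float, float]:
        try:
            return hurst_fit(scales, flucts, (lo, hi))
        except FitError:
            warnings.warn(
                f"band [{lo}, {hi}] has fewer than 2 scales; reported as NaN"
            )
            return float("nan"), float("nan")

    h_low, b_low = _band(0, cfg.band_split - 1)
    h_high, b_high = _band(cfg.band_split + 1, np.inf)
    return DFAResult(
        scales=scales,
        fluctuations=flucts,
        hurst_full=h_full,
        hurst_low=h_low,
        hurst_high=h_high,
        intercept_full=b_full,
        intercept_low=b_low,
        intercept_high=b_high,
        band_split=cfg.band_split,
    )


def log_fluctuation_difference(
    result_a: DFAResult, result_b: DFAResult
) -> tuple[np.ndarray, np.ndarray]:
    """log F_a(n) - log F_b(n) at the scales the two results share."""
    common, ia, ib = np.intersect1d(
        result_a.scales, result_b.scales, return_indices=True
    )
    diff = np.log(result_a.fluctuations[ia]) - np.log(result_b.fluctuations[ib])
    return common, diff


def action_series(
    recording: EEGRecording,
    timeline: EventTimeline,
    class_id: int,
    pre: int = 0,
    post: int | None = None,
    noise: NoiseSpec | None = None,
    aggregate: str = "mean",
) -> np.ndarray:
    """Concatenated per-trial signal of one action class for DFA.

    For every trigger onset of ``class_id``, extracts
    ``[onset - pre, onset + post)`` samples from a channel aggregate (mean
    across channels by default, or one channel via ``aggregate="ch<i>"``),
    concatenates the trials in temporal order, and optionally adds i.i.d.
    Gaussian noise. Trials whose window exceeds the recording bounds are
    skipped with a warning.
    """
    onsets = timeline.onsets(class_id)
    if onsets.size == 0:
        raise SizingError(f"class {class_id} has no trigger runs")
    if post is None:
        runs = np.flatnonzero(
            np.diff(np.concatenate((timeline.triggers[class_id], [0]))) == -1
        )
        post = int(runs[0] - onsets[0]) + 1 if runs.size else 1
    if aggregate == "mean":
        signal = recording.data.mean(axis=0)
    elif aggregate.startswith("ch"):
        signal = recording.data[int(aggregate[2:])]
    else:
        raise ConfigurationError(f"unknown aggregate mode: {aggregate!r}")

    pieces = []
    for onset in onsets:
        lo, hi = onset - pre, onset + post
        if lo < 0 or hi > signal.size:
            warnings.warn(f"trial at sample {onset} exceeds bounds; skipped")
            continue
        pieces.append(signal[lo:hi])
    if not pieces:
        raise SizingError("every trial window fell outside the recording")
    series = np.concatenate(pieces)
    if noise is not None and noise.sigma > 0:
        rng = np.random.default_rng(noise.seed)
        series = series + rng.normal(0.0, noise.sigma, size=series.size)
    return series
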