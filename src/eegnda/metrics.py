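"""ROC-AUC (per class, micro, macro), steady-region statistics, LOWESS.

AUC follows the rank (Mann-Whitney) formulation: the probability that a
random positive outranks a random negative, ties counted 1/2. "Micro"
pools label/score pairs across all classes before ranking; "macro" is the
unweighted mean of per-class AUCs. Classes without both a positive and a
negative example have undefined AUC and are excluded and flagged, never
silently scored 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .errors import SizingError, UndefinedAUCError


@dataclass
class SweepRecord:
    """Per-(N, offset, sigma) evaluation of one trained checkpoint."""

    n_samples: int
    offset: float
    sigma: float
    per_class_auc: np.ndarray  # 6 values, NaN where undefined
    micro_auc: float
    macro_auc: float
    checkpoint: str  # "best_loss" | "best_acc"
    seed: int

    def __post_init__(self) -> None:
        self.per_class_auc = np.asarray(self.per_class_auc, dtype=float)
        valid = self.per_class_auc[~np.isnan(self.per_class_auc)]
        if valid.size and not ((valid >= 0) & (valid <= 1)).all():
            raise ValueError("AUC values must lie in [0, 1]")
        if valid.size and abs(self.macro_auc - valid.mean()) > 1e-12:
            raise ValueError("macro_auc must equal the mean of per-class AUCs")


@dataclass
class SteadyStats:
    """Summary of a metric-vs-N series over a steady region of N."""

    region: tuple[float, float]
    mean: float
    std: float
    max: float
    min: float
    n_points: int

    @property
    def range(self) -> float:
        return self.max - self.min


def roc_auc(labels, scores) -> float:
    """ROC-AUC of binary ``labels`` against real ``scores``.

    Raises :class:`UndefinedAUCError` when labels are single-class; callers
    record such cells as missing rather than defaulting to 0.5.
    """
    labels = np.asarray(labels).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have the same length")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    if labels.min() == labels.max():
        raise UndefinedAUCError(
            "AUC undefined: labels contain a single class"
        )
    return float(roc_auc_score(labels, scores))


def micro_macro(labels, scores) -> tuple[float, float, np.ndarray]:
    """Micro AUC, macro AUC and the per-class AUC vector.

    ``labels`` and ``scores`` are [count, n_classes]. Degenerate classes
    (all-positive or all-negative) get NaN and are excluded from the macro
    mean; micro pools every (label, score) pair across classes.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape or labels.ndim != 2:
        raise ValueError("labels and scores must be matching 2-D arrays")
    n_classes = labels.shape[1]
    per_class = np.full(n_classes, np.nan)
    for c in range(n_classes):
        try:
            per_class[c] = roc_auc(labels[:, c], scores[:, c])
        except UndefinedAUCError:
            pass
    if np.isnan(per_class).all():
        raise UndefinedAUCError("every class has single-class labels")
    macro = float(np.nanmean(per_class))
    micro = roc_auc(labels.ravel(), scores.ravel())
    return micro, macro, per_class


def steady_stats(
    n_values, values, region: tuple[float, float] = (1000, 10000)
) -> SteadyStats:
    """Mean, sample std, max, min over series points with N inside ``region``.

    The default region [1000, 10000] is where the AUC-vs-N curves plateau.
    """
    n_values = np.asarray(n_values, dtype=float)
    values = np.asarray(values, dtype=float)
    lo, hi = region
    if not lo < hi:
        raise ValueError("region must satisfy n_min < n_max")
    mask = (n_values >= lo) & (n_values <= hi)
    sel = values[mask]
    if sel.size < 2:
        raise SizingError(
            f"need >= 2 points inside the steady region, found {sel.size}"
        )
    return SteadyStats(
        region=(lo, hi),
        mean=float(sel.mean()),
        std=float(sel.std(ddof=1)),
        max=float(sel.max()),
        min=float(sel.min()),
        n_points=int(sel.size),
    )


def _tricube(d: np.ndarray, d_max: float) -> np.ndarray:
    w = 1.0 - (d / d_max) ** 3
    np.clip(w, 0.0, None, out=w)
    return w**3


def lowess(x, y, frac: float = 0.3, degree: int = 1) -> np.ndarray:
    """Locally weighted linear regression (LOWESS) fitted values.

    At each x_i a degree-1 polynomial is fit by weighted least squares over
    the ceil(frac * n) nearest neighbors, with tricube weights
    w(d) = (1 - (d/d_max)^3)^3. When all neighbors share one x (or d_max
    is 0) the fit degenerates to the weighted mean there. Output order
    matches input order and depends only on point geometry, so it is
    invariant to permutations of the input.
    """
    if degree != 1:
        raise ValueError("only degree-1 local fits are supported")
    if not 0.0 < frac <= 1.0:
        raise ValueError("frac must lie in (0, 1]")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise SizingError("need at least 3 points")
    k = math.ceil(frac * n)
    k = max(k, 2)

    fitted = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        neighbors = np.argpartition(d, k - 1)[:k]
        dn = d[neighbors]
        d_max = dn.max()
        xn = x[neighbors]
        yn = y[neighbors]
        if d_max == 0:
            fitted[i] = yn.mean()
            continue
        w = _tricube(dn, d_max)
        sw = w.sum()
        xbar = (w * xn).sum() / sw
        ybar = (w * yn).sum() / sw
        sxx = (w * (xn - xbar) ** 2).sum()
        if sxx <= 0:
            fitted[i] = ybar
            continue
        slope = (w * (xn - xbar) * (yn - ybar)).sum() / sxx
        fitted[i] = ybar + slope * (x[i] - xbar)
    return fitted
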