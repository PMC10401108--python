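"""Global mineralization threshold from per-slice gray-level histograms.

The threshold for separating mineralized from unmineralized tissue is the
"horizontal slope" point of each slice's gray-level histogram: after a
centered moving-average smoothing, the position between the two dominant
intensity modes where the histogram is flattest — the minimum of the
absolute first derivative, refined to sub-bin precision at the adjacent
second-derivative sign change.  The global threshold is the mean of the
per-slice values and their population standard deviation quantifies its
uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .io import ImageStack


class ThresholdError(RuntimeError):
    """No usable plateau between two histogram modes."""


@dataclass
class ThresholdResult:
    """Global threshold (gray levels) with per-slice values and uncertainty.

    ``uncertainty`` is the population standard deviation of the per-slice
    thresholds; slices where no bimodal plateau was found are listed in
    ``failed_slices`` rather than silently dropped from the report.
    """

    global_threshold: float
    per_slice_thresholds: list[float]
    uncertainty: float
    failed_slices: list[int] = field(default_factory=list)


@dataclass
class VolumeGrowth:
    """Mineralized-volume change over a growth interval (mm³)."""

    v_early: float
    v_late: float
    percent_increase: float


def _smooth(hist: np.ndarray, window: int) -> np.ndarray:
    return uniform_filter1d(hist.astype(float), size=window, mode="nearest")


def _plateau_maxima(h: np.ndarray) -> list[tuple[float, float]]:
    """(position, height) of local maxima, plateau runs collapsed to centers."""
    n = len(h)
    maxima = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and h[j + 1] == h[i]:
            j += 1
        left_ok = i == 0 or h[i - 1] < h[i]
        right_ok = j == n - 1 or h[j + 1] < h[j]
        if left_ok and right_ok and not (i == 0 and j == n - 1):
            maxima.append(((i + j) / 2.0, float(h[i])))
        i = j + 1
    return maxima


def slice_threshold(histogram, smoothing_window: int = 5) -> float:
    """Horizontal-slope threshold of one gray-level histogram.

    Parameters
    ----------
    histogram : array of counts per gray level (bin k = gray level k)
    smoothing_window : odd moving-average width in bins (≥ 1)

    Returns the (possibly fractional) gray level between the two dominant
    modes where the smoothed histogram's slope magnitude is minimal; exact
    ties over a flat run resolve to the midpoint of the maximal run.

    Raises :class:`ThresholdError` if the smoothed histogram is not bimodal.
    """
    h = np.asarray(histogram, dtype=float)
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ValueError("smoothing_window must be odd and >= 1")
    if np.count_nonzero(h) < 3:
        raise ThresholdError("histogram has fewer than 3 nonzero bins")
    hs = _smooth(h, smoothing_window)
    maxima = sorted(_plateau_maxima(hs), key=lambda m: m[1], reverse=True)
    if len(maxima) < 2:
        raise ThresholdError("no plateau: histogram unimodal after smoothing")
    # second dominant mode must be separated from the first by a valley
    # dipping below half its height, else the histogram is effectively unimodal
    p1 = maxima[0][0]
    second = None
    for pos, height in maxima[1:]:
        lo, hi = int(round(min(p1, pos))), int(round(max(p1, pos)))
        if hi - lo >= 2 and hs[lo:hi + 1].min() < 0.5 * height:
            second = pos
            break
    if second is None:
        raise ThresholdError("no plateau: histogram unimodal after smoothing")
    i1, i2 = sorted(int(round(p)) for p in (p1, second))

    d1 = np.gradient(hs)
    interior = np.arange(i1 + 1, i2)
    a1 = np.abs(d1[interior])
    m = a1.min()
    tied = a1 == m
    if tied.sum() > 1:
        # midpoint of the maximal flat run of tied bins
        runs, start = [], None
        for k, t in enumerate(tied):
            if t and start is None:
                start = k
            if (not t or k == len(tied) - 1) and start is not None:
                end = k if t else k - 1
                runs.append((start, end))
                start = None
        start, end = max(runs, key=lambda r: r[1] - r[0])
        return float(interior[start] + interior[end]) / 2.0

    b = int(interior[np.argmin(a1)])
    # sub-bin refinement: linear zero crossing of the second derivative
    d2 = np.gradient(d1)
    best = float(b)
    for k in (b - 1, b):
        if 0 <= k and k + 1 < len(d2) and d2[k] * d2[k + 1] < 0:
            x = k + d2[k] / (d2[k] - d2[k + 1])
            if abs(x - b) <= 1.0:
                best = float(np.clip(x, i1 + 1, i2 - 1))
                break
    return best


def global_threshold(stack: ImageStack, smoothing_window: int = 5) -> ThresholdResult:
    """Mean per-slice horizontal-slope threshold over a stack.

    Each z-slice contributes one histogram-derived threshold; the global
    value is their mean and the population SD is the uncertainty.  Slices
    without a bimodal plateau are recorded in ``failed_slices``.
    """
    if not np.issubdtype(stack.voxels.dtype, np.integer):
        raise ValueError("global_threshold expects an integer-valued stack")
    n_bins = 2**stack.bit_depth
    values: list[float] = []
    failed: list[int] = []
    for z in range(stack.shape[0]):
        hist = np.bincount(stack.voxels[z].ravel(), minlength=n_bins)
        try:
            values.append(slice_threshold(hist, smoothing_window))
        except ThresholdError:
            failed.append(z)
    if not values:
        raise ThresholdError("no slice produced a bimodal histogram")
    arr = np.asarray(values)
    return ThresholdResult(global_threshold=float(arr.mean()),
                           per_slice_thresholds=[float(v) for v in values],
                           uncertainty=float(arr.std(ddof=0)),
                           failed_slices=failed)


def mineralized_volume(stack: ImageStack, threshold: float) -> float:
    """Volume of voxels at or above ``threshold``, in mm³."""
    n = int(np.count_nonzero(stack.voxels >= threshold))
    return n * stack.voxel_volume * 1e-9  # µm³ -> mm³


def mineralized_mask(stack: ImageStack, threshold: float) -> np.ndarray:
    """Boolean mask of the threshold-based mineralized segmentation."""
    return stack.voxels >= threshold


def volume_growth(v_early: float, v_late: float) -> VolumeGrowth:
    """Percent increase of mineralized volume between two time points (mm³)."""
    if not v_early > 0:
        raise ValueError("v_early must be positive")
    return VolumeGrowth(v_early=float(v_early), v_late=float(v_late),
                        percent_increase=100.0 * (v_late - v_early) / v_early)
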