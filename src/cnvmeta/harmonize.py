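"""Bringing heterogeneous caller outputs onto one absolute copy-number scale.

Three harmonisation paths feed the consensus model:

* the coverage caller's absolute CNs are corrected for the systematic bias
  visible as a shift of the frequency peak away from the ploidy,
  ``CN_norm = CN + clamp(factor * bias)`` with ``factor = min(CN/2, 1)`` and
  the applied correction clamped to +/- 0.5 CN units;
* log2 ratios against a matched sample are median-centred genome-wide and
  mapped through ``P * 2**log2``;
* non-negative ratios against a zero-coverage null alignment are multiplied
  by the equaliser factor ``q = (1 + CN/100) ** (0.75 * CN)`` which undoes
  the exponential distortion such ratios exhibit.

The deletion/normal/amplification thresholds T1/T2 are estimated from the
normalised coverage track: T2 is the local minimum of the CN frequency
histogram inside [2, 2.3] and T1 mirrors it at 2*P - T2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .core import CallerTrack, IntervalCall, Thresholds, ValueScale

logger = logging.getLogger(__name__)

#: histogram resolution (CN units) for peak / local-minimum detection
DEFAULT_BIN_WIDTH = 0.05
#: largest applied bias correction, in CN units
DEFAULT_CLAMP = 0.5
#: search interval for the T2 local minimum
DEFAULT_T2_INTERVAL = (2.0, 2.3)


@dataclass(frozen=True)
class BiasEstimate:
    """Systematic shift of a coverage caller's CN distribution.

    ``bias = P - peak_cn`` where ``peak_cn`` is the histogram peak closest
    to the ploidy; a positive bias means the caller under-calls.
    """

    bias: float
    peak_cn: float
    histogram_bin_width: float


@dataclass(frozen=True)
class EqualizerParams:
    """Parameters of the null-ratio equaliser factor q."""

    base_divisor: float = 100.0
    exponent_coefficient: float = 0.75

    def __post_init__(self) -> None:
        if self.base_divisor <= 0:
            raise ValueError("base_divisor must be > 0")
        if self.exponent_coefficient < 0:
            raise ValueError("exponent_coefficient must be >= 0")


def _length_weighted_histogram(track: CallerTrack, bin_width: float):
    """Histogram of call values, weighted by interval length.

    Bins are centred on integer multiples of ``bin_width`` so that a value
    sitting exactly on the grid (e.g. 1.9 with width 0.05) is represented
    by its own centre rather than a half-shifted bin edge.
    """
    values = np.array([c.value for c in track.calls if c.value is not None], dtype=float)
    weights = np.array([c.length for c in track.calls if c.value is not None], dtype=float)
    if values.size == 0:
        raise ValueError("track has no valued calls")
    idx = np.floor(values / bin_width + 0.5).astype(int)
    lo, hi = idx.min(), idx.max()
    counts = np.zeros(hi - lo + 1, dtype=float)
    np.add.at(counts, idx - lo, weights)
    centres = (np.arange(lo, hi + 1)) * bin_width
    return centres, counts


def estimate_bias(
    track: CallerTrack,
    ploidy: int = 2,
    histogram_bin_width: float = DEFAULT_BIN_WIDTH,
) -> BiasEstimate:
    """Estimate the coverage caller's systematic CN bias genome-wide.

    Builds a length-weighted frequency histogram of the track's absolute
    copy numbers and takes the peak as the mode of the histogram within
    half a copy of the ploidy (the window in which any correction could
    apply; ties go to the smaller CN). If no mass falls in that window the
    global mode is used. Returns ``bias = P - peak_cn``.
    """
    if track.value_scale is not ValueScale.ABSOLUTE_CN:
        raise ValueError("bias estimation needs a track on the absolute-CN scale")
    centres, counts = _length_weighted_histogram(track, histogram_bin_width)
    if counts.size > 1 and np.allclose(counts, counts[0]):
        logger.warning("flat CN histogram; assuming zero bias")
        return BiasEstimate(0.0, float(ploidy), histogram_bin_width)
    half = histogram_bin_width / 2.0
    window = (centres >= ploidy - 0.5 - half) & (centres <= ploidy + 0.5 + half)
    cand = np.nonzero(window & (counts > 0))[0]
    if cand.size == 0:
        cand = np.arange(counts.size)
    best = int(cand[np.argmax(counts[cand])])  # argmax keeps the first (smaller CN) tie
    peak_cn = float(centres[best])
    return BiasEstimate(float(ploidy) - peak_cn, peak_cn, histogram_bin_width)


def normalize_cn(cn: float, bias: float, clamp: float = DEFAULT_CLAMP) -> float:
    """Bias-correct one absolute copy number.

    The correction scales linearly with CN up to the ploidy (factor =
    min(CN/2, 1)) and the *applied* correction is clamped to +/- ``clamp``;
    the result is floored at 0.
    """
    if cn < 0:
        raise ValueError("copy numbers must be >= 0")
    factor = min(cn / 2.0, 1.0)
    correction = factor * bias
    correction = max(-clamp, min(clamp, correction))
    return max(cn + correction, 0.0)


def normalize_track(
    track: CallerTrack,
    ploidy: int = 2,
    histogram_bin_width: float = DEFAULT_BIN_WIDTH,
    clamp: float = DEFAULT_CLAMP,
) -> tuple[CallerTrack, BiasEstimate]:
    """Bias-correct every call of a coverage track; returns (track, estimate)."""
    est = estimate_bias(track, ploidy, histogram_bin_width)
    calls = [
        replace(c, value=normalize_cn(c.value, est.bias, clamp))
        for c in track.calls
    ]
    return replace(track, calls=calls), est


def log2_to_absolute(values, ploidy: int = 2, lengths=None) -> np.ndarray:
    """Convert matched-sample log2 ratios to absolute CNs.

    The genome-wide (length-weighted) median of the log2 values is
    subtracted first, recentring the bulk of the genome on the ploidy, then
    each bin maps through ``P * 2**corrected``.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("no log2 values to convert")
    if lengths is None:
        med = float(np.median(arr))
    else:
        med = _weighted_median(arr, np.asarray(lengths, dtype=float))
    return ploidy * np.power(2.0, arr - med)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    cutoff = cum[-1] / 2.0
    i = int(np.searchsorted(cum, cutoff))
    if math.isclose(cum[i], cutoff) and i + 1 < v.size:
        return float((v[i] + v[i + 1]) / 2.0)
    return float(v[i])


def equalizer_q(cn_ratio, params: EqualizerParams = EqualizerParams()):
    """The multiplicative equaliser factor q for null-ratio values."""
    arr = np.asarray(cn_ratio, dtype=float)
    return np.power(1.0 + arr / params.base_divisor, params.exponent_coefficient * arr)


def equalize_null_ratio(cn_ratio, params: EqualizerParams = EqualizerParams()):
    """Undo the exponential distortion of ratios taken against a null alignment.

    Returns ``CN_meta = CN * q(CN)``; the input must be non-negative (a
    ratio against zero coverage cannot be negative). Scalar in, scalar out.
    """
    arr = np.asarray(cn_ratio, dtype=float)
    if np.any(arr < 0):
        raise ValueError("null-ratio values must be non-negative")
    out = arr * equalizer_q(arr, params)
    return float(out) if np.isscalar(cn_ratio) or arr.ndim == 0 else out


def harmonize_hybrid_track(
    track: CallerTrack,
    ploidy: int = 2,
    params: EqualizerParams = EqualizerParams(),
) -> CallerTrack:
    """Map a hybrid track onto the absolute-CN scale along its declared path."""
    if track.value_scale is ValueScale.LOG2_VS_MATCHED:
        vals = [c.value for c in track.calls]
        lens = [c.length for c in track.calls]
        abs_cn = log2_to_absolute(vals, ploidy, lengths=lens)
        calls = [replace(c, value=float(v)) for c, v in zip(track.calls, abs_cn)]
    elif track.value_scale is ValueScale.RATIO_VS_NULL:
        calls = [replace(c, value=equalize_null_ratio(c.value, params)) for c in track.calls]
    elif track.value_scale is ValueScale.ABSOLUTE_CN:
        return track
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(f"unknown value scale {track.value_scale}")
    return replace(track, calls=calls, value_scale=ValueScale.ABSOLUTE_CN)


def compute_thresholds(
    coverage_track: CallerTrack,
    ploidy: int = 2,
    histogram_bin_width: float = DEFAULT_BIN_WIDTH,
    t2_search_interval: tuple[float, float] = DEFAULT_T2_INTERVAL,
) -> Thresholds:
    """Derive T1/T2 from the normalised coverage track's CN distribution.

    T2 is the interior local minimum (bin strictly lower than both
    neighbours) of the length-weighted histogram inside the search
    interval; among several, the lowest frequency wins, ties towards the
    smaller CN. With no interior minimum the interval midpoint is used.
    """
    lo, hi = t2_search_interval
    centres, counts = _length_weighted_histogram(coverage_track, histogram_bin_width)
    candidates: list[tuple[float, float]] = []  # (frequency, cn)
    for i in range(centres.size):
        if not (lo <= centres[i] <= hi):
            continue
        left = counts[i - 1] if i > 0 else None
        right = counts[i + 1] if i + 1 < counts.size else None
        if left is not None and right is not None and counts[i] < left and counts[i] < right:
            candidates.append((float(counts[i]), float(centres[i])))
    if candidates:
        _, t2 = min(candidates)
    else:
        t2 = (lo + hi) / 2.0
        logger.warning(
            "no interior local minimum in [%g, %g]; falling back to T2 = %g", lo, hi, t2
        )
    t1 = 2.0 * ploidy - t2
    return Thresholds(t1=t1, t2=t2, ploidy=ploidy)
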