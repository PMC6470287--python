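"""Burst-suppression pattern extraction from EEG and regressor construction.

Burst suppression (BS) is the deep-anesthesia EEG regime in which high-voltage
bursts alternate with near-isoelectric suppression epochs.  This module turns a
multichannel EEG recording into the binary BS pattern (0 = suppression,
1 = non-suppression), computes the burst-suppression ratio (BSR, percent of
time suppressed), and builds the hemodynamic regressor used to model the
coupling of the BS pattern with BOLD fluctuations: the binary series convolved
with a canonical double-gamma hemodynamic response function (HRF) and sampled
on the fMRI volume grid.

Conventions: time in seconds, suppression intervals are half-open
``[onset, offset)``, volume ``k`` is acquired at ``k * tr``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal, stats


class DetectionError(ValueError):
    """Raised when suppression detection cannot proceed (e.g. flat EEG)."""


@dataclass(frozen=True)
class DetectionParams:
    """Parameters of the amplitude-threshold suppression detector.

    envelope_window
        Length of the moving-RMS window used for the amplitude envelope, s.
    threshold_fraction
        Fraction of the robust burst amplitude (90th percentile of the summed
        normalized envelope) below which a sample counts as suppressed.
    min_suppression
        Suppression runs shorter than this are discarded, s.
    min_burst_gap
        Non-suppression gaps shorter than this are merged into the flanking
        suppressions, s.
    """

    envelope_window: float = 0.25
    threshold_fraction: float = 0.25
    min_suppression: float = 0.5
    min_burst_gap: float = 0.2

    def __post_init__(self) -> None:
        if self.envelope_window <= 0 or self.min_suppression <= 0 or self.min_burst_gap <= 0:
            raise ValueError("detection durations must be positive")
        if not 0.0 < self.threshold_fraction < 1.0:
            raise ValueError("threshold_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma HRF parameters (SPM-style defaults).

    The kernel is ``gampdf(t; peak) - gampdf(t; undershoot) / ratio`` on
    ``[0, kernel_length]``, rescaled to unit peak.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    peak_undershoot_ratio: float = 6.0
    kernel_length: float = 32.0

    def __post_init__(self) -> None:
        vals = (
            self.peak_delay,
            self.undershoot_delay,
            self.peak_dispersion,
            self.undershoot_dispersion,
            self.peak_undershoot_ratio,
            self.kernel_length,
        )
        if any(v <= 0 for v in vals):
            raise ValueError("all HRF parameters must be positive")
        if self.kernel_length < self.undershoot_delay:
            raise ValueError("kernel_length must cover the undershoot delay")


@dataclass
class EEGRecording:
    """Multichannel EEG: ``data`` is channels x samples at ``sample_rate`` Hz."""

    data: np.ndarray
    sample_rate: float
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.channel_names is None:
            self.channel_names = [f"ch{i:02d}" for i in range(self.data.shape[0])]
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass
class BSPattern:
    """Binary burst-suppression pattern on a uniform time grid.

    ``values[i] = 0`` marks suppression at sample ``i``; 1 marks burst /
    non-suppression.  ``intervals`` lists the suppression epochs as half-open
    ``(onset, offset)`` pairs in seconds and always reconstructs ``values``.
    """

    values: np.ndarray
    sample_rate: float
    intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("pattern values must be a non-empty 1-D array")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("pattern values must be binary")
        self.values = self.values.astype(np.int8)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not self.intervals:
            self.intervals = _values_to_intervals(self.values, self.sample_rate)

    @property
    def duration(self) -> float:
        return self.values.size / self.sample_rate

    @property
    def bsr(self) -> float:
        return compute_bsr(self)


@dataclass
class VolumeRegressor:
    """BS regressor sampled at fMRI volume onsets, mean-centered.

    ``n_dropped_leading_volumes`` records how many initial volumes were
    discarded before sampling (dummy scans), so ``values`` aligns with the
    retained volumes of the run.
    """

    values: np.ndarray
    tr: float
    n_dropped_leading_volumes: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("regressor must be 1-D")
        if not np.isfinite(self.values).all():
            raise ValueError("regressor values must be finite")
        if self.tr <= 0:
            raise ValueError("tr must be positive")


def _values_to_intervals(values: np.ndarray, sample_rate: float) -> list[tuple[float, float]]:
    """Half-open suppression intervals (s) for the zero-runs of a binary series."""
    suppressed = np.asarray(values) == 0
    if not suppressed.any():
        return []
    edges = np.diff(suppressed.astype(np.int8))
    onsets = np.flatnonzero(edges == 1) + 1
    offsets = np.flatnonzero(edges == -1) + 1
    if suppressed[0]:
        onsets = np.r_[0, onsets]
    if suppressed[-1]:
        offsets = np.r_[offsets, suppressed.size]
    return [(int(a) / sample_rate, int(b) / sample_rate) for a, b in zip(onsets, offsets)]


def make_binary_pattern(
    intervals: list[tuple[float, float]], duration: float, sample_rate: float
) -> BSPattern:
    """Build a :class:`BSPattern` that is 0 inside the given suppression intervals.

    Intervals are half-open in seconds, must be non-overlapping and lie within
    ``[0, duration)``.  A sample at time ``i / sample_rate`` is suppressed when
    it falls inside an interval.
    """
    if duration <= 0 or sample_rate <= 0:
        raise ValueError("duration and sample_rate must be positive")
    ivs = sorted((float(a), float(b)) for a, b in intervals)
    n = int(round(duration * sample_rate))
    values = np.ones(n, dtype=np.int8)
    prev_end = -np.inf
    for onset, offset in ivs:
        if offset <= onset:
            raise ValueError(f"empty or inverted interval ({onset}, {offset})")
        if onset < 0 or offset > duration + 1e-9:
            raise ValueError(f"interval ({onset}, {offset}) outside [0, {duration})")
        if onset < prev_end:
            raise ValueError(f"overlapping intervals at onset {onset}")
        prev_end = offset
        i0 = int(np.ceil(onset * sample_rate - 1e-9))
        i1 = min(int(np.ceil(offset * sample_rate - 1e-9)), n)
        values[i0:i1] = 0
    return BSPattern(values=values, sample_rate=sample_rate)


def compute_bsr(pattern: BSPattern) -> float:
    """Burst-suppression ratio: percent of samples in suppression."""
    return 100.0 * float(np.mean(pattern.values == 0))


def moving_rms(x: np.ndarray, window_samples: int) -> np.ndarray:
    """Moving root-mean-square with a centered window (edges use reflection)."""
    if window_samples < 1:
        raise ValueError("window must span at least one sample")
    power = ndimage.uniform_filter1d(np.square(x, dtype=float), size=window_samples, mode="reflect", axis=-1)
    return np.sqrt(np.maximum(power, 0.0))


def detect_suppressions(
    eeg: EEGRecording, params: DetectionParams | None = None
) -> list[tuple[float, float]]:
    """Detect suppression epochs by thresholding the summed normalized envelope.

    Each channel's moving-RMS envelope is normalized by its own 90th percentile
    (a robust estimate of burst-level amplitude, insensitive to per-channel
    gain), the normalized envelopes are summed across channels, and samples
    where the sum falls below ``threshold_fraction`` times the robust burst
    level of the sum are marked suppressed.  Suppression runs shorter than
    ``min_suppression`` are dropped and burst gaps shorter than
    ``min_burst_gap`` are merged.

    Returns sorted, disjoint, half-open intervals in seconds.
    """
    params = params or DetectionParams()
    fs = eeg.sample_rate
    if params.envelope_window >= eeg.duration:
        raise ValueError("envelope_window must be shorter than the recording")
    win = max(int(round(params.envelope_window * fs)), 1)
    env = moving_rms(eeg.data, win)
    scale = np.percentile(env, 90, axis=1, keepdims=True)
    if np.any(scale <= 0):
        raise DetectionError("no amplitude contrast: flat channel in recording")
    summed = (env / scale).sum(axis=0)
    burst_level = np.percentile(summed, 90)
    if burst_level <= 0:
        raise DetectionError("no amplitude contrast")
    suppressed = summed < params.threshold_fraction * burst_level
    intervals = _values_to_intervals((~suppressed).astype(np.int8), fs)
    # Centered moving-RMS thresholding localizes each burst/suppression edge
    # with a fixed inward bias: for an amplitude step the envelope crosses
    # f * A_burst at w * (1/2 - f^2) inside the suppression.  Undo it so
    # boundaries land on the true transition.
    bias = params.envelope_window * (0.5 - params.threshold_fraction**2)
    intervals = [
        (max(0.0, a - bias), min(eeg.duration, b + bias)) for a, b in intervals
    ]
    widened: list[tuple[float, float]] = []
    for iv in intervals:
        if widened and iv[0] <= widened[-1][1]:
            widened[-1] = (widened[-1][0], max(widened[-1][1], iv[1]))
        else:
            widened.append(iv)
    # drop sub-minimum suppressions, then close short burst gaps
    intervals = [iv for iv in widened if iv[1] - iv[0] >= params.min_suppression]
    merged: list[tuple[float, float]] = []
    for iv in intervals:
        if merged and iv[0] - merged[-1][1] < params.min_burst_gap:
            merged[-1] = (merged[-1][0], iv[1])
        else:
            merged.append(iv)
    return merged


def canonical_hrf(params: HRFParams | None = None, dt: float = 0.1) -> np.ndarray:
    """Sample the canonical double-gamma HRF on ``[0, kernel_length]`` at step ``dt``.

    The kernel is the difference of two gamma densities (peak minus scaled
    undershoot) normalized to unit peak amplitude.
    """
    params = params or HRFParams()
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, params.kernel_length + dt / 2, dt)
    peak = stats.gamma.pdf(t, params.peak_delay / params.peak_dispersion, scale=params.peak_dispersion)
    under = stats.gamma.pdf(
        t, params.undershoot_delay / params.undershoot_dispersion, scale=params.undershoot_dispersion
    )
    kernel = peak - under / params.peak_undershoot_ratio
    return kernel / kernel.max()


def build_bs_regressor(
    pattern: BSPattern,
    tr: float,
    n_volumes: int,
    n_drop: int = 10,
    hrf: HRFParams | None = None,
) -> VolumeRegressor:
    """Convolve the BS pattern with the HRF and sample at volume onsets.

    Convolution runs at the pattern's native rate (preserving sub-TR timing of
    suppression onsets); the result is read at ``t = k * tr`` for retained
    volumes ``k = n_drop .. n_volumes - 1`` and mean-centered.
    """
    if tr <= 0 or n_volumes <= 0:
        raise ValueError("tr and n_volumes must be positive")
    if not 0 <= n_drop < n_volumes:
        raise ValueError("n_drop must lie in [0, n_volumes)")
    fs = pattern.sample_rate
    needed = (n_volumes - 1) * tr
    if pattern.duration < needed:
        raise ValueError(
            f"pattern covers {pattern.duration:.2f} s but {needed:.2f} s are required"
        )
    kernel = canonical_hrf(hrf, dt=1.0 / fs)
    conv = signal.fftconvolve(pattern.values.astype(float), kernel)[: pattern.values.size]
    idx = np.round(np.arange(n_drop, n_volumes) * tr * fs).astype(int)
    idx = np.minimum(idx, conv.size - 1)
    values = conv[idx]
    values = values - values.mean()
    return VolumeRegressor(values=values, tr=tr, n_dropped_leading_volumes=n_drop)


def temporal_jaccard(
    a: list[tuple[float, float]], b: list[tuple[float, float]]
) -> float:
    """Jaccard overlap of two interval sets, measured in seconds of overlap."""

    def total(ivs):
        return sum(o - s for s, o in ivs)

    inter = 0.0
    for s1, o1 in a:
        for s2, o2 in b:
            inter += max(0.0, min(o1, o2) - max(s1, s2))
    union = total(a) + total(b) - inter
    return inter / union if union > 0 else 1.0
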