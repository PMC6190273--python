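"""PPG preprocessing: IIR low-pass filtering and pulse segmentation.

The raw thumb PPG is cleaned with a second-order Butterworth low-pass
filter cut off at 20 Hz (the pulse waveform's energy lives well below
that; broadband sensor noise and motion artifact above it).  The filtered
signal is then segmented into pulse-foot-to-pulse-foot windows, and each
window is annotated with its systolic peak and, when present, its dicrotic
notch.

Filtering is causal (forward-only) by default, matching a streaming
acquisition front end; a zero-phase forward-backward mode is available.
Bilateral timing features compare the two channels filtered identically,
so the constant group delay of the causal filter cancels out.

Foot detection follows a standard slope-based beat detector: candidate
systolic upstrokes are maxima of the smoothed first derivative above an
adaptive threshold (half the 90th percentile of the positive derivative),
separated by a refractory period, and each foot is the signal minimum in a
short window preceding its upstroke.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "FilterSpec",
    "PulseWindow",
    "FootDetectorParams",
    "butterworth_lowpass",
    "detect_pulse_feet",
    "detect_landmarks",
    "segment_record",
]


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass filter design: order-2 Butterworth, 20 Hz at fs = 1 kHz."""

    order: int = 2
    cutoff: float = 20.0  # Hz
    fs: float = 1000.0  # Hz
    zero_phase: bool = False

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if not 0.0 < self.cutoff < self.fs / 2.0:
            raise ValueError(
                f"cutoff must lie in (0, fs/2) = (0, {self.fs / 2}), got {self.cutoff}"
            )

    def coefficients(self) -> tuple[np.ndarray, np.ndarray]:
        return sps.butter(self.order, self.cutoff, btype="low", fs=self.fs)


@dataclass(frozen=True)
class PulseWindow:
    """One beat, half-open ``[start_index, end_index)``, 0-based indices.

    ``start_index`` is the pulse foot; ``end_index`` the next pulse foot.
    ``notch_index`` is None when the beat shows no interior local minimum
    after the systolic peak (damped pulse).
    """

    start_index: int
    end_index: int
    peak_index: int
    notch_index: int | None = None

    def __post_init__(self) -> None:
        if not self.start_index < self.peak_index < self.end_index:
            raise ValueError(
                f"need start < peak < end, got ({self.start_index}, "
                f"{self.peak_index}, {self.end_index})"
            )
        if self.notch_index is not None and not (
            self.peak_index < self.notch_index < self.end_index
        ):
            raise ValueError("notch_index must lie strictly between peak and end")

    @property
    def foot_index(self) -> int:
        return self.start_index


@dataclass(frozen=True)
class FootDetectorParams:
    """Tunables of the slope-based foot detector."""

    smooth_window: float = 0.025  # s, moving-average width for the derivative
    threshold_frac: float = 0.5  # of the 90th percentile of the positive slope
    refractory: float = 0.25  # s, minimum spacing between upstrokes
    foot_search: float = 0.40  # s, how far before an upstroke the foot may sit
    min_interval: float = 0.33  # s, physiologic lower bound on foot spacing
    max_interval: float = 2.0  # s, physiologic upper bound on foot spacing


def butterworth_lowpass(x: np.ndarray, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Apply the Butterworth low-pass filter to a 1-D signal.

    Causal (``lfilter``) by default; set ``spec.zero_phase`` for
    forward-backward filtering.  Unity gain at DC, -3 dB at the cutoff.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D sample array")
    if len(x) <= 3 * spec.order:
        raise ValueError(f"input too short to filter ({len(x)} samples)")
    b, a = spec.coefficients()
    if spec.zero_phase:
        return sps.filtfilt(b, a, x)
    # Initialize at the DC steady state for the first sample to suppress
    # the start-up transient of the causal filter.
    zi = sps.lfilter_zi(b, a) * x[0]
    y, _ = sps.lfilter(b, a, x, zi=zi)
    return y


def detect_pulse_feet(
    x: np.ndarray,
    fs: float = 1000.0,
    params: FootDetectorParams = FootDetectorParams(),
) -> np.ndarray:
    """Locate pulse feet (onset minima) in a filtered PPG channel.

    Returns a strictly increasing array of 0-based sample indices, one per
    detected cardiac cycle.  Flat or aperiodic input yields an empty array
    with a warning.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2.0 * fs:
        raise ValueError("need at least 2 s of samples for foot detection")

    dx = np.gradient(x)
    w = max(1, int(round(params.smooth_window * fs)))
    dx = np.convolve(dx, np.ones(w) / w, mode="same")

    pos = dx[dx > 0]
    if len(pos) == 0:
        warnings.warn("no rising slopes found; returning no pulse feet", stacklevel=2)
        return np.empty(0, dtype=int)
    height = params.threshold_frac * float(np.percentile(pos, 90))
    if height <= 0:
        warnings.warn("flat signal; returning no pulse feet", stacklevel=2)
        return np.empty(0, dtype=int)
    upstrokes, _ = sps.find_peaks(
        dx, height=height, distance=max(1, int(round(params.refractory * fs)))
    )
    if len(upstrokes) == 0:
        warnings.warn("no systolic upstrokes detected", stacklevel=2)
        return np.empty(0, dtype=int)

    search = int(round(params.foot_search * fs))
    feet: list[int] = []
    for up in upstrokes:
        lo = max(0, up - search)
        if feet:
            lo = max(lo, feet[-1] + 1)
        if up <= lo:
            continue
        foot = lo + int(np.argmin(x[lo : up + 1]))
        if feet and foot - feet[-1] < params.min_interval * fs:
            # Too close to the previous foot: spurious upstroke (e.g. the
            # dicrotic wave); keep the earlier foot.
            continue
        feet.append(foot)

    # Enforce the physiologic upper bound only as a sanity warning: gaps
    # longer than max_interval indicate missed beats, not invalid feet.
    arr = np.asarray(feet, dtype=int)
    if len(arr) >= 2:
        gaps = np.diff(arr) / fs
        if np.any(gaps > params.max_interval):
            warnings.warn(
                f"{int(np.sum(gaps > params.max_interval))} inter-foot gap(s) exceed "
                f"{params.max_interval} s; beats may have been missed",
                stacklevel=2,
            )
    return arr


def detect_landmarks(
    x: np.ndarray,
    foot_pair: tuple[int, int],
    fs: float = 1000.0,
    notch_search_frac: float = 0.80,
) -> PulseWindow:
    """Annotate one beat window with its systolic peak and dicrotic notch.

    The peak is the interior argmax of the window; the notch the most
    prominent local minimum between the peak and ``notch_search_frac`` of
    the window (None when the pulse is too damped to show one).
    """
    start, end = int(foot_pair[0]), int(foot_pair[1])
    x = np.asarray(x, dtype=float)
    if not 0 <= start < end <= len(x):
        raise ValueError(f"invalid foot pair ({start}, {end})")
    if (end - start) / fs < 0.33:
        raise ValueError(f"beat window shorter than 0.33 s: ({start}, {end})")

    seg = x[start:end]
    peak = start + int(np.argmax(seg))
    if peak == start or peak >= end - 1:
        raise ValueError("systolic peak must be interior to the beat window")

    hi = start + int(round(notch_search_frac * (end - start)))
    notch: int | None = None
    if hi - peak > 2:
        sub = x[peak:hi]
        mins = sps.argrelmin(sub)[0]
        if len(mins):
            # Most prominent = deepest relative to the lower flank maxima.
            notch = peak + int(mins[np.argmin(sub[mins])])
    return PulseWindow(start_index=start, end_index=end, peak_index=peak, notch_index=notch)


def segment_record(
    x: np.ndarray,
    fs: float = 1000.0,
    spec: FilterSpec = FilterSpec(),
    params: FootDetectorParams = FootDetectorParams(),
) -> list[PulseWindow]:
    """Filter one channel and segment it into annotated beat windows."""
    y = butterworth_lowpass(x, spec)
    feet = detect_pulse_feet(y, fs, params)
    windows = []
    for a, b in zip(feet[:-1], feet[1:]):
        try:
            windows.append(detect_landmarks(y, (int(a), int(b)), fs))
        except ValueError:
            continue  # degenerate beat (too short / boundary peak)
    return windows
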