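"""Synthetic bilateral PPG generator with stenosis-dependent asymmetry.

When an arteriovenous fistula narrows on one arm, the pulse arriving at
that hand is delayed, slowed and damped relative to the healthy arm, so the
two thumb PPG channels drift out of synchrony.  This module emulates that
structure: each beat is the sum of two log-normal-shaped lobes (systolic
wave plus dicrotic wave, giving a detectable pulse foot, systolic peak and
dicrotic notch), and the right channel is perturbed relative to the left by
four asymmetry parameters — a pulse-foot delay, a rise-time skew, an
amplitude attenuation and a dicrotic-notch shift — each a deterministic
monotone function of the degree of stenosis (DOS).

Defaults couple asymmetry to DOS as

    foot_delay      = 0.08 * DOS   [s]
    rise_time_skew  = 0.05 * DOS   [s]
    amplitude_ratio = 1 - 0.4 * DOS
    notch_shift     = 0.03 * DOS   [s]

These effect sizes make the three severity classes separable but
overlapping once per-subject jitter (beat-period CV 2%, landmark SD 5 ms,
amplitude CV 3%) is added; all of them are exposed in
:class:`AsymmetryCoupling` and :class:`JitterParams`.

The generator also emits ground-truth landmark annotations (pulse foot,
systolic peak, dicrotic notch per beat and channel), computed numerically
from the clean rendered waveform, so that downstream detectors can be
scored against a known reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .grading import SubjectMeta, diameter_for_dos, dos_to_class

__all__ = [
    "PulseShapeParams",
    "AsymmetryParams",
    "AsymmetryCoupling",
    "JitterParams",
    "PPGRecord",
    "asymmetry_for_dos",
    "generate_subject",
    "generate_cohort",
    "add_noise",
    "write_record_csv",
    "read_record_csv",
]

DEFAULT_FS = 1000.0
#: Default DOS sampling bands for the three severity classes.
DEFAULT_CLASS_BANDS = ((0.05, 0.30), (0.30, 0.50), (0.50, 0.85))

# Log-domain widths of the lobes.  The systolic lobe must decay fast
# enough before the dicrotic lobe rises that an interior local minimum
# (the notch) actually forms between them; the dicrotic lobe decays much
# more slowly than it rises, giving the flat diastolic runoff of a real
# pulse ahead of the next foot.
_SYS_LOG_WIDTH = 0.30
_DIC_RISE_LOG_WIDTH = 0.30
_DIC_DECAY_LOG_WIDTH = 0.55


@dataclass(frozen=True)
class PulseShapeParams:
    """Morphology of a single pulse, common to both channels.

    ``notch_depth`` controls how far the waveform dips between the systolic
    and dicrotic lobes: the dicrotic lobe amplitude is
    ``(1 - notch_depth) * systolic_amplitude``, so depth near 1 gives a
    deep, well-defined notch and depth near 0 a shoulder.
    """

    heart_rate: float = 75.0  # beats/min
    systolic_amplitude: float = 1.0  # arbitrary units
    rise_time: float = 0.15  # s, pulse foot to systolic peak
    notch_delay: float = 0.12  # s, systolic peak to dicrotic notch
    notch_depth: float = 0.65  # fraction of systolic amplitude, in (0, 1)
    baseline_drift_amp: float = 0.03  # arbitrary units, respiratory-band drift

    def __post_init__(self) -> None:
        if self.heart_rate <= 0:
            raise ValueError("heart_rate must be > 0")
        if self.systolic_amplitude <= 0:
            raise ValueError("systolic_amplitude must be > 0")
        if self.rise_time <= 0 or self.notch_delay <= 0:
            raise ValueError("rise_time and notch_delay must be > 0")
        if not 0.0 < self.notch_depth < 1.0:
            raise ValueError("notch_depth must lie strictly in (0, 1)")
        if self.baseline_drift_amp < 0:
            raise ValueError("baseline_drift_amp must be >= 0")
        if self.rise_time + self.notch_delay >= self.beat_period:
            raise ValueError(
                "rise_time + notch_delay must be shorter than the beat period "
                f"{self.beat_period:.3f} s"
            )

    @property
    def beat_period(self) -> float:
        return 60.0 / self.heart_rate


@dataclass(frozen=True)
class AsymmetryParams:
    """Right-minus-left channel asymmetry.

    A zero-asymmetry instance (0, 0, 1, 0) renders identical channels up to
    jitter and noise.
    """

    foot_delay: float = 0.0  # s, right pulse foot minus left pulse foot
    rise_time_skew: float = 0.0  # s, added to the right channel's rise time
    amplitude_ratio: float = 1.0  # right / left systolic amplitude
    notch_shift: float = 0.0  # s, added to the right dicrotic timing

    def __post_init__(self) -> None:
        for name in ("foot_delay", "rise_time_skew", "notch_shift"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not (math.isfinite(self.amplitude_ratio) and self.amplitude_ratio > 0):
            raise ValueError("amplitude_ratio must be finite and > 0")


@dataclass(frozen=True)
class AsymmetryCoupling:
    """Linear DOS -> asymmetry coupling coefficients (per unit DOS)."""

    foot_delay: float = 0.08  # s
    rise_time_skew: float = 0.05  # s
    amplitude_drop: float = 0.4  # amplitude_ratio = 1 - amplitude_drop * DOS
    notch_shift: float = 0.03  # s


@dataclass(frozen=True)
class JitterParams:
    """Per-subject physiological variability.

    Beat-period jitter is shared by both channels (one heart); landmark and
    amplitude jitter are drawn independently per beat and channel.
    """

    beat_period_cv: float = 0.02  # coefficient of variation of the beat period
    landmark_sd: float = 0.005  # s, SD of per-beat landmark timing jitter
    amplitude_cv: float = 0.03  # coefficient of variation of beat amplitude

    @classmethod
    def off(cls) -> "JitterParams":
        return cls(0.0, 0.0, 0.0)


@dataclass
class PPGRecord:
    """Synchronously sampled right/left thumb PPG.

    ``annotations``, when present, maps channel name ("right"/"left") to a
    dict of integer sample-index arrays ``{"foot", "peak", "notch"}`` with
    -1 marking an absent notch.
    """

    subject_id: str
    fs: float
    right: np.ndarray
    left: np.ndarray
    duration: float
    annotations: dict | None = None

    def __post_init__(self) -> None:
        self.right = np.asarray(self.right, dtype=float)
        self.left = np.asarray(self.left, dtype=float)
        if self.right.shape != self.left.shape or self.right.ndim != 1:
            raise ValueError("right and left must be 1-D arrays of equal length")
        if len(self.right) != round(self.fs * self.duration):
            raise ValueError("array length must equal round(fs * duration)")


def asymmetry_for_dos(
    dos: float, coupling: AsymmetryCoupling = AsymmetryCoupling()
) -> AsymmetryParams:
    """Deterministic monotone asymmetry for a given DOS fraction."""
    if not 0.0 <= dos <= 1.0:
        raise ValueError(f"DOS fraction must be in [0, 1], got {dos}")
    return AsymmetryParams(
        foot_delay=coupling.foot_delay * dos,
        rise_time_skew=coupling.rise_time_skew * dos,
        amplitude_ratio=1.0 - coupling.amplitude_drop * dos,
        notch_shift=coupling.notch_shift * dos,
    )


def _lognormal_lobe(
    tau: np.ndarray, center: float, log_width: float, decay_log_width: float | None = None
) -> np.ndarray:
    """Unit-height lobe peaking at ``tau = center``, zero for ``tau <= 0``.

    With ``decay_log_width`` the falling flank uses its own (wider)
    log-domain width, producing an asymmetric lobe with a long right tail;
    the join at the peak is smooth (both one-sided derivatives vanish).
    """
    out = np.zeros_like(tau)
    pos = tau > 0
    logr = np.log(tau[pos] / center)
    width = np.full_like(logr, log_width)
    if decay_log_width is not None:
        width[logr > 0] = decay_log_width
    z = logr / width
    out[pos] = np.exp(-0.5 * z * z)
    return out


def _render_channel(
    t: np.ndarray,
    onsets: np.ndarray,
    rise_times: np.ndarray,
    amplitudes: np.ndarray,
    dic_centers: np.ndarray,
    dic_amp_frac: float,
    fs: float,
) -> np.ndarray:
    x = np.zeros_like(t)
    n = len(t)
    horizon = 2.5  # s of tail rendered per beat
    for onset, rt, amp, dc in zip(onsets, rise_times, amplitudes, dic_centers):
        i0 = max(0, int(math.floor(onset * fs)))
        i1 = min(n, int(math.ceil((onset + horizon) * fs)))
        if i1 <= i0:
            continue
        tau = t[i0:i1] - onset
        x[i0:i1] += amp * (
            _lognormal_lobe(tau, rt, _SYS_LOG_WIDTH)
            + dic_amp_frac
            * _lognormal_lobe(tau, dc, _DIC_RISE_LOG_WIDTH, _DIC_DECAY_LOG_WIDTH)
        )
    return x


def _annotate_channel(
    x: np.ndarray, onsets: np.ndarray, period: float, fs: float
) -> dict[str, np.ndarray]:
    """Numeric ground-truth landmarks of a clean rendered channel.

    Foot is the sample-level minimum near each beat onset, peak the maximum
    of the following systolic upstroke, notch the deepest interior local
    minimum between peak and 85% of the beat window.
    """
    from scipy.signal import argrelmin

    n = len(x)
    feet, peaks, notches = [], [], []
    for onset in onsets:
        lo = int(round((onset - 0.05 * period) * fs))
        hi = int(round((onset + 0.35 * period) * fs))
        if lo < 0 or hi >= n:
            continue
        foot = lo + int(np.argmin(x[lo:hi]))
        p_hi = min(n, foot + int(round(0.6 * period * fs)))
        peak = foot + int(np.argmax(x[foot:p_hi]))
        if peak <= foot or peak >= n - 1:
            continue
        w_hi = min(n, int(round((onset + 0.85 * period) * fs)))
        notch = -1
        if w_hi - peak > 2:
            seg = x[peak:w_hi]
            mins = argrelmin(seg)[0]
            if len(mins):
                notch = peak + int(mins[np.argmin(seg[mins])])
        feet.append(foot)
        peaks.append(peak)
        notches.append(notch)
    return {
        "foot": np.asarray(feet, dtype=int),
        "peak": np.asarray(peaks, dtype=int),
        "notch": np.asarray(notches, dtype=int),
    }


def generate_subject(
    dos: float,
    shape: PulseShapeParams = PulseShapeParams(),
    duration: float = 10.0,
    seed: int = 0,
    *,
    jitter: JitterParams = JitterParams(),
    coupling: AsymmetryCoupling = AsymmetryCoupling(),
    asymmetry: AsymmetryParams | None = None,
    subject_id: str | None = None,
    fs: float = DEFAULT_FS,
    age: float | None = None,
    gender: str | None = None,
) -> tuple[PPGRecord, SubjectMeta]:
    """Render one subject's bilateral PPG record for a given DOS.

    The asymmetry defaults to the monotone DOS coupling; pass ``asymmetry``
    explicitly to probe a single controlled asymmetry.  The returned
    metadata carries a diameter pair consistent with the DOS via
    ``d = D * sqrt(1 - DOS)`` with ``D = 1.0``.
    """
    if not 0.0 <= dos <= 1.0:
        raise ValueError(f"DOS fraction must be in [0, 1], got {dos}")
    period = shape.beat_period
    if duration < 5.0 * period:
        raise ValueError(
            f"duration {duration} s is shorter than 5 beat periods ({5 * period:.2f} s)"
        )
    asym = asymmetry if asymmetry is not None else asymmetry_for_dos(dos, coupling)
    rng = np.random.default_rng(seed)

    n = round(fs * duration)
    t = np.arange(n) / fs

    # Beat onsets shared by both channels; one warm-up beat before t = 0 so
    # the first annotated foot sits on a decaying diastolic tail.
    n_beats = int(math.ceil((duration + 1.0) / period)) + 2
    periods = period * (1.0 + jitter.beat_period_cv * rng.standard_normal(n_beats))
    onsets_l = np.concatenate(([0.0], np.cumsum(periods[:-1]))) - period + 0.15
    onsets_r = onsets_l + asym.foot_delay

    dic_center = shape.rise_time + 2.5 * shape.notch_delay
    dic_amp = 1.0 - shape.notch_depth

    chans = {}
    ann = {}
    for name, onsets, rt0, amp0, dc0 in (
        ("left", onsets_l, shape.rise_time, shape.systolic_amplitude, dic_center),
        (
            "right",
            onsets_r,
            shape.rise_time + asym.rise_time_skew,
            shape.systolic_amplitude * asym.amplitude_ratio,
            dic_center + asym.rise_time_skew + asym.notch_shift,
        ),
    ):
        on = onsets + jitter.landmark_sd * rng.standard_normal(n_beats)
        rts = rt0 + jitter.landmark_sd * rng.standard_normal(n_beats)
        rts = np.clip(rts, 0.25 * rt0, None)
        amps = amp0 * (1.0 + jitter.amplitude_cv * rng.standard_normal(n_beats))
        amps = np.clip(amps, 0.1 * amp0, None)
        dcs = dc0 + jitter.landmark_sd * rng.standard_normal(n_beats)
        x = _render_channel(t, on, rts, amps, dcs, dic_amp, fs)
        if shape.baseline_drift_amp > 0:
            # Respiratory-band drift, common mode across channels.
            x = x + shape.baseline_drift_amp * np.sin(
                2.0 * math.pi * 0.25 * t + 2.0 * math.pi * 0.37
            )
        chans[name] = x
        ann[name] = _annotate_channel(x, on, period, fs)

    sid = subject_id if subject_id is not None else f"S{seed:05d}"
    record = PPGRecord(
        subject_id=sid,
        fs=fs,
        right=chans["right"],
        left=chans["left"],
        duration=duration,
        annotations=ann,
    )
    meta = SubjectMeta(
        subject_id=sid,
        d=diameter_for_dos(dos, 1.0),
        D=1.0,
        dos=dos,
        age=float(age) if age is not None else float(rng.integers(50, 91)),
        gender=gender if gender is not None else ("male", "female")[rng.integers(0, 2)],
        true_class=dos_to_class(dos),
    )
    return record, meta


def generate_cohort(
    n_per_class: int,
    class_dos_ranges: tuple = DEFAULT_CLASS_BANDS,
    seed: int = 0,
    *,
    shape: PulseShapeParams = PulseShapeParams(),
    duration: float = 10.0,
    jitter: JitterParams = JitterParams(),
    coupling: AsymmetryCoupling = AsymmetryCoupling(),
) -> list[tuple[PPGRecord, SubjectMeta]]:
    """Draw ``n_per_class`` subjects per severity class.

    DOS is sampled uniformly within each class band and the class label is
    assigned from the drawn DOS through the grading partition.  The whole
    cohort is reproducible from ``seed``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if len(class_dos_ranges) != 3:
        raise ValueError("class_dos_ranges must hold three (low, high) intervals")
    for lo, hi in class_dos_ranges:
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError(f"invalid DOS interval ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    cohort = []
    k = 0
    for c, (lo, hi) in enumerate(class_dos_ranges, start=1):
        for _ in range(n_per_class):
            dos = float(rng.uniform(lo, hi))
            sub_seed = int(rng.integers(0, 2**31 - 1))
            rec, meta = generate_subject(
                dos,
                shape=shape,
                duration=duration,
                seed=sub_seed,
                jitter=jitter,
                coupling=coupling,
                subject_id=f"C{c}S{k:03d}",
            )
            cohort.append((rec, meta))
            k += 1
    return cohort


def add_noise(
    signal: np.ndarray, snr_db: float, seed: int = 0, color: str = "white"
) -> np.ndarray:
    """Add zero-mean noise at a target SNR.

    SNR is defined as ``10*log10(P_signal / P_noise)`` with powers taken as
    mean squared value after mean removal.  The drawn noise is rescaled to
    its empirical power, so the realized SNR equals the target exactly.
    ``snr_db = inf`` is the clean sentinel and returns a copy.

    ``color`` selects the noise construction:

    * ``"white"`` — white Gaussian samples;
    * ``"signal"`` — a phase-randomized surrogate of the signal itself
      (its FFT magnitudes with uniformly random phases), i.e. noise
      constructed from the PPG recording and sharing its spectrum.  This
      noise lives in the pulse band, so the low-pass preprocessing cannot
      remove it and landmark timing degrades realistically.
    """
    x = np.asarray(signal, dtype=float)
    if math.isnan(snr_db):
        raise ValueError("snr_db must not be NaN")
    if math.isinf(snr_db) and snr_db > 0:
        return x.copy()
    if not math.isfinite(snr_db):
        raise ValueError("snr_db must be finite or +inf")
    p_signal = float(np.mean((x - x.mean()) ** 2))
    if p_signal <= 0.0:
        raise ValueError("signal has zero power; SNR is undefined")
    rng = np.random.default_rng(seed)
    if color == "white":
        w = rng.standard_normal(x.shape)
    elif color == "signal":
        spec = np.fft.rfft(x - x.mean())
        phases = rng.uniform(0.0, 2.0 * math.pi, size=len(spec))
        phases[0] = 0.0
        w = np.fft.irfft(np.abs(spec) * np.exp(1j * phases), n=len(x))
    else:
        raise ValueError(f"unknown noise color {color!r}")
    w -= w.mean()
    p_target = p_signal / 10.0 ** (snr_db / 10.0)
    w *= math.sqrt(p_target / float(np.mean(w * w)))
    return x + w


def noisy_record(
    record: PPGRecord, snr_db: float, seed: int = 0, color: str = "white"
) -> PPGRecord:
    """Both channels of a record with independent noise at the same SNR."""
    return replace(
        record,
        right=add_noise(record.right, snr_db, seed=seed, color=color),
        left=add_noise(record.left, snr_db, seed=seed + 1_000_003, color=color),
        annotations=None,
    )


def write_record_csv(record: PPGRecord, path: str | Path, header: bool = False) -> None:
    """Write a two-column (right, left) sample CSV for one subject."""
    df = pd.DataFrame({"right": record.right, "left": record.left})
    df.to_csv(path, index=False, header=header)


def read_record_csv(
    path: str | Path,
    subject_id: str | None = None,
    fs: float = DEFAULT_FS,
    header: bool | None = None,
) -> PPGRecord:
    """Read a two-column (right, left) sample CSV.

    With ``header=None`` the first line is sniffed: a non-numeric first
    field is treated as a header row.
    """
    path = Path(path)
    if header is None:
        with open(path) as fh:
            first = fh.readline().split(",")[0].strip()
        try:
            float(first)
            header = False
        except ValueError:
            header = True
    df = pd.read_csv(path, header=0 if header else None)
    if df.shape[1] != 2:
        raise ValueError(f"{path} must have exactly two columns, got {df.shape[1]}")
    right = df.iloc[:, 0].to_numpy(dtype=float)
    left = df.iloc[:, 1].to_numpy(dtype=float)
    return PPGRecord(
        subject_id=subject_id if subject_id is not None else path.stem,
        fs=fs,
        right=right,
        left=left,
        duration=len(right) / fs,
    )
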