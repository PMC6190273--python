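"""Bilateral asymmetry features of two-channel PPG.

A stenosed fistula delays and damps the pulse on one arm, so left/right
landmark timings and amplitudes diverge.  Four per-subject features
capture this:

    d1  absolute bilateral pulse-foot time difference        [s]
    d2  absolute bilateral systolic-peak time difference     [s]
        (the pulse-transit-time asymmetry)
    d3  absolute bilateral rise-time difference              [s]
        (rise time = peak time - foot time per channel)
    d4  absolute bilateral normalized-amplitude difference   [-]

Beats are matched across channels by nearest foot times (within half the
median beat period); per-beat differences are aggregated by the median so
an occasional landmark misdetection does not dominate.  Beat amplitudes
are scaled by the larger of the two channels' median pulse amplitudes, so
d4 is invariant to a common gain applied to both channels while still
responding to a genuine left/right attenuation.

The element-wise bilateral difference pattern |xR - xL| and cohort-level
min-max normalization (fit on training rows only, applied unclipped to
test rows) live here too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import FilterSpec, FootDetectorParams, PulseWindow, butterworth_lowpass, segment_record
from .synth import PPGRecord

__all__ = [
    "DifferencePattern",
    "FeatureVector",
    "NormalizationScaler",
    "bilateral_difference",
    "extract_features",
    "features_from_record",
    "cohort_feature_table",
    "fit_minmax",
    "apply_minmax",
]

FEATURE_NAMES = ("d1", "d2", "d3", "d4")


@dataclass(frozen=True)
class DifferencePattern:
    """Element-wise absolute bilateral difference |xR_i - xL_i|."""

    values: np.ndarray

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class FeatureVector:
    d1: float  # s
    d2: float  # s
    d3: float  # s
    d4: float  # dimensionless
    normalized: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.d1, self.d2, self.d3, self.d4], dtype=float)


def bilateral_difference(xR: np.ndarray, xL: np.ndarray) -> DifferencePattern:
    """Difference pattern of Eq.-style element-wise |right - left| samples."""
    xR = np.asarray(xR, dtype=float)
    xL = np.asarray(xL, dtype=float)
    if xR.shape != xL.shape:
        raise ValueError(f"channel length mismatch: {xR.shape} vs {xL.shape}")
    if xR.size < 1:
        raise ValueError("need at least one sample")
    return DifferencePattern(values=np.abs(xR - xL))


def _match_beats(
    feet_R: np.ndarray, feet_L: np.ndarray, fs: float
) -> list[tuple[int, int]]:
    """Pair beats across channels by nearest foot time.

    A pair is kept when the foot-time gap is below half the median beat
    period of the left channel; each beat is used at most once.
    """
    if len(feet_L) < 2:
        return []
    half_period = 0.5 * float(np.median(np.diff(feet_L))) / fs
    pairs = []
    used_R: set[int] = set()
    for i, fl in enumerate(feet_L):
        j = int(np.argmin(np.abs(feet_R - fl)))
        if j in used_R:
            continue
        if abs(feet_R[j] - fl) / fs <= half_period:
            pairs.append((j, i))
            used_R.add(j)
    return pairs


def extract_features(
    record: PPGRecord,
    windows_R: list[PulseWindow],
    windows_L: list[PulseWindow],
    *,
    filtered_R: np.ndarray | None = None,
    filtered_L: np.ndarray | None = None,
    spec: FilterSpec = FilterSpec(),
) -> FeatureVector:
    """Raw asymmetry features from per-channel beat windows.

    Amplitudes are read from the filtered channels (filtered here with
    ``spec`` unless provided).  Requires at least two matched beat pairs.
    """
    if filtered_R is None:
        filtered_R = butterworth_lowpass(record.right, spec)
    if filtered_L is None:
        filtered_L = butterworth_lowpass(record.left, spec)
    fs = record.fs

    feet_R = np.array([w.foot_index for w in windows_R], dtype=int)
    feet_L = np.array([w.foot_index for w in windows_L], dtype=int)
    pairs = _match_beats(feet_R, feet_L, fs)
    if len(pairs) < 2:
        raise ValueError(
            f"need >= 2 matched beat pairs across channels, got {len(pairs)}"
        )

    amp_R = np.array(
        [filtered_R[w.peak_index] - filtered_R[w.foot_index] for w in windows_R]
    )
    amp_L = np.array(
        [filtered_L[w.peak_index] - filtered_L[w.foot_index] for w in windows_L]
    )
    # Common scale: the larger channel-median amplitude.  Dividing each
    # channel by its own median would erase the very attenuation d4 measures.
    scale = max(float(np.median(amp_R)), float(np.median(amp_L)))
    if scale <= 0:
        raise ValueError("non-positive pulse amplitudes; cannot scale d4")

    d_foot, d_peak, d_rise, d_amp = [], [], [], []
    for j, i in pairs:
        wR, wL = windows_R[j], windows_L[i]
        d_foot.append(abs(wR.foot_index - wL.foot_index) / fs)
        d_peak.append(abs(wR.peak_index - wL.peak_index) / fs)
        rise_R = (wR.peak_index - wR.foot_index) / fs
        rise_L = (wL.peak_index - wL.foot_index) / fs
        d_rise.append(abs(rise_R - rise_L))
        d_amp.append(abs(amp_R[j] - amp_L[i]) / scale)

    return FeatureVector(
        d1=float(np.median(d_foot)),
        d2=float(np.median(d_peak)),
        d3=float(np.median(d_rise)),
        d4=float(np.median(d_amp)),
    )


def features_from_record(
    record: PPGRecord,
    spec: FilterSpec = FilterSpec(),
    params: FootDetectorParams = FootDetectorParams(),
) -> FeatureVector:
    """Full per-subject pipeline: filter, segment both channels, extract."""
    filt_R = butterworth_lowpass(record.right, spec)
    filt_L = butterworth_lowpass(record.left, spec)
    win_R = segment_record(record.right, record.fs, spec, params)
    win_L = segment_record(record.left, record.fs, spec, params)
    return extract_features(
        record, win_R, win_L, filtered_R=filt_R, filtered_L=filt_L, spec=spec
    )


def cohort_feature_table(
    cohort,
    spec: FilterSpec = FilterSpec(),
    params: FootDetectorParams = FootDetectorParams(),
) -> pd.DataFrame:
    """Feature table (subject_id, d1..d4, dos, class) for a list of
    (PPGRecord, SubjectMeta) pairs."""
    rows = []
    for record, meta in cohort:
        fv = features_from_record(record, spec, params)
        rows.append(
            {
                "subject_id": meta.subject_id,
                "d1": fv.d1,
                "d2": fv.d2,
                "d3": fv.d3,
                "d4": fv.d4,
                "dos": meta.dos,
                "class": meta.true_class,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class NormalizationScaler:
    """Column-wise min-max scaler: x_hat = (x - min) / (max - min)."""

    min_: np.ndarray
    max_: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.max_ < self.min_):
            raise ValueError("per-column max must be >= min")


def fit_minmax(features: np.ndarray) -> NormalizationScaler:
    """Fit column-wise min/max on (training) rows.  Degenerate columns
    (max == min) are permitted and flagged on application."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    return NormalizationScaler(min_=X.min(axis=0), max_=X.max(axis=0))


def apply_minmax(scaler: NormalizationScaler, features: np.ndarray) -> np.ndarray:
    """Apply min-max normalization column-wise.

    Rows outside the fitted range map outside [0, 1] and are deliberately
    not clipped; degenerate columns (max == min) map to 0 with a warning.
    """
    X = np.asarray(features, dtype=float)
    one_row = X.ndim == 1
    if one_row:
        X = X[None, :]
    if X.shape[1] != len(scaler.min_):
        raise ValueError(
            f"column-count mismatch: scaler has {len(scaler.min_)}, data {X.shape[1]}"
        )
    span = scaler.max_ - scaler.min_
    degenerate = span == 0
    if np.any(degenerate):
        warnings.warn(
            f"{int(degenerate.sum())} degenerate column(s) (max == min) mapped to 0",
            stacklevel=2,
        )
    safe = np.where(degenerate, 1.0, span)
    out = (X - scaler.min_) / safe
    out[:, degenerate] = 0.0
    return out[0] if one_row else out


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"d1", "d2", "d3", "d4"} - set(df.columns)
    if missing:
        raise ValueError(f"feature table {path} missing columns {sorted(missing)}")
    return df
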