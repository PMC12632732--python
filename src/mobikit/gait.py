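"""Treadmill gait kinematics from heel-marker trajectories.

On a treadmill the heel marker oscillates along the belt (anterior-
posterior, AP) axis: the most anterior excursion marks heel strike and
the most posterior excursion within a stride marks heel lift. A stride
runs from one heel strike to the next strike of the same foot. From the
two heel markers we compute stride time, stride length (AP distance
from a heel lift to the next strike), and step width (mediolateral
separation of the heels at right heel strike), then block-level means
and coefficients of variation (CV% = SD/mean x 100).

Axes: x = mediolateral (ML), y = anterior-posterior (AP, anterior
positive), z = vertical. Units are millimetres and milliseconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks


class InsufficientDataError(RuntimeError):
    """Raised when a trajectory does not contain enough gait events."""


@dataclass
class MarkerTrajectory:
    """Uniformly sampled 3-D position of one marker (mm)."""

    sample_rate: float
    positions: np.ndarray  # (n_samples, 3): ML, AP, vertical
    marker_id: str = ""
    side: str = ""  # 'left' | 'right' | ''

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n_samples, 3)")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions contain non-finite samples")

    @property
    def ml(self) -> np.ndarray:
        return self.positions[:, 0]

    @property
    def ap(self) -> np.ndarray:
        return self.positions[:, 1]

    @property
    def vertical(self) -> np.ndarray:
        return self.positions[:, 2]

    @property
    def n_samples(self) -> int:
        return self.positions.shape[0]


@dataclass
class GaitEvents:
    """Heel-strike and heel-lift sample indices for one foot.

    Lifts interleave strikes: exactly one lift strictly between each
    pair of consecutive same-foot strikes.
    """

    heel_strikes: np.ndarray
    heel_lifts: np.ndarray

    def __post_init__(self):
        self.heel_strikes = np.asarray(self.heel_strikes, dtype=int)
        self.heel_lifts = np.asarray(self.heel_lifts, dtype=int)
        if np.any(np.diff(self.heel_strikes) <= 0) or np.any(np.diff(self.heel_lifts) <= 0):
            raise ValueError("event indices must be strictly increasing")
        if len(self.heel_lifts) != len(self.heel_strikes) - 1:
            raise ValueError("expected exactly one lift per stride")
        for i, lift in enumerate(self.heel_lifts):
            if not (self.heel_strikes[i] < lift < self.heel_strikes[i + 1]):
                raise ValueError("each lift must fall strictly between its strikes")


@dataclass
class GaitMetrics:
    """Block-level summary: means and CV% of the three gait measures."""

    mean_stride_time_ms: float
    mean_stride_length_mm: float
    mean_step_width_mm: float
    cv_stride_time_pct: float
    cv_stride_length_pct: float
    cv_step_width_pct: float
    n_strides: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def detect_heel_strikes(
    traj: MarkerTrajectory,
    expected_stride_time: float,
    min_separation_frac: float = 0.5,
    prominence_frac: float = 0.25,
) -> np.ndarray:
    """Heel strikes = local maxima of the AP coordinate.

    Peaks must be separated by at least ``min_separation_frac`` of the
    expected stride time and have prominence of at least
    ``prominence_frac`` of the median AP peak-to-trough excursion
    (estimated from a first separation-only pass). Raises
    InsufficientDataError when fewer than two qualifying peaks exist.
    """
    ap = traj.ap
    distance = max(1, int(round(min_separation_frac * expected_stride_time
                                * traj.sample_rate)))
    peaks0, _ = find_peaks(ap, distance=distance)
    troughs0, _ = find_peaks(-ap, distance=distance)
    if len(peaks0) < 2:
        raise InsufficientDataError("fewer than two AP peaks found")
    if len(troughs0):
        excursion = float(np.median(ap[peaks0]) - np.median(ap[troughs0]))
    else:
        excursion = float(np.ptp(ap))
    prominence = prominence_frac * max(excursion, 0.0)
    peaks, _ = find_peaks(ap, distance=distance, prominence=prominence or None)
    if len(peaks) < 2:
        raise InsufficientDataError("fewer than two prominent heel strikes")
    return peaks.astype(int)


def detect_heel_lifts(traj: MarkerTrajectory, strikes: np.ndarray) -> np.ndarray:
    """Heel lift = most posterior AP sample strictly between consecutive strikes.

    Ties on a plateau resolve to the earliest sample.
    """
    strikes = np.asarray(strikes, dtype=int)
    if len(strikes) < 2:
        raise InsufficientDataError("need at least two heel strikes")
    ap = traj.ap
    lifts = np.empty(len(strikes) - 1, dtype=int)
    for i in range(len(strikes) - 1):
        a, b = strikes[i] + 1, strikes[i + 1]
        if a >= b:
            raise InsufficientDataError("no samples between consecutive strikes")
        lifts[i] = a + int(np.argmin(ap[a:b]))  # argmin -> earliest on ties
    return lifts


def compute_stride_times(strikes: np.ndarray, sample_rate: float) -> np.ndarray:
    """Strike-to-strike intervals of the same foot, in ms."""
    strikes = np.asarray(strikes, dtype=int)
    if len(strikes) < 2:
        raise InsufficientDataError("need at least two heel strikes")
    return np.diff(strikes) / sample_rate * 1000.0


def compute_stride_lengths(
    traj: MarkerTrajectory, lifts: np.ndarray, strikes: np.ndarray
) -> np.ndarray:
    """AP distance from each heel lift to the following heel strike, mm.

    Negative values indicate a data-quality problem (backward travel);
    they are retained but flagged with a warning.
    """
    lifts = np.asarray(lifts, dtype=int)
    strikes = np.asarray(strikes, dtype=int)
    if len(lifts) != len(strikes) - 1:
        raise ValueError("expected one lift per stride (len(lifts) == len(strikes)-1)")
    ap = traj.ap
    lengths = ap[strikes[1:]] - ap[lifts]
    n_bad = int(np.sum(lengths < 0))
    if n_bad:
        warnings.warn(f"{n_bad} non-positive stride length(s) retained", stacklevel=2)
    return lengths


def compute_step_widths(
    left: MarkerTrajectory, right: MarkerTrajectory, right_strikes: np.ndarray
) -> np.ndarray:
    """|ML_left - ML_right| at each right heel strike, mm.

    Strikes beyond the left trajectory's extent are skipped with a warning.
    """
    if left.sample_rate != right.sample_rate:
        raise ValueError("trajectories must share a sample rate")
    right_strikes = np.asarray(right_strikes, dtype=int)
    in_range = right_strikes < left.n_samples
    if not np.all(in_range):
        warnings.warn(
            f"{int(np.sum(~in_range))} right strike(s) beyond left trajectory skipped",
            stacklevel=2,
        )
    idx = right_strikes[in_range]
    return np.abs(left.ml[idx] - right.ml[idx])


def summarize_gait(
    stride_times_ms: np.ndarray,
    stride_lengths_mm: np.ndarray,
    step_widths_mm: np.ndarray,
    min_strides: int = 10,
) -> GaitMetrics:
    """Block-level means and CV% (sample SD, n-1 denominator).

    Emits a warning when fewer than ``min_strides`` strides are
    available (partial blocks are summarized over what exists).
    """
    from .stats import cv_percent

    arrays = {
        "stride time": np.asarray(stride_times_ms, dtype=float),
        "stride length": np.asarray(stride_lengths_mm, dtype=float),
        "step width": np.asarray(step_widths_mm, dtype=float),
    }
    for name, arr in arrays.items():
        if arr.size == 0:
            raise InsufficientDataError(f"no {name} values to summarize")
        if arr.mean() <= 0:
            raise ValueError(f"non-positive mean {name}: CV undefined")
    n_strides = len(arrays["stride time"])
    if n_strides < min_strides:
        warnings.warn(
            f"only {n_strides} strides in block (minimum recommended {min_strides})",
            stacklevel=2,
        )
    means = {k: float(v.mean()) for k, v in arrays.items()}
    cvs = {k: cv_percent(v) if len(v) > 1 else 0.0 for k, v in arrays.items()}
    return GaitMetrics(
        mean_stride_time_ms=means["stride time"],
        mean_stride_length_mm=means["stride length"],
        mean_step_width_mm=means["step width"],
        cv_stride_time_pct=cvs["stride time"],
        cv_stride_length_pct=cvs["stride length"],
        cv_step_width_pct=cvs["step width"],
        n_strides=n_strides,
    )


def analyze_block(
    left: MarkerTrajectory,
    right: MarkerTrajectory,
    expected_stride_time: float,
) -> tuple[GaitMetrics, GaitEvents]:
    """Full per-block gait analysis driven by the right foot.

    Strides (time and length) are taken from the right heel marker;
    step width is evaluated at right heel strikes against the left heel.
    """
    strikes = detect_heel_strikes(right, expected_stride_time)
    lifts = detect_heel_lifts(right, strikes)
    events = GaitEvents(strikes, lifts)
    times = compute_stride_times(strikes, right.sample_rate)
    lengths = compute_stride_lengths(right, lifts, strikes)
    widths = compute_step_widths(left, right, strikes)
    return summarize_gait(times, lengths, widths), events
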