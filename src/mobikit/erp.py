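"""ERP processing: zero-phase band-pass filtering, average reference,
spherical-spline bad-channel interpolation, epoching with baseline
correction, grand averages, difference waves, and component peak
extraction (P2 / N2 / P3).

Conventions: data are microvolts; epochs run from -100 ms to +800 ms
around stimulus onset; component windows and electrodes follow the
standard visual Go/NoGo literature (P2 at FCz 200-280 ms, N2 at FCz
280-380 ms, P3 at CPz 350-500 ms).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numpy.polynomial import legendre
from scipy.signal import firwin, fftconvolve


@dataclass
class ContinuousEEG:
    """Continuous multichannel recording (channels x samples, microvolts)."""

    data: np.ndarray
    sample_rate: float
    labels: list[str]
    montage: pd.DataFrame | None = None  # label-indexed x, y, z unit-sphere

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.labels = list(self.labels)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.labels):
            raise ValueError("data must be (n_channels, n_samples) matching labels")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not present") from None


@dataclass
class EpochSet:
    """Stimulus-locked epochs: channels x time x trials with trial labels.

    ``trials`` carries one row per epoch with at least the columns
    condition, response_type, group, participant.
    """

    data: np.ndarray
    times: np.ndarray  # seconds relative to stimulus onset
    sample_rate: float
    labels: list[str]
    trials: pd.DataFrame
    montage: pd.DataFrame | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (channels, time, trials)")
        if self.data.shape[1] != len(self.times):
            raise ValueError("time axis mismatch")
        if self.data.shape[2] != len(self.trials):
            raise ValueError("trials metadata length mismatch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    def channel_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not present") from None


@dataclass
class ERPAverage:
    """Averaged waveform (channels x time, microvolts) plus bookkeeping."""

    data: np.ndarray
    times: np.ndarray
    sample_rate: float
    labels: list[str]
    n_trials: int = 0
    meta: dict = field(default_factory=dict)

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.data[self.labels.index(label)]
        except ValueError:
            raise KeyError(f"channel {label!r} not present") from None


@dataclass
class ComponentSpec:
    """Where and when to look for an ERP component peak."""

    name: str
    electrode: str
    window_ms: tuple[float, float]
    polarity: int  # +1 (positive peak) or -1 (negative)
    topo_halfwidth_ms: float

    def __post_init__(self):
        if self.polarity not in (+1, -1):
            raise ValueError("polarity must be +1 or -1")
        if self.name == "N2" and self.polarity != -1:
            raise ValueError("N2 is a negative-going component")


#: a-priori component definitions (fronto-central P2/N2, centro-parietal P3)
DEFAULT_COMPONENTS = [
    ComponentSpec("P2", "FCz", (200.0, 280.0), +1, 25.0),
    ComponentSpec("N2", "FCz", (280.0, 380.0), -1, 25.0),
    ComponentSpec("P3", "CPz", (350.0, 500.0), +1, 50.0),
]


@dataclass
class PeakResult:
    amplitude_uv: float
    latency_ms: float
    boundary: bool  # extremum sits on the window edge (monotone segment)


# ---------------------------------------------------------------------------
# preprocessing


def design_bandpass(
    sample_rate: float,
    low: float = 0.25,
    high: float = 40.0,
    transition_low: float = 0.25,
) -> np.ndarray:
    """Hamming-windowed linear-phase FIR band-pass kernel.

    Kernel length scales with the low-edge transition bandwidth
    (roughly 3.3 / transition cycles), which dominates for the narrow
    0.25 Hz high-pass edge used here.
    """
    if sample_rate <= 2 * high:
        raise ValueError("sample rate must exceed twice the high cutoff")
    numtaps = int(np.ceil(3.3 * sample_rate / transition_low))
    numtaps += 1 - numtaps % 2  # odd length -> symmetric, integer delay
    return firwin(numtaps, [low, high], window="hamming",
                  pass_zero=False, fs=sample_rate)


def _zero_phase(data: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Forward-backward FIR filtering (zero net phase shift).

    The symmetric kernel is applied twice (second pass time-reversed),
    with odd-symmetric edge padding as in conventional filtfilt.
    """
    n = data.shape[-1]
    pad = min(n - 1, len(kernel))
    left = 2.0 * data[..., :1] - data[..., 1:pad + 1][..., ::-1]
    right = 2.0 * data[..., -1:] - data[..., -pad - 1:-1][..., ::-1]
    x = np.concatenate([left, data, right], axis=-1)
    k = kernel if x.ndim == 1 else kernel[None, :]
    y = fftconvolve(x, k, mode="same", axes=-1)
    y = fftconvolve(y[..., ::-1], k, mode="same", axes=-1)[..., ::-1]
    return y[..., pad:pad + n]


def bandpass_filter(
    eeg: ContinuousEEG,
    low: float = 0.25,
    high: float = 40.0,
    transition_low: float = 0.25,
) -> ContinuousEEG:
    """Zero-phase 0.25-40 Hz band-pass (Hamming FIR, forward-backward)."""
    kernel = design_bandpass(eeg.sample_rate, low, high, transition_low)
    if eeg.n_samples <= len(kernel):
        raise ValueError(
            f"recording ({eeg.n_samples} samples) shorter than the filter "
            f"kernel ({len(kernel)}); widen transition_low or record longer"
        )
    return replace(eeg, data=_zero_phase(eeg.data, kernel))


def average_reference(eeg: ContinuousEEG) -> ContinuousEEG:
    """Re-reference to the instantaneous mean across channels."""
    if eeg.n_channels < 2:
        raise ValueError("average reference needs at least two channels")
    return replace(eeg, data=eeg.data - eeg.data.mean(axis=0, keepdims=True))


# ---------------------------------------------------------------------------
# spherical-spline interpolation (Perrin-style)


def _g_matrix(cosang: np.ndarray, stiffness: int = 4, n_terms: int = 50) -> np.ndarray:
    n = np.arange(1, n_terms + 1)
    coeffs = np.zeros(n_terms + 1)
    coeffs[1:] = (2 * n + 1) / (n * (n + 1.0)) ** stiffness / (4 * np.pi)
    return legendre.legval(np.clip(cosang, -1.0, 1.0), coeffs)


def spline_interpolation_matrix(
    pos_good: np.ndarray,
    pos_bad: np.ndarray,
    stiffness: int = 4,
    reg: float = 1e-5,
) -> np.ndarray:
    """(n_bad, n_good) matrix mapping good-channel data to bad channels.

    Spherical-spline interpolation on the unit sphere with stiffness
    m=4 and ridge regularization of the self-Gram matrix.
    """
    pos_good = pos_good / np.linalg.norm(pos_good, axis=1, keepdims=True)
    pos_bad = pos_bad / np.linalg.norm(pos_bad, axis=1, keepdims=True)
    k = len(pos_good)
    g_self = _g_matrix(pos_good @ pos_good.T, stiffness) + reg * np.eye(k)
    g_cross = _g_matrix(pos_bad @ pos_good.T, stiffness)
    aug = np.zeros((k + 1, k + 1))
    aug[:k, :k] = g_self
    aug[:k, k] = 1.0
    aug[k, :k] = 1.0
    inv = np.linalg.inv(aug)
    return np.hstack([g_cross, np.ones((len(pos_bad), 1))]) @ inv[:, :k]


def interpolate_bad_channels(eeg: ContinuousEEG, bad: list[str]) -> ContinuousEEG:
    """Replace the listed channels by spherical-spline estimates."""
    if eeg.montage is None:
        raise ValueError("montage with electrode coordinates required")
    bad = list(bad)
    unknown = set(bad) - set(eeg.labels)
    if unknown:
        raise KeyError(f"bad channels not in recording: {sorted(unknown)}")
    good = [lab for lab in eeg.labels if lab not in bad]
    if not bad:
        return eeg
    if len(good) < 4:
        raise ValueError("need at least four good channels to interpolate")
    pos = eeg.montage
    missing = [lab for lab in eeg.labels if lab not in pos.index]
    if missing:
        raise KeyError(f"montage lacks coordinates for: {missing}")
    m = spline_interpolation_matrix(
        pos.loc[good].to_numpy(), pos.loc[bad].to_numpy()
    )
    good_idx = [eeg.labels.index(lab) for lab in good]
    data = eeg.data.copy()
    est = m @ data[good_idx]
    for i, lab in enumerate(bad):
        data[eeg.labels.index(lab)] = est[i]
    return replace(eeg, data=data)


def flag_bad_channels(eeg: ContinuousEEG, z_thresh: float = 5.0) -> list[str]:
    """Candidate bad channels: robust-z of log total power beyond the
    threshold, or flatline. Candidates are meant for explicit human
    confirmation, not silent removal."""
    power = np.log(np.maximum(np.var(eeg.data, axis=1), 1e-30))
    med = np.median(power)
    mad = np.median(np.abs(power - med))
    scale = 1.4826 * mad if mad > 0 else np.std(power) or 1.0
    z = (power - med) / scale
    flat = np.var(eeg.data, axis=1) == 0.0
    return [lab for lab, zi, fl in zip(eeg.labels, z, flat)
            if abs(zi) > z_thresh or fl]


# ---------------------------------------------------------------------------
# epoching and averaging


def epoch_sample_grid(
    sample_rate: float, window_ms: tuple[float, float] = (-100.0, 800.0)
) -> tuple[int, int]:
    """(start_offset, n_samples) of the epoch grid relative to onset.

    The start offset is the nearest sample to the lower bound and the
    length is the nearest-sample count of the full window, so a
    -100..800 ms window at 512 Hz spans samples -51..409 (461 samples).
    """
    tmin, tmax = window_ms[0] / 1000.0, window_ms[1] / 1000.0
    start = int(round(tmin * sample_rate))
    n = int(round((tmax - tmin) * sample_rate))
    return start, n


def epoch(
    eeg: ContinuousEEG,
    onsets_s: np.ndarray,
    trial_info: pd.DataFrame,
    window_ms: tuple[float, float] = (-100.0, 800.0),
    baseline_ms: tuple[float, float] | None = (-100.0, 0.0),
) -> EpochSet:
    """Cut stimulus-locked epochs and baseline-correct them.

    Trials whose window exceeds the recording are dropped (count
    warned). Epochs are sorted by condition then response type when
    those columns are present in ``trial_info``.
    """
    onsets_s = np.asarray(onsets_s, dtype=float)
    if len(onsets_s) != len(trial_info):
        raise ValueError("one metadata row per onset required")
    start, n = epoch_sample_grid(eeg.sample_rate, window_ms)
    times = (start + np.arange(n)) / eeg.sample_rate

    centers = np.round(onsets_s * eeg.sample_rate).astype(int)
    keep = (centers + start >= 0) & (centers + start + n <= eeg.n_samples)
    n_dropped = int(np.sum(~keep))
    if n_dropped:
        warnings.warn(f"{n_dropped} epoch(s) dropped at recording edges",
                      stacklevel=2)
    centers = centers[keep]
    info = trial_info.loc[keep].reset_index(drop=True)

    data = np.empty((eeg.n_channels, n, len(centers)))
    for j, c in enumerate(centers):
        data[:, :, j] = eeg.data[:, c + start:c + start + n]

    if baseline_ms is not None:
        b0, b1 = baseline_ms[0] / 1000.0, baseline_ms[1] / 1000.0
        mask = (times >= b0 - 1e-9) & (times <= b1 + 1e-9)
        if not mask.any():
            raise ValueError("baseline interval contains no samples")
        data -= data[:, mask, :].mean(axis=1, keepdims=True)

    sort_cols = [c for c in ("condition", "response_type") if c in info.columns]
    if sort_cols:
        order = info.sort_values(sort_cols, kind="stable").index.to_numpy()
        data = data[:, :, order]
        info = info.loc[order].reset_index(drop=True)

    return EpochSet(data, times, eeg.sample_rate, list(eeg.labels), info,
                    montage=eeg.montage)


def participant_average(epochs: EpochSet, by: list[str]) -> dict[tuple, ERPAverage]:
    """Per-participant mean waveform for every cell of ``by``.

    Keys are (participant, *cell-levels) tuples.
    """
    out = {}
    cols = ["participant", *by]
    for key, idx in epochs.trials.groupby(cols, sort=True).groups.items():
        key = key if isinstance(key, tuple) else (key,)
        sel = epochs.data[:, :, epochs.trials.index.get_indexer(idx)]
        out[key] = ERPAverage(
            sel.mean(axis=2), epochs.times, epochs.sample_rate,
            list(epochs.labels), n_trials=sel.shape[2],
            meta=dict(zip(cols, key)),
        )
    return out


def grand_average(
    epochs: EpochSet | list[EpochSet], by: list[str]
) -> dict[tuple, ERPAverage]:
    """Grand average: participant means first, then an unweighted mean
    across participants (each participant counts once regardless of its
    trial count)."""
    if isinstance(epochs, EpochSet):
        parts = participant_average(epochs, by)
    else:
        parts = {}
        for ep in epochs:
            parts.update(participant_average(ep, by))
    cells: dict[tuple, list[ERPAverage]] = {}
    for key, avg in parts.items():
        cells.setdefault(key[1:], []).append(avg)
    out = {}
    for cell, avgs in cells.items():
        data = np.mean([a.data for a in avgs], axis=0)
        a0 = avgs[0]
        out[cell] = ERPAverage(
            data, a0.times, a0.sample_rate, list(a0.labels),
            n_trials=sum(a.n_trials for a in avgs),
            meta={"by": by, "cell": cell, "n_participants": len(avgs)},
        )
    return out


def difference_wave(cr_avg: ERPAverage, hit_avg: ERPAverage) -> ERPAverage:
    """Correct-Rejection minus Hit waveform, elementwise."""
    if cr_avg.data.shape != hit_avg.data.shape or cr_avg.labels != hit_avg.labels:
        raise ValueError("averages must share channels and time axis")
    return ERPAverage(
        cr_avg.data - hit_avg.data, cr_avg.times, cr_avg.sample_rate,
        list(cr_avg.labels),
        n_trials=cr_avg.n_trials + hit_avg.n_trials,
        meta={"contrast": "CR-Hit", "a": cr_avg.meta, "b": hit_avg.meta},
    )


def extract_peak(
    avg: ERPAverage,
    spec: ComponentSpec,
    window_ms: tuple[float, float] | None = None,
) -> PeakResult:
    """Signed extremum of the component's electrode within its window.

    ``window_ms`` overrides the spec's window (used for per-group
    adjusted windows). Ties resolve to the earliest sample; an extremum
    on the window edge is flagged as a boundary peak.
    """
    lo, hi = window_ms if window_ms is not None else spec.window_ms
    wave = avg.channel(spec.electrode)
    t_ms = avg.times * 1000.0
    mask = (t_ms >= lo - 1e-9) & (t_ms <= hi + 1e-9)
    if not mask.any():
        raise ValueError("component window outside the epoch")
    seg = wave[mask]
    idx = int(np.argmax(seg)) if spec.polarity > 0 else int(np.argmin(seg))
    where = np.flatnonzero(mask)
    return PeakResult(
        amplitude_uv=float(seg[idx]),
        latency_ms=float(t_ms[where[idx]]),
        boundary=idx in (0, len(seg) - 1),
    )


def topographic_window_mean(
    avg: ERPAverage, center_ms: float, halfwidth_ms: float
) -> pd.Series:
    """Per-channel time-mean over [center - halfwidth, center + halfwidth].

    A zero halfwidth returns the value at the nearest sample.
    """
    t_ms = avg.times * 1000.0
    if center_ms < t_ms[0] or center_ms > t_ms[-1]:
        raise ValueError("window center outside the epoch")
    if halfwidth_ms == 0:
        j = int(np.argmin(np.abs(t_ms - center_ms)))
        vals = avg.data[:, j]
    else:
        mask = (t_ms >= center_ms - halfwidth_ms - 1e-9) & \
               (t_ms <= center_ms + halfwidth_ms + 1e-9)
        if not mask.any():
            raise ValueError("window contains no samples")
        vals = avg.data[:, mask].mean(axis=1)
    return pd.Series(vals, index=avg.labels, name=f"{center_ms:g}ms")
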