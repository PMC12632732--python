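"""Synthetic MoBI session generator with known ground truth.

No raw recordings ship with this package, so every downstream stage is
exercised against simulated data whose generating parameters are
retained: heel-marker trajectories on a treadmill (100 Hz), Go/NoGo
event streams (180 trials, 20% NoGo, 400 ms stimuli, 200-400 ms ISI),
and stimulus-locked EEG epochs (512 Hz, -100..800 ms) built from
Gaussian-in-time, scalp-distance-weighted ERP components plus lag-1
autoregressive noise.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .behavior import EventStream, GO, NOGO
from .erp import EpochSet, epoch_sample_grid
from .gait import MarkerTrajectory
from .montage import BIOSEMI64_LABELS, angular_distance, make_montage

HIT = "Hit"
CR = "CorrectRejection"


# ---------------------------------------------------------------------------
# gait


@dataclass
class GaitSimConfig:
    """Ground-truth gait parameters for one walking block.

    Means are the per-block targets; CVs are percent coefficients of
    variation of the per-stride draws. ``duty_factor`` is the fraction
    of the stride spent in stance (heel strike to heel lift).
    """

    mean_stride_time: float = 1.30  # s
    mean_stride_length: float = 1237.0  # mm
    mean_step_width: float = 196.0  # mm
    cv_stride_time: float = 3.0  # %
    cv_stride_length: float = 2.7  # %
    cv_step_width: float = 9.0  # %
    duty_factor: float = 0.62
    n_strides: int = 120
    sample_rate: float = 100.0
    noise_sd_mm: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.mean_stride_time, self.mean_stride_length,
               self.mean_step_width) <= 0:
            raise ValueError("means must be positive")
        if min(self.cv_stride_time, self.cv_stride_length,
               self.cv_step_width) < 0:
            raise ValueError("CVs must be non-negative")
        if not 0 < self.duty_factor < 1:
            raise ValueError("duty_factor must be in (0, 1)")
        if self.n_strides < 2:
            raise ValueError("need at least two strides")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")


@dataclass
class GaitTruth:
    """Per-foot ground-truth draws and event sample indices."""

    strikes: np.ndarray  # sample index of each heel strike
    lifts: np.ndarray  # sample index of each heel lift (one per stride)
    stride_times_s: np.ndarray
    stride_lengths_mm: np.ndarray
    step_widths_mm: np.ndarray  # defined at this foot's strikes


@dataclass
class GaitSimResult:
    left: MarkerTrajectory
    right: MarkerTrajectory
    truth_left: GaitTruth
    truth_right: GaitTruth
    config: GaitSimConfig


def _draw_positive(rng, mean, cv_pct, size, floor, what, max_retries=100):
    sd = cv_pct / 100.0 * mean
    vals = rng.normal(mean, sd, size)
    for _ in range(max_retries):
        bad = vals <= floor
        if not bad.any():
            return vals
        vals[bad] = rng.normal(mean, sd, int(bad.sum()))
    raise ValueError(f"could not draw positive {what} after {max_retries} retries")


def _foot_ap(times, strike_times, stride_times, lengths, duty):
    """Piecewise AP trajectory: +L/2 at strike, linear descent to -L/2 at
    heel lift (end of stance), half-cosine swing back up to the next
    strike's +L/2."""
    ap = np.empty_like(times)
    s0 = strike_times[0]
    pre = times < s0
    # monotone half-cosine approach to the first strike: unique max at s0
    ap[pre] = -lengths[0] / 2 + lengths[0] * (1 - np.cos(np.pi * times[pre] / s0)) / 2
    for i in range(len(stride_times)):
        t0 = strike_times[i]
        t1 = t0 + duty * stride_times[i]
        t2 = strike_times[i + 1]
        li = lengths[i]
        lnext = lengths[i + 1] if i + 1 < len(lengths) else lengths[i]
        stance = (times >= t0) & (times < t1)
        ap[stance] = li / 2 - li * (times[stance] - t0) / (t1 - t0)
        swing = (times >= t1) & (times < t2)
        u = (times[swing] - t1) / (t2 - t1)
        ap[swing] = -li / 2 + (lnext / 2 + li / 2) * (1 - np.cos(np.pi * u)) / 2
    tail = times >= strike_times[-1]
    ln = lengths[-1]
    ap[tail] = ln / 2 - ln * (times[tail] - strike_times[-1]) \
        / (duty * stride_times[-1])
    return ap


def simulate_gait(config: GaitSimConfig) -> GaitSimResult:
    """Two heel-marker trajectories (left, right) with retained truth.

    Per-stride stride times and lengths are independent normal draws at
    the configured mean and CV; feet are phase-shifted by half a
    stride. The mediolateral coordinates are piecewise constant between
    strikes at +-W/2 with per-step width draws, so step width measured
    at a strike equals that step's drawn width exactly.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sample_rate
    min_dt = 4.0 / fs  # a stride must span at least a few samples

    feet = {}
    for side, t_start in (("right", 0.5 * cfg.mean_stride_time),
                          ("left", 1.0 * cfg.mean_stride_time)):
        st = _draw_positive(rng, cfg.mean_stride_time,
                            cfg.cv_stride_time, cfg.n_strides, min_dt,
                            "stride time")
        sl = _draw_positive(rng, cfg.mean_stride_length,
                            cfg.cv_stride_length, cfg.n_strides + 1, 0.0,
                            "stride length")
        strike_times = t_start + np.concatenate([[0.0], np.cumsum(st)])
        feet[side] = (st, sl, strike_times)

    t_end = max(feet[s][2][-1] for s in feet) + 0.5 * cfg.mean_stride_time
    n_samples = int(round(t_end * fs)) + 1
    times = np.arange(n_samples) / fs

    widths = {
        side: _draw_positive(rng, cfg.mean_step_width, cfg.cv_step_width,
                             cfg.n_strides + 1, 0.0, "step width")
        for side in ("right", "left")
    }

    trajs, truths = {}, {}
    for side in ("right", "left"):
        st, sl, strike_times = feet[side]
        ap = _foot_ap(times, strike_times, st, sl, cfg.duty_factor)
        # ML: piecewise constant between this foot's strikes at +-W/2
        w = widths[side]
        ml_sign = 1.0 if side == "right" else -1.0
        ml = np.empty_like(times)
        seg = np.searchsorted(strike_times, times, side="right")
        ml[:] = ml_sign * w[np.clip(seg, 0, len(w) - 1)] / 2.0
        # small vertical bump during swing, zero in stance
        z = np.zeros_like(times)
        for i in range(len(st)):
            t1 = strike_times[i] + cfg.duty_factor * st[i]
            t2 = strike_times[i + 1]
            swing = (times >= t1) & (times < t2)
            z[swing] = 30.0 * np.sin(np.pi * (times[swing] - t1) / (t2 - t1))

        pos = np.column_stack([ml, ap, z])
        if cfg.noise_sd_mm > 0:
            pos = pos + rng.normal(0.0, cfg.noise_sd_mm, pos.shape)
        trajs[side] = MarkerTrajectory(fs, pos, marker_id=f"{side[0].upper()}HEEL",
                                       side=side)
        strikes_idx = np.round(strike_times * fs).astype(int)
        lifts_idx = np.round((strike_times[:-1] + cfg.duty_factor * st) * fs).astype(int)
        truths[side] = GaitTruth(
            strikes=strikes_idx,
            lifts=lifts_idx,
            stride_times_s=st.copy(),
            stride_lengths_mm=sl[:-1].copy(),
            step_widths_mm=w[1:1 + len(strikes_idx)].copy(),
        )

    # step width at a right strike is the |ML_left - ML_right| there;
    # align left ML segments to right strikes so the measurement equals
    # the drawn width exactly
    r_strikes = feet["right"][2]
    w_r = widths["right"]
    seg = np.searchsorted(r_strikes, times, side="right")
    half = w_r[np.clip(seg, 0, len(w_r) - 1)] / 2.0
    left_pos = trajs["left"].positions.copy()
    left_pos[:, 0] = -half
    right_pos = trajs["right"].positions.copy()
    right_pos[:, 0] = half
    if cfg.noise_sd_mm > 0:
        left_pos[:, 0] += rng.normal(0.0, cfg.noise_sd_mm, n_samples)
        right_pos[:, 0] += rng.normal(0.0, cfg.noise_sd_mm, n_samples)
    trajs["left"] = MarkerTrajectory(fs, left_pos, "LHEEL", "left")
    trajs["right"] = MarkerTrajectory(fs, right_pos, "RHEEL", "right")
    for side in ("right", "left"):
        s_idx = truths[side].strikes
        truths[side].step_widths_mm = w_r[np.clip(
            np.searchsorted(r_strikes, s_idx / fs, side="right"),
            0, len(w_r) - 1)]

    return GaitSimResult(trajs["left"], trajs["right"],
                         truths["left"], truths["right"], cfg)


# ---------------------------------------------------------------------------
# behavior


@dataclass
class BehaviorSimConfig:
    """One Go/NoGo block: 180 trials, 20% NoGo, 400 ms stimuli,
    uniform 200-400 ms inter-stimulus interval, lognormal reaction
    times parameterized by their median."""

    n_trials: int = 180
    p_nogo: float = 0.20
    stimulus_duration: float = 400.0  # ms
    isi_range: tuple[float, float] = (200.0, 400.0)  # ms
    hit_rate: float = 0.96
    false_alarm_rate: float = 0.20
    rt_median: float = 350.0  # ms
    rt_lognormal_sigma: float = 0.20
    exact_counts: bool = True  # exactly round(p_nogo * n) NoGo stimuli
    start_offset: float = 1.0  # s of lead-in before the first stimulus
    seed: int = 0

    def __post_init__(self):
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        for r in (self.p_nogo, self.hit_rate, self.false_alarm_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.isi_range[0] > self.isi_range[1]:
            raise ValueError("ISI lower bound exceeds upper bound")


def simulate_behavior(config: BehaviorSimConfig) -> EventStream:
    """Event stream for one block.

    Onsets accumulate stimulus duration plus a uniform ISI draw.
    Responses occur with probability hit_rate on Go trials and
    false_alarm_rate on NoGo trials, at onset + lognormal RT.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_trials
    isi_s = rng.uniform(cfg.isi_range[0], cfg.isi_range[1], n) / 1000.0
    gaps = cfg.stimulus_duration / 1000.0 + isi_s
    onsets = cfg.start_offset + np.concatenate([[0.0], np.cumsum(gaps[:-1])])

    if cfg.exact_counts:
        n_nogo = int(round(cfg.p_nogo * n))
        types = np.array([NOGO] * n_nogo + [GO] * (n - n_nogo), dtype=object)
        rng.shuffle(types)
    else:
        types = np.where(rng.random(n) < cfg.p_nogo, NOGO, GO).astype(object)

    responses = []
    for i in range(n):
        p_resp = cfg.hit_rate if types[i] == GO else cfg.false_alarm_rate
        if rng.random() < p_resp:
            rt_ms = cfg.rt_median * np.exp(cfg.rt_lognormal_sigma
                                           * rng.standard_normal())
            responses.append(onsets[i] + rt_ms / 1000.0)
    return EventStream(onsets, types, np.array(responses))


# ---------------------------------------------------------------------------
# ERP epochs


@dataclass
class ErpComponent:
    """One simulated ERP component.

    The time course is a Gaussian of SD ``width_ms`` centred at
    ``latency_ms`` (jittered per trial); the spatial map decays with
    great-circle distance from ``electrode`` as exp(-(d/spread)^2), so
    the configured amplitude is exact at the centre electrode.
    ``scale`` maps (condition, response_type, group) cells to
    multipliers; missing cells default to 1.
    """

    name: str
    electrode: str
    latency_ms: float
    amplitude_uv: float
    width_ms: float = 35.0
    spread: float = 0.9  # radians of great-circle distance
    scale: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.name == "N2" and self.amplitude_uv >= 0:
            raise ValueError("N2 amplitude must be negative")
        if self.name in ("P2", "P3") and self.amplitude_uv <= 0:
            raise ValueError(f"{self.name} amplitude must be positive")

    def multiplier(self, condition, response_type, group) -> float:
        return float(self.scale.get((condition, response_type, group), 1.0))


def default_components() -> list[ErpComponent]:
    """Canonical Go/NoGo component set with CR-enhanced P3/P2."""
    return [
        ErpComponent("P2", "FCz", 240.0, 4.0),
        ErpComponent("N2", "FCz", 330.0, -3.0),
        ErpComponent("P3", "CPz", 420.0, 6.0),
    ]


@dataclass
class ErpSimConfig:
    """Simulated epoched EEG for one participant.

    Noise is lag-1 autoregressive Gaussian per channel and trial,
    spatially independent, with stationary SD ``noise_sd``.
    """

    channels: list[str] = field(default_factory=lambda: list(BIOSEMI64_LABELS))
    sample_rate: float = 512.0
    epoch_window_ms: tuple[float, float] = (-100.0, 800.0)
    components: list[ErpComponent] = field(default_factory=default_components)
    conditions: list[str] = field(default_factory=lambda: ["S-NF-T", "W-NF-T", "W-F-T"])
    response_types: list[str] = field(default_factory=lambda: [HIT, CR])
    group: str = "TD"
    participant: str = "p01"
    latency_jitter_sd: float = 10.0  # ms
    noise_sd: float = 10.0  # microvolts
    noise_autocorrelation: float = 0.95  # lag-1 coefficient
    n_trials_per_cell: int = 30
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.noise_autocorrelation < 1.0:
            raise ValueError("autocorrelation must lie in [0, 1)")
        if self.noise_sd < 0 or self.latency_jitter_sd < 0:
            raise ValueError("noise and jitter SDs must be non-negative")
        if self.n_trials_per_cell < 1:
            raise ValueError("need at least one trial per cell")


def _ar1_noise(rng, shape, sd, rho):
    """Stationary AR(1) noise along the last axis."""
    if sd == 0:
        return np.zeros(shape)
    e = rng.standard_normal(shape) * sd * np.sqrt(1.0 - rho**2)
    e[..., 0] /= np.sqrt(1.0 - rho**2)  # stationary start
    return lfilter([1.0], [1.0, -rho], e, axis=-1)


def simulate_erp_epochs(config: ErpSimConfig) -> EpochSet:
    """Epoched EEG for one participant with known component truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    montage = make_montage(cfg.channels)
    start, n_t = epoch_sample_grid(cfg.sample_rate, cfg.epoch_window_ms)
    times = (start + np.arange(n_t)) / cfg.sample_rate
    t_ms = times * 1000.0

    spatial = {}
    for comp in cfg.components:
        if comp.electrode not in montage.index:
            raise KeyError(f"unknown electrode {comp.electrode!r} in component "
                           f"{comp.name}")
        ang = angular_distance(montage, comp.electrode).to_numpy()
        spatial[comp.name] = np.exp(-((ang / comp.spread) ** 2))

    n_ch = len(cfg.channels)
    cells = [(c, r) for c in cfg.conditions for r in cfg.response_types]
    n_total = len(cells) * cfg.n_trials_per_cell
    data = np.empty((n_ch, n_t, n_total))
    rows = []
    j = 0
    for cond, resp in cells:
        for _ in range(cfg.n_trials_per_cell):
            trial = _ar1_noise(rng, (n_ch, n_t), cfg.noise_sd,
                               cfg.noise_autocorrelation)
            for comp in cfg.components:
                amp = comp.amplitude_uv * comp.multiplier(cond, resp, cfg.group)
                lat = comp.latency_ms
                if cfg.latency_jitter_sd > 0:
                    lat = lat + cfg.latency_jitter_sd * rng.standard_normal()
                course = amp * np.exp(-((t_ms - lat) ** 2)
                                      / (2.0 * comp.width_ms**2))
                trial += spatial[comp.name][:, None] * course[None, :]
            data[:, :, j] = trial
            rows.append({"condition": cond, "response_type": resp,
                         "group": cfg.group, "participant": cfg.participant})
            j += 1

    return EpochSet(data, times, cfg.sample_rate, list(cfg.channels),
                    pd.DataFrame(rows), montage=montage)


def simulate_erp_study(
    base: ErpSimConfig,
    participants: list[tuple[str, str]],
    subject_scale_sd: float = 0.12,
    seed: int = 0,
) -> list[EpochSet]:
    """One EpochSet per (participant, group), derived deterministically.

    Each participant receives an overall amplitude multiplier drawn
    from Normal(1, subject_scale_sd) — the between-subject variability
    that group-level t statistics operate on — and a child seed from
    the study seed.
    """
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
                   for s in ss.spawn(len(participants) + 1)]
    rng = np.random.default_rng(child_seeds[-1])
    out = []
    for (pid, group), child in zip(participants, child_seeds):
        mult = max(0.1, 1.0 + subject_scale_sd * rng.standard_normal())
        comps = [
            ErpComponent(c.name, c.electrode, c.latency_ms,
                         c.amplitude_uv * mult, c.width_ms, c.spread,
                         dict(c.scale))
            for c in base.components
        ]
        cfg = ErpSimConfig(
            channels=list(base.channels), sample_rate=base.sample_rate,
            epoch_window_ms=base.epoch_window_ms, components=comps,
            conditions=list(base.conditions),
            response_types=list(base.response_types),
            group=group, participant=pid,
            latency_jitter_sd=base.latency_jitter_sd,
            noise_sd=base.noise_sd,
            noise_autocorrelation=base.noise_autocorrelation,
            n_trials_per_cell=base.n_trials_per_cell, seed=child,
        )
        out.append(simulate_erp_epochs(cfg))
    return out


def config_to_dict(cfg) -> dict:
    """Plain-dict view of any simulation config (YAML-friendly)."""
    d = asdict(cfg)
    return d
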