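"""Go/NoGo behavioral scoring: trial classification, reaction time, d-prime.

A block is a stream of stimulus events ('go' = press, 'nogo' = withhold)
and button-press events. Trials are scored as Hit / Miss / FalseAlarm /
CorrectRejection, reaction time is the onset-to-press interval on Hits,
and sensitivity is the signal-detection d' = z(hit rate) - z(false-alarm
rate) with a log-linear correction that keeps ceiling/floor blocks finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

GO = "go"
NOGO = "nogo"

HIT = "Hit"
MISS = "Miss"
FALSE_ALARM = "FalseAlarm"
CORRECT_REJECTION = "CorrectRejection"


@dataclass
class EventStream:
    """Timestamped stimulus and response events for one block.

    Attributes
    ----------
    stim_onsets : seconds, strictly increasing
    stim_types : 'go' / 'nogo' per stimulus
    response_times : seconds, non-negative (button presses)
    """

    stim_onsets: np.ndarray
    stim_types: np.ndarray
    response_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.stim_onsets = np.asarray(self.stim_onsets, dtype=float)
        self.stim_types = np.asarray(self.stim_types, dtype=object)
        self.response_times = np.sort(np.asarray(self.response_times, dtype=float))
        if self.stim_onsets.ndim != 1 or len(self.stim_onsets) != len(self.stim_types):
            raise ValueError("stim_onsets and stim_types must be 1-D and equal length")
        if np.any(np.diff(self.stim_onsets) <= 0):
            raise ValueError("stimulus onsets must be strictly increasing")
        unknown = set(self.stim_types) - {GO, NOGO}
        if unknown:
            raise ValueError(f"unknown stimulus types: {sorted(unknown)}")
        if len(self.response_times) and self.response_times[0] < 0:
            raise ValueError("response times must be non-negative")

    @property
    def n_trials(self) -> int:
        return len(self.stim_onsets)


def classify_trials(
    events: EventStream,
    response_window: tuple[float, float] = (100.0, 1000.0),
    cap_at_next_onset: bool = True,
) -> pd.DataFrame:
    """Score every trial of a block.

    A press is attributed to the most recent stimulus whose response
    window contains it; the window is ``onset + [min_ms, max_ms]`` and, by
    default, is capped at the next stimulus onset so windows never
    overlap. Only the first press in a trial's window counts. Returns a
    TrialTable: one row per stimulus with columns ``trial, type, outcome,
    rt_ms`` (rt_ms is NaN unless the outcome is Hit or FalseAlarm).
    """
    lo_ms, hi_ms = float(response_window[0]), float(response_window[1])
    if lo_ms >= hi_ms:
        raise ValueError("response window min must be below max")
    onsets = events.stim_onsets
    n = len(onsets)
    lo, hi = lo_ms / 1000.0, hi_ms / 1000.0
    if not cap_at_next_onset and n > 1:
        min_gap = float(np.min(np.diff(onsets)))
        if hi > min_gap:
            raise ValueError(
                "response window max exceeds the minimum onset-to-onset "
                "interval; enable cap_at_next_onset or shorten the window"
            )

    win_hi = onsets + hi
    if cap_at_next_onset and n > 1:
        win_hi[:-1] = np.minimum(win_hi[:-1], onsets[1:])
    win_lo = onsets + lo

    rt_ms = np.full(n, np.nan)
    responded = np.zeros(n, dtype=bool)
    for r in events.response_times:
        # most recent stimulus whose window could contain r
        k = int(np.searchsorted(win_lo, r, side="right")) - 1
        if k < 0 or r > win_hi[k] or responded[k]:
            continue
        responded[k] = True
        rt_ms[k] = (r - onsets[k]) * 1000.0

    is_go = events.stim_types == GO
    outcome = np.where(
        is_go,
        np.where(responded, HIT, MISS),
        np.where(responded, FALSE_ALARM, CORRECT_REJECTION),
    )
    return pd.DataFrame(
        {
            "trial": np.arange(n),
            "type": events.stim_types,
            "outcome": outcome,
            "rt_ms": rt_ms,
        }
    )


def outcome_counts(trials: pd.DataFrame) -> dict[str, int]:
    """Tally of the four trial outcomes in a TrialTable."""
    c = trials["outcome"].value_counts()
    return {k: int(c.get(k, 0)) for k in (HIT, MISS, FALSE_ALARM, CORRECT_REJECTION)}


def dprime(
    n_hit: int,
    n_miss: int,
    n_fa: int,
    n_cr: int,
    correction: str | None = "loglinear",
) -> float:
    """Signal-detection sensitivity d' = z(hit rate) - z(false-alarm rate).

    With ``correction='loglinear'`` (the default) 0.5 is added to each
    numerator and 1 to each denominator, so perfect or empty rates stay
    finite. ``correction=None`` uses raw rates (infinite at 0 or 1).
    """
    n_go = n_hit + n_miss
    n_nogo = n_fa + n_cr
    if n_go <= 0 or n_nogo <= 0:
        raise ValueError("need at least one Go and one NoGo trial")
    if correction == "loglinear":
        h = (n_hit + 0.5) / (n_go + 1.0)
        f = (n_fa + 0.5) / (n_nogo + 1.0)
    elif correction is None:
        h = n_hit / n_go
        f = n_fa / n_nogo
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return float(sps.norm.ppf(h) - sps.norm.ppf(f))


def mean_rt(trials: pd.DataFrame) -> float:
    """Arithmetic mean reaction time (ms) over Hits only.

    False-alarm presses never enter the mean. Returns NaN (with a
    warning) when the block contains no Hit.
    """
    rts = trials.loc[trials["outcome"] == HIT, "rt_ms"]
    if rts.empty:
        warnings.warn("no Hit trials: mean RT undefined", stacklevel=2)
        return float("nan")
    return float(rts.mean())


def score_block(
    events: EventStream,
    response_window: tuple[float, float] = (100.0, 1000.0),
) -> dict:
    """Classify a block and return its summary (counts, d', mean RT)."""
    trials = classify_trials(events, response_window)
    counts = outcome_counts(trials)
    return {
        **{f"n_{k.lower()}": v for k, v in counts.items()},
        "d_prime": dprime(counts[HIT], counts[MISS], counts[FALSE_ALARM],
                          counts[CORRECT_REJECTION]),
        "mean_rt_ms": mean_rt(trials) if counts[HIT] else float("nan"),
    }
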