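"""Pointwise t-maps with a consecutivity (run-length) cluster criterion.

Every channel x time sample gets a two-tailed t statistic — paired
across participants for within-group contrasts (Hits vs Correct
Rejections), pooled two-sample for between-group contrasts on CR-Hit
difference waves. A cluster is a maximal run of consecutive samples on
one channel that all pass the significance threshold with the same
t-sign; only runs of at least ``min_run`` samples are reported (10
samples is about 19.5 ms at 512 Hz). Channels are treated
independently — there is no cross-channel multiplicity control, so
clusters are exploratory descriptions, not family-wise-corrected tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .erp import ERPAverage


@dataclass
class TMap:
    """t and two-tailed p per channel x sample."""

    t: np.ndarray
    p: np.ndarray
    df: int
    labels: list[str]
    times: np.ndarray  # seconds
    contrast: str  # 'paired' | 'independent'
    zero_variance: np.ndarray = field(default=None)  # bool mask, flagged samples

    def __post_init__(self):
        if self.zero_variance is None:
            self.zero_variance = np.zeros_like(self.t, dtype=bool)


@dataclass
class ClusterResult:
    channel: str
    start_ms: float
    end_ms: float
    length: int
    mean_t: float
    peak_t: float
    sign: int  # +1 | -1

    def as_dict(self) -> dict:
        return {
            "channel": self.channel,
            "start_ms": self.start_ms,
            "end_ms": self.end_ms,
            "length": self.length,
            "mean_t": self.mean_t,
            "peak_t": self.peak_t,
            "sign": self.sign,
        }


def stack_averages(avgs: list[ERPAverage]) -> np.ndarray:
    """(participants, channels, time) array from per-participant averages."""
    if not avgs:
        raise ValueError("empty average list")
    ref = avgs[0]
    for a in avgs[1:]:
        if a.data.shape != ref.data.shape or a.labels != ref.labels:
            raise ValueError("averages must share channels and time axis")
    return np.stack([a.data for a in avgs], axis=0)


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x
    return stack_averages(list(x))


def pointwise_paired_t(a, b, labels=None, times=None) -> TMap:
    """Paired t per channel x sample across participants.

    ``a`` and ``b`` are matched per-participant averages (lists of
    ERPAverage in the same participant order, or arrays of shape
    (participants, channels, time)). Zero-variance samples get t = 0,
    p = 1 and are flagged, never significant.
    """
    a_list = list(a) if not isinstance(a, np.ndarray) else None
    xa, xb = _as_array(a), _as_array(b)
    if xa.shape != xb.shape:
        raise ValueError("paired sets must have identical shape")
    n = xa.shape[0]
    if n < 3:
        raise ValueError("paired t needs at least three participants")
    if labels is None or times is None:
        if a_list is None:
            raise ValueError("labels and times required with array input")
        labels, times = a_list[0].labels, a_list[0].times
    d = xa - xb
    md = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    zero = sd == 0
    se = np.where(zero, 1.0, sd / np.sqrt(n))
    t = np.where(zero, 0.0, md / se)
    df = n - 1
    p = np.where(zero, 1.0, 2.0 * sps.t.sf(np.abs(t), df))
    return TMap(t, p, df, list(labels), np.asarray(times), "paired", zero)


def pointwise_independent_t(group_a, group_b, labels=None, times=None) -> TMap:
    """Pooled-variance two-sample t per channel x sample.

    Intended for comparing per-participant CR-Hit difference waves
    between groups; df = nA + nB - 2.
    """
    a_list = list(group_a) if not isinstance(group_a, np.ndarray) else None
    xa, xb = _as_array(group_a), _as_array(group_b)
    if xa.shape[1:] != xb.shape[1:]:
        raise ValueError("groups must share channels and time axis")
    na, nb = xa.shape[0], xb.shape[0]
    if min(na, nb) < 2:
        raise ValueError("need at least two participants per group")
    if labels is None or times is None:
        if a_list is None:
            raise ValueError("labels and times required with array input")
        labels, times = a_list[0].labels, a_list[0].times
    df = na + nb - 2
    va = xa.var(axis=0, ddof=1)
    vb = xb.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    zero = sp2 == 0
    se = np.sqrt(np.where(zero, 1.0, sp2) * (1.0 / na + 1.0 / nb))
    t = np.where(zero, 0.0, (xa.mean(axis=0) - xb.mean(axis=0)) / se)
    p = np.where(zero, 1.0, 2.0 * sps.t.sf(np.abs(t), df))
    return TMap(t, p, df, list(labels), np.asarray(times), "independent", zero)


def find_clusters(
    tmap: TMap, alpha: float = 0.05, min_run: int = 10
) -> list[ClusterResult]:
    """Maximal same-sign runs of consecutive significant samples.

    A sample is significant when p < alpha and it is not flagged as
    zero-variance; a run breaks whenever significance lapses or the t
    sign flips. Runs shorter than ``min_run`` are discarded. Boundaries
    are reported in ms of epoch time.
    """
    if min_run < 1:
        raise ValueError("min_run must be at least 1")
    t_ms = tmap.times * 1000.0
    sig = (tmap.p < alpha) & ~tmap.zero_variance
    sign = np.sign(tmap.t).astype(int)
    clusters: list[ClusterResult] = []
    n_ch, n_t = tmap.t.shape
    for ch in range(n_ch):
        j = 0
        while j < n_t:
            if not sig[ch, j]:
                j += 1
                continue
            s = sign[ch, j]
            k = j
            while k + 1 < n_t and sig[ch, k + 1] and sign[ch, k + 1] == s:
                k += 1
            length = k - j + 1
            if length >= min_run:
                seg = tmap.t[ch, j:k + 1]
                clusters.append(ClusterResult(
                    channel=tmap.labels[ch],
                    start_ms=float(t_ms[j]),
                    end_ms=float(t_ms[k]),
                    length=length,
                    mean_t=float(seg.mean()),
                    peak_t=float(seg[np.argmax(np.abs(seg))]),
                    sign=int(s),
                ))
            j = k + 1
    return clusters


def significance_mask(
    tmap: TMap, alpha: float = 0.05, min_run: int = 10
) -> np.ndarray:
    """Boolean channels x time mask of samples inside reported clusters."""
    mask = np.zeros_like(tmap.t, dtype=bool)
    idx = {lab: i for i, lab in enumerate(tmap.labels)}
    t_ms = tmap.times * 1000.0
    for cl in find_clusters(tmap, alpha, min_run):
        ch = idx[cl.channel]
        cols = (t_ms >= cl.start_ms - 1e-9) & (t_ms <= cl.end_ms + 1e-9)
        mask[ch, cols] = True
    return mask


def permutation_cluster_null(
    a, b, n_permutations: int = 500, alpha: float = 0.05,
    min_run: int = 10, seed: int | None = None, labels=None, times=None,
) -> np.ndarray:
    """Optional label-shuffling null for the paired contrast.

    Returns the distribution of the largest cluster length (in samples)
    across channel rows under random sign flips of the paired
    differences. This is an extension beyond the plain run-length rule,
    for calibrating how often long runs arise by chance.
    """
    xa, xb = _as_array(a), _as_array(b)
    if labels is None or times is None:
        seq = list(a) if not isinstance(a, np.ndarray) else None
        if seq is None:
            raise ValueError("labels and times required with array input")
        labels, times = seq[0].labels, seq[0].times
    d = xa - xb
    rng = np.random.default_rng(seed)
    n = d.shape[0]
    out = np.zeros(n_permutations, dtype=int)
    for i in range(n_permutations):
        flips = rng.choice([-1.0, 1.0], size=n)[:, None, None]
        dd = d * flips
        md = dd.mean(axis=0)
        sd = dd.std(axis=0, ddof=1)
        zero = sd == 0
        t = np.where(zero, 0.0, md / np.where(zero, 1.0, sd / np.sqrt(n)))
        p = np.where(zero, 1.0, 2.0 * sps.t.sf(np.abs(t), n - 1))
        tm = TMap(t, p, n - 1, list(labels), np.asarray(times), "paired", zero)
        cl = find_clusters(tm, alpha, min_run=1)
        out[i] = max((c.length for c in cl), default=0)
    return out
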