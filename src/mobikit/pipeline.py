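"""Session orchestration: manifests, run configuration, and the
end-to-end behavior -> gait -> ERP -> cluster -> ANOVA run.

A session manifest lists participants (with group labels) and their
blocks; each block carries a condition label from the closed set
{S-NF-T, W-NF-T, W-F-T, W-NF-NT, W-F-NT} plus paths to its events,
motion, and EEG files. Task-inclusive conditions end in '-T'; no-task
blocks contribute only to gait. Every output table carries the
configuration hash so two runs with equal hashes are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as bhv
from . import clusterstats as cst
from . import erp as erpmod
from . import gait as gaitmod
from . import io as mio
from . import stats as mst
from .montage import make_montage, write_locations
from .synth import (
    BehaviorSimConfig, ErpSimConfig, GaitSimConfig,
    simulate_behavior, simulate_erp_epochs, simulate_gait,
)

CONDITIONS = ("S-NF-T", "W-NF-T", "W-F-T", "W-NF-NT", "W-F-NT")
TASK_CONDITIONS = ("S-NF-T", "W-NF-T", "W-F-T")
WALK_CONDITIONS = ("W-NF-T", "W-F-T", "W-NF-NT", "W-F-NT")


def is_task(condition: str) -> bool:
    return condition.endswith("-T") and not condition.endswith("-NT")


def is_walking(condition: str) -> bool:
    return condition.startswith("W")


def has_flow(condition: str) -> bool:
    return "-F-" in condition


@dataclass
class RunConfig:
    """All tunable pipeline parameters, serialized with every output."""

    response_window_ms: tuple[float, float] = (100.0, 1000.0)
    filter_band_hz: tuple[float, float] = (0.25, 40.0)
    filter_transition_hz: float = 0.25
    epoch_window_ms: tuple[float, float] = (-100.0, 800.0)
    baseline_ms: tuple[float, float] | None = (-100.0, 0.0)
    alpha: float = 0.05
    min_run: int = 10
    expected_stride_time_s: float = 1.3
    peak_windows_ms: dict = field(default_factory=lambda: {
        "P2": (200.0, 280.0), "N2": (280.0, 380.0), "P3": (350.0, 500.0)})
    group_peak_windows_ms: dict = field(default_factory=dict)  # group -> name -> window
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(asdict(self)), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("response_window_ms", "filter_band_hz", "epoch_window_ms",
                    "baseline_ms"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        raw["peak_windows_ms"] = {
            k: tuple(v) for k, v in raw.get("peak_windows_ms", {}).items()}
        raw["group_peak_windows_ms"] = {
            g: {k: tuple(v) for k, v in d.items()}
            for g, d in raw.get("group_peak_windows_ms", {}).items()}
        return cls(**raw)

    def hash(self) -> str:
        blob = yaml.safe_dump(_plain(asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


@dataclass
class BlockEntry:
    condition: str
    events: str | None = None
    motion: str | None = None
    eeg: str | None = None
    locations: str | None = None

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition {self.condition!r} not in {CONDITIONS}")


@dataclass
class ParticipantEntry:
    id: str
    group: str
    blocks: list[BlockEntry]


@dataclass
class SessionManifest:
    participants: list[ParticipantEntry]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(asdict(self)), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SessionManifest":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        parts = [
            ParticipantEntry(
                id=p["id"], group=p["group"],
                blocks=[BlockEntry(**b) for b in p["blocks"]],
            )
            for p in raw["participants"]
        ]
        return cls(parts)


# ---------------------------------------------------------------------------
# synthetic session writer


def make_synthetic_session(
    outdir,
    groups: dict[str, int] = None,
    conditions: tuple = TASK_CONDITIONS,
    n_trials: int = 40,
    n_strides: int = 40,
    eeg_channels: list[str] | None = None,
    group_gait: dict[str, GaitSimConfig] | None = None,
    seed: int = 0,
) -> SessionManifest:
    """Write a complete synthetic session to disk and return its manifest.

    EEG for each task block is generated as a continuous recording
    whose stimulus-locked responses match the behavioral event stream:
    each classified trial contributes P2/N2/P3 deflections (Correct
    Rejections with an enhanced P3), so the file-based pipeline has
    coherent events, motion, and EEG.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    groups = groups or {"TD": 2, "ASD": 2}
    channels = eeg_channels or ["Fz", "FCz", "Cz", "CPz", "Pz", "C3", "C4", "Oz"]
    montage = make_montage(channels)
    loc_path = outdir / "electrodes.tsv"
    write_locations(montage, loc_path)

    ss = np.random.SeedSequence(seed)
    participants = []
    pid_n = 0
    for group, n_part in groups.items():
        for _ in range(n_part):
            pid_n += 1
            pid = f"p{pid_n:02d}"
            blocks = []
            for ci, cond in enumerate(conditions):
                child = ss.spawn(1)[0]
                s1, s2, s3 = (int(x % (2**31 - 1))
                              for x in child.generate_state(3))
                paths = {}
                if is_task(cond):
                    ev = simulate_behavior(BehaviorSimConfig(
                        n_trials=n_trials, seed=s1))
                    ev_path = outdir / f"{pid}_{cond}_events.tsv"
                    mio.write_events(ev, ev_path)
                    paths["events"] = str(ev_path)
                    eeg = _synth_continuous_eeg(ev, channels, montage, seed=s2,
                                                cr_p3_boost=1.6)
                    eeg_path = outdir / f"{pid}_{cond}_eeg.tsv"
                    mio.write_eeg_text(eeg, eeg_path)
                    paths["eeg"] = str(eeg_path)
                    paths["locations"] = str(loc_path)
                if is_walking(cond):
                    gcfg = (group_gait or {}).get(group) or GaitSimConfig(
                        n_strides=n_strides, seed=s3)
                    gcfg = GaitSimConfig(**{**asdict(gcfg),
                                            "n_strides": n_strides, "seed": s3})
                    sim = simulate_gait(gcfg)
                    mo_path = outdir / f"{pid}_{cond}_motion.tsv"
                    mio.write_motion([sim.left, sim.right], mo_path)
                    paths["motion"] = str(mo_path)
                blocks.append(BlockEntry(condition=cond, **paths))
            participants.append(ParticipantEntry(pid, group, blocks))
    manifest = SessionManifest(participants)
    manifest.to_yaml(outdir / "manifest.yaml")
    return manifest


def _synth_continuous_eeg(events, channels, montage, seed, cr_p3_boost=1.6,
                          sample_rate=512.0, noise_sd=6.0):
    """Continuous EEG whose stimulus responses follow the event stream."""
    from .montage import angular_distance
    from .synth import _ar1_noise

    rng = np.random.default_rng(seed)
    duration = events.stim_onsets[-1] + 1.5
    n = int(round(duration * sample_rate))
    data = _ar1_noise(rng, (len(channels), n), noise_sd, 0.95)
    t = np.arange(n) / sample_rate
    w_fcz = np.exp(-(angular_distance(montage, "FCz").to_numpy() / 0.9) ** 2)
    w_cpz = np.exp(-(angular_distance(montage, "CPz").to_numpy() / 0.9) ** 2)
    comps = [  # (weights, latency ms, sd ms, amplitude)
        (w_fcz, 240.0, 30.0, 4.0), (w_fcz, 330.0, 30.0, -3.0),
        (w_cpz, 420.0, 45.0, 6.0),
    ]
    for onset, ty in zip(events.stim_onsets, events.stim_types):
        boost = cr_p3_boost if ty == "nogo" else 1.0
        for k, (w, lat, sd, amp) in enumerate(comps):
            a = amp * (boost if k == 2 else 1.0)
            tt = (t - onset) * 1000.0 - lat
            course = a * np.exp(-(tt**2) / (2 * sd**2))
            sel = np.abs(tt) < 4 * sd
            data[:, sel] += w[:, None] * course[sel][None, :]
    from .erp import ContinuousEEG
    return ContinuousEEG(data, sample_rate, list(channels), montage=montage)


# ---------------------------------------------------------------------------
# orchestration


def run_pipeline(manifest: SessionManifest, config: RunConfig, outdir) -> dict:
    """Execute every stage over a session and write the report bundle.

    Returns the bundle as a dict of DataFrames / cluster lists; writes
    behavior_summary.csv, gait_metrics.csv, erp_peaks.csv, ANOVA
    tables, clusters.json and run_log.json under ``outdir``. A failing
    block is logged and skipped; remaining blocks continue.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    failures: list[dict] = []

    behavior_rows = []
    gait_rows = []
    part_avgs: dict[tuple, erpmod.ERPAverage] = {}
    group_of: dict[str, str] = {}

    for part in manifest.participants:
        group_of[part.id] = part.group
        for bi, block in enumerate(part.blocks):
            ctx = {"participant": part.id, "condition": block.condition,
                   "block": bi}
            try:
                if is_task(block.condition) and block.events:
                    events = mio.read_events(block.events)
                    summary = bhv.score_block(events, config.response_window_ms)
                    behavior_rows.append({**ctx, **summary})
                if is_walking(block.condition) and block.motion:
                    markers = mio.read_motion(block.motion)
                    left = next(m for m in markers.values() if m.side == "left")
                    right = next(m for m in markers.values() if m.side == "right")
                    metrics, _ = gaitmod.analyze_block(
                        left, right, config.expected_stride_time_s)
                    gait_rows.append({**ctx, **metrics.as_dict()})
                if is_task(block.condition) and block.eeg:
                    _erp_block(part, block, config, part_avgs)
            except Exception as exc:  # keep going; provenance in the log
                failures.append({**ctx, "error": f"{type(exc).__name__}: {exc}"})

    bundle: dict = {"config_hash": cfg_hash, "failures": failures}

    behavior_df = pd.DataFrame(behavior_rows)
    if not behavior_df.empty:
        behavior_df.insert(0, "group",
                           behavior_df["participant"].map(group_of))
        agg = (behavior_df
               .groupby(["participant", "group", "condition"], sort=True)
               [["d_prime", "mean_rt_ms"]].mean().reset_index())
        mio.write_table(_with_hash(behavior_df, cfg_hash),
                        outdir / "behavior_blocks.csv")
        mio.write_table(_with_hash(agg, cfg_hash),
                        outdir / "behavior_summary.csv")
        bundle["behavior"] = agg
        for dv in ("d_prime", "mean_rt_ms"):
            res = _try_anova(agg, dv, within="condition",
                             subject="participant", between="group")
            if res is not None:
                mio.write_table(_with_hash(res, cfg_hash),
                                outdir / f"anova_{dv}.csv")
                bundle[f"anova_{dv}"] = res

    gait_df = pd.DataFrame(gait_rows)
    if not gait_df.empty:
        gait_df.insert(0, "group", gait_df["participant"].map(group_of))
        gait_df["flow"] = np.where(
            [has_flow(c) for c in gait_df["condition"]], "F", "NF")
        gait_df["task"] = np.where(
            [is_task(c) for c in gait_df["condition"]], "T", "NT")
        mio.write_table(_with_hash(gait_df, cfg_hash),
                        outdir / "gait_metrics.csv")
        bundle["gait"] = gait_df
        if gait_df["flow"].nunique() == 2 and gait_df["task"].nunique() == 2:
            for dv in ("mean_stride_time_ms", "mean_stride_length_mm",
                       "mean_step_width_mm", "cv_stride_time_pct",
                       "cv_stride_length_pct", "cv_step_width_pct"):
                res = _try_anova(gait_df, dv, within=["flow", "task"],
                                 subject="participant", between="group")
                if res is not None:
                    mio.write_table(_with_hash(res, cfg_hash),
                                    outdir / f"anova_{dv}.csv")
                    bundle[f"anova_{dv}"] = res

    if part_avgs:
        bundle.update(_erp_reports(part_avgs, group_of, config, outdir, cfg_hash))

    log = {
        "config_hash": cfg_hash,
        "config": _plain(asdict(config)),
        "n_participants": len(manifest.participants),
        "n_behavior_blocks": len(behavior_rows),
        "n_gait_blocks": len(gait_rows),
        "n_failures": len(failures),
        "failures": failures,
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return bundle


def _with_hash(df: pd.DataFrame, cfg_hash: str) -> pd.DataFrame:
    out = df.copy()
    out["config_hash"] = cfg_hash
    return out


def _try_anova(df, dv, within, subject, between):
    try:
        return mst.rm_anova(df, dv=dv, within=within, subject=subject,
                            between=between)
    except ValueError as exc:
        warnings.warn(f"ANOVA on {dv} skipped: {exc}", stacklevel=2)
        return None


def _erp_block(part, block, config, part_avgs):
    """Preprocess one task block's EEG and accumulate participant averages."""
    eeg = mio.read_eeg(block.eeg, block.locations)
    eeg = erpmod.bandpass_filter(
        eeg, config.filter_band_hz[0], config.filter_band_hz[1],
        transition_low=config.filter_transition_hz)
    eeg = erpmod.average_reference(eeg)
    events = mio.read_events(block.events)
    trials = bhv.classify_trials(events, config.response_window_ms)
    keep = trials["outcome"].isin([bhv.HIT, bhv.CORRECT_REJECTION])
    info = pd.DataFrame({
        "condition": block.condition,
        "response_type": trials.loc[keep, "outcome"],
        "group": part.group,
        "participant": part.id,
    })
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ep = erpmod.epoch(eeg, events.stim_onsets[keep.to_numpy()], info,
                          config.epoch_window_ms, config.baseline_ms)
    for key, avg in erpmod.participant_average(
            ep, ["condition", "response_type"]).items():
        if key in part_avgs:  # several blocks of one condition: average in
            prev = part_avgs[key]
            w1, w2 = prev.n_trials, avg.n_trials
            merged = (prev.data * w1 + avg.data * w2) / (w1 + w2)
            part_avgs[key] = erpmod.ERPAverage(
                merged, avg.times, avg.sample_rate, avg.labels,
                n_trials=w1 + w2, meta=avg.meta)
        else:
            part_avgs[key] = avg


def _erp_reports(part_avgs, group_of, config, outdir, cfg_hash):
    """Peak tables, component ANOVAs, and cluster analyses."""
    bundle = {}
    specs = [erpmod.ComponentSpec(s.name, s.electrode,
                                  config.peak_windows_ms.get(s.name, s.window_ms),
                                  s.polarity, s.topo_halfwidth_ms)
             for s in erpmod.DEFAULT_COMPONENTS]

    peak_rows = []
    for (pid, cond, resp), avg in sorted(part_avgs.items()):
        group = group_of[pid]
        for spec in specs:
            win = config.group_peak_windows_ms.get(group, {}).get(spec.name)
            pk = erpmod.extract_peak(avg, spec, window_ms=win)
            peak_rows.append({
                "participant": pid, "group": group, "condition": cond,
                "response_type": resp, "component": spec.name,
                "electrode": spec.electrode,
                "amplitude_uv": pk.amplitude_uv, "latency_ms": pk.latency_ms,
                "boundary": pk.boundary,
            })
    peaks = pd.DataFrame(peak_rows)
    mio.write_table(_with_hash(peaks, cfg_hash), outdir / "erp_peaks.csv")
    bundle["erp_peaks"] = peaks
    for comp in peaks["component"].unique():
        for dv in ("amplitude_uv", "latency_ms"):
            res = _try_anova(peaks[peaks["component"] == comp], dv,
                             within=["condition", "response_type"],
                             subject="participant", between="group")
            if res is not None:
                bundle[f"anova_{comp}_{dv}"] = res
                mio.write_table(_with_hash(res, cfg_hash),
                                outdir / f"anova_{comp}_{dv}.csv")

    # cluster analyses: Hit vs CR within group x condition; CR-Hit
    # group difference within condition
    clusters = []
    conditions = sorted({k[1] for k in part_avgs})
    groups = sorted(set(group_of.values()))
    diffs: dict[str, dict[str, list]] = {g: {c: [] for c in conditions}
                                         for g in groups}
    for g in groups:
        for cond in conditions:
            pids = sorted({pid for (pid, c, r) in part_avgs
                           if c == cond and group_of[pid] == g})
            pairs = [(part_avgs.get((pid, cond, bhv.HIT)),
                      part_avgs.get((pid, cond, bhv.CORRECT_REJECTION)))
                     for pid in pids]
            pairs = [(h, c) for h, c in pairs if h is not None and c is not None]
            if len(pairs) >= 3:
                crs = [c for _, c in pairs]
                hits = [h for h, _ in pairs]
                tmap = cst.pointwise_paired_t(crs, hits)
                for cl in cst.find_clusters(tmap, config.alpha, config.min_run):
                    clusters.append({"analysis": f"{g}:{cond}:CRvsHit",
                                     **cl.as_dict()})
            diffs[g][cond] = [erpmod.difference_wave(c, h) for h, c in pairs]
    for cond in conditions:
        if len(groups) == 2:
            a, b = (diffs[groups[0]][cond], diffs[groups[1]][cond])
            if len(a) >= 2 and len(b) >= 2:
                tmap = cst.pointwise_independent_t(a, b)
                for cl in cst.find_clusters(tmap, config.alpha, config.min_run):
                    clusters.append({
                        "analysis": f"{groups[0]}-{groups[1]}:{cond}:diff",
                        **cl.as_dict()})
    with open(outdir / "clusters.json", "w") as fh:
        json.dump({"config_hash": cfg_hash, "clusters": clusters}, fh,
                  indent=1, sort_keys=True)
        fh.write("\n")
    bundle["clusters"] = clusters
    return bundle
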