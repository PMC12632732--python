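"""Plain-text file I/O for the three data streams.

Formats (all delimited text):
  * motion TSV, long format: time_s, marker_id, x_mm, y_mm, z_mm
  * events TSV: onset_s, event_type ('stimulus' | 'response'), code
    ('go' | 'nogo' | 'press')
  * EEG: tab-separated channels x samples matrix, first column the
    channel label, with a '# sample_rate_hz: <fs>' comment header;
    electrode locations in a separate label/x/y/z table. EDF files are
    read through mne when that package is available.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import EventStream
from .clusterstats import ClusterResult
from .erp import ContinuousEEG
from .gait import MarkerTrajectory
from .montage import read_locations

MAX_GAP_SAMPLES = 5


# ---------------------------------------------------------------------------
# motion


def write_motion(trajs: list[MarkerTrajectory], path) -> None:
    frames = []
    for tr in trajs:
        t = np.arange(tr.n_samples) / tr.sample_rate
        frames.append(pd.DataFrame({
            "time_s": t,
            "marker_id": tr.marker_id,
            "x_mm": tr.positions[:, 0],
            "y_mm": tr.positions[:, 1],
            "z_mm": tr.positions[:, 2],
        }))
    pd.concat(frames).to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_motion(path) -> dict[str, MarkerTrajectory]:
    """Per-marker trajectories from a long-format motion TSV.

    Gaps of up to 5 samples are linearly interpolated; a longer gap
    truncates the trajectory to its longest contiguous segment with a
    warning. Duplicated or non-monotone timestamps are errors.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"time_s", "marker_id", "x_mm", "y_mm", "z_mm"}
    if not required.issubset(df.columns):
        raise ValueError(f"motion file must have columns {sorted(required)}")
    out = {}
    for marker, sub in df.groupby("marker_id", sort=True):
        t = sub["time_s"].to_numpy()
        if np.any(np.diff(t) == 0):
            raise ValueError(f"duplicated timestamp for marker {marker!r}")
        if np.any(np.diff(t) < 0):
            raise ValueError(f"non-monotone time for marker {marker!r}")
        dt = np.median(np.diff(t))
        fs = 1.0 / dt
        idx = np.round((t - t[0]) / dt).astype(int)
        gaps = np.diff(idx) - 1
        if np.any(gaps > MAX_GAP_SAMPLES):
            bounds = np.flatnonzero(gaps > MAX_GAP_SAMPLES) + 1
            segments = np.split(np.arange(len(idx)), bounds)
            seg = max(segments, key=len)
            warnings.warn(
                f"marker {marker!r}: gap of {int(gaps.max())} samples splits "
                "the block; keeping the longest contiguous segment",
                stacklevel=2)
            sub = sub.iloc[seg]
            idx = idx[seg] - idx[seg[0]]
        full = np.arange(idx[-1] + 1)
        pos = np.full((len(full), 3), np.nan)
        pos[idx] = sub[["x_mm", "y_mm", "z_mm"]].to_numpy()
        if np.isnan(pos).any():
            filled = pd.DataFrame(pos).interpolate(limit_area="inside").to_numpy()
            n_filled = int(np.isnan(pos[:, 0]).sum())
            warnings.warn(f"marker {marker!r}: {n_filled} gap sample(s) "
                          "linearly interpolated", stacklevel=2)
            pos = filled
        side = {"L": "left", "R": "right"}.get(str(marker)[:1].upper(), "")
        out[marker] = MarkerTrajectory(fs, pos, marker_id=str(marker), side=side)
    return out


# ---------------------------------------------------------------------------
# events


def write_events(events: EventStream, path) -> None:
    rows = [
        {"onset_s": o, "event_type": "stimulus", "code": ty}
        for o, ty in zip(events.stim_onsets, events.stim_types)
    ] + [
        {"onset_s": r, "event_type": "response", "code": "press"}
        for r in events.response_times
    ]
    df = pd.DataFrame(rows).sort_values("onset_s", kind="stable")
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_events(path) -> EventStream:
    df = pd.read_csv(path, sep="\t")
    stim = df[df["event_type"] == "stimulus"]
    resp = df[df["event_type"] == "response"]
    return EventStream(
        stim["onset_s"].to_numpy(),
        stim["code"].to_numpy(),
        resp["onset_s"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# EEG


def write_eeg_text(eeg: ContinuousEEG, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# sample_rate_hz: {eeg.sample_rate:g}\n")
        for lab, row in zip(eeg.labels, eeg.data):
            fh.write(lab + "\t" + "\t".join(f"{v:.4f}" for v in row) + "\n")


def _read_eeg_text(path) -> tuple[np.ndarray, list[str], float]:
    labels, rows, fs = [], [], None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                if key.strip() == "sample_rate_hz":
                    fs = float(val)
                continue
            parts = line.split("\t")
            labels.append(parts[0])
            rows.append(np.array(parts[1:], dtype=float))
    if fs is None:
        raise ValueError(f"{path}: missing '# sample_rate_hz:' header")
    return np.vstack(rows), labels, fs


def read_eeg(path, locations_path) -> ContinuousEEG:
    """Continuous EEG from an EDF file or a delimited text matrix.

    Channels are reordered to follow the locations file; a label
    present in the data but absent from the locations file (or vice
    versa) is an error naming the label.
    """
    path = Path(path)
    montage = read_locations(locations_path)
    if path.suffix.lower() == ".edf":
        import mne  # optional dependency, only for EDF input

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # volts -> microvolts
        labels = list(raw.ch_names)
        fs = float(raw.info["sfreq"])
    else:
        data, labels, fs = _read_eeg_text(path)

    missing = [lab for lab in labels if lab not in montage.index]
    if missing:
        raise ValueError(f"no electrode location for channel(s): {missing}")
    wanted = [lab for lab in montage.index if lab in labels]
    order = [labels.index(lab) for lab in wanted]
    return ContinuousEEG(data[order], fs, wanted, montage=montage.loc[wanted])


# ---------------------------------------------------------------------------
# results


def write_cluster_report(clusters: list[ClusterResult], path, meta: dict | None = None) -> None:
    payload = {"meta": meta or {}, "clusters": [c.as_dict() for c in clusters]}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_table(df: pd.DataFrame, path) -> None:
    """Deterministically formatted CSV output."""
    df.to_csv(path, index=False, float_format="%.6g")
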