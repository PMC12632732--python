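"""Idealized spherical-head electrode geometry for the 10-20 / 10-10 system.

Electrodes are placed on a unit sphere in head coordinates (x: right,
y: anterior, z: up). Midline electrodes sit on the sagittal meridian at
10%-of-arc steps from the vertex; the outermost electrode of each coronal
row sits on the "rim" circle 72 degrees from the vertex (the circle that
carries Fpz, F7/8, T7/8, P7/8 and Oz in the classic layout); intermediate
electrodes are spherically interpolated along the arc between the two.
This is an idealization — no individual head digitization is modelled —
but it preserves the neighbourhood structure that spherical-spline
interpolation and the ERP simulator's spatial spread rely on.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

# polar angle (deg) of each row's midline electrode, positive toward nasion
_ROW_MIDLINE_DEG = {
    "Fp": 72.0, "AF": 54.0, "F": 36.0, "FC": 18.0, "C": 0.0,
    "CP": -18.0, "P": -36.0, "PO": -54.0, "O": -72.0,
}
# azimuth (deg from anterior, toward the left ear) of each row's rim electrode
_ROW_RIM_AZ_DEG = {
    "Fp": 18.0, "AF": 36.0, "F": 54.0, "FC": 72.0, "C": 90.0,
    "CP": 108.0, "P": 126.0, "PO": 144.0, "O": 162.0,
}
_RIM_POLAR_DEG = 72.0
# lateral rank of the rim electrode within each row (rank = (index+1)//2)
_ROW_RIM_RANK = {
    "Fp": 1, "AF": 4, "F": 4, "FC": 4, "C": 4,
    "CP": 4, "P": 4, "PO": 4, "O": 1,
}

#: the 64-channel 10-10 subset used by common active-electrode caps
BIOSEMI64_LABELS = [
    "Fp1", "AF7", "AF3", "F1", "F3", "F5", "F7", "FT7", "FC5", "FC3", "FC1",
    "C1", "C3", "C5", "T7", "TP7", "CP5", "CP3", "CP1", "P1", "P3", "P5",
    "P7", "P9", "PO7", "PO3", "O1", "Iz", "Oz", "POz", "Pz", "CPz",
    "Fpz", "Fp2", "AF8", "AF4", "AFz", "Fz", "F2", "F4", "F6", "F8", "FT8",
    "FC6", "FC4", "FC2", "FCz", "Cz", "C2", "C4", "C6", "T8", "TP8", "CP6",
    "CP4", "CP2", "P2", "P4", "P6", "P8", "P10", "PO8", "PO4", "O2",
]

_LABEL_RE = re.compile(r"^(Fp|AF|FT|FC|TP|CP|PO|F|C|T|P|O|I)(z|\d+)$")


def _parse_label(label: str) -> tuple[str, int | None]:
    """Return (row, index); index None for midline 'z' electrodes."""
    m = _LABEL_RE.match(label)
    if m is None:
        raise ValueError(f"unrecognized 10-10 electrode label: {label!r}")
    row, idx = m.group(1), m.group(2)
    # temporal aliases collapse onto their coronal rows
    row = {"T": "C", "FT": "FC", "TP": "CP"}.get(row, row)
    if idx == "z":
        return row, None
    return row, int(idx)


def _slerp(a: np.ndarray, b: np.ndarray, u: float) -> np.ndarray:
    dot = float(np.clip(a @ b, -1.0, 1.0))
    omega = np.arccos(dot)
    if omega < 1e-12:
        return a
    return (np.sin((1 - u) * omega) * a + np.sin(u * omega) * b) / np.sin(omega)


def _rim_point(az_deg: float, side: str, polar_deg: float = _RIM_POLAR_DEG) -> np.ndarray:
    th = np.deg2rad(polar_deg)
    az = np.deg2rad(az_deg)
    sx = -1.0 if side == "left" else 1.0
    return np.array([sx * np.sin(th) * np.sin(az), np.sin(th) * np.cos(az), np.cos(th)])


def electrode_position(label: str) -> np.ndarray:
    """Unit-sphere (x, y, z) of a 10-10 electrode on the idealized head."""
    if label == "Iz":
        return np.array([0.0, -1.0, 0.0])
    row, idx = _parse_label(label)
    m = np.deg2rad(_ROW_MIDLINE_DEG[row])
    mid = np.array([0.0, np.sin(m), np.cos(m)])
    if idx is None:
        return mid
    side = "left" if idx % 2 == 1 else "right"
    rank = (idx + 1) // 2
    rim_rank = _ROW_RIM_RANK[row]
    if rank > rim_rank:  # below-rim electrodes (P9/P10): equator, rim azimuth
        return _rim_point(_ROW_RIM_AZ_DEG[row], side, polar_deg=90.0)
    rim = _rim_point(_ROW_RIM_AZ_DEG[row], side)
    return _slerp(mid, rim, rank / rim_rank)


def make_montage(labels: list[str] | None = None) -> pd.DataFrame:
    """Coordinate table (index: label; columns x, y, z on the unit sphere)."""
    if labels is None:
        labels = list(BIOSEMI64_LABELS)
    pos = np.array([electrode_position(lab) for lab in labels])
    return pd.DataFrame(pos, index=pd.Index(labels, name="label"),
                        columns=["x", "y", "z"])


def angular_distance(montage: pd.DataFrame, center: str) -> pd.Series:
    """Great-circle distance (radians) from ``center`` to every electrode."""
    if center not in montage.index:
        raise KeyError(f"electrode {center!r} not in montage")
    p = montage.loc[center].to_numpy()
    dots = np.clip(montage.to_numpy() @ p, -1.0, 1.0)
    return pd.Series(np.arccos(dots), index=montage.index, name="angle_rad")


def write_locations(montage: pd.DataFrame, path) -> None:
    """Write a plain-text electrode location file (label x y z, tab-separated)."""
    montage.to_csv(path, sep="\t", float_format="%.6f")


def read_locations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="label")
    missing = {"x", "y", "z"} - set(df.columns)
    if missing:
        raise ValueError(f"locations file {path} lacks columns: {sorted(missing)}")
    return df[["x", "y", "z"]]
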