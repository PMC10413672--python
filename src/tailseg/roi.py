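"""Left/right presomitic-mesoderm region-of-interest statistics.

An ROI is an axis-aligned box in embryo coordinates (conventionally the
anterior 125 um of the left or right PSM). Windows belong to an ROI if and
only if their *start* position lies inside the (closed) box; the rest of
the window may leave. Two series are computed per ROI over time: the
fraction of PZ-type windows, and the mean and SD of the signed
medial-lateral displacement, where motion toward the midline is positive on
both sides (computed as the decrease in distance to the midline from window
start to window end). Frames with no member windows are reported as missing,
not as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pipeline import StateTable

#: Default anterior-posterior extent of a PSM ROI (um).
DEFAULT_AP_EXTENT = 125.0


@dataclass(frozen=True)
class ROI:
    """A closed axis-aligned box on one side of the midline.

    ``box`` maps coordinate columns (default ``x``/``y``/``z``) to
    ``(lo, hi)`` bounds; axes absent from the box are unconstrained.
    ``midline`` is the medial-lateral coordinate of the embryo midline and
    ``ml_axis`` the column holding the medial-lateral coordinate.
    """

    side: str  # "left" | "right"
    box: dict
    midline: float
    ml_axis: str = "x"

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        for axis, (lo, hi) in self.box.items():
            if not lo < hi:
                raise ValueError(f"degenerate box on axis {axis!r}: [{lo}, {hi}]")


def assign_to_roi(states: StateTable, roi: ROI) -> pd.DataFrame:
    """Windows whose start position lies in the ROI box (closed boundaries)."""
    t = states.table
    mask = np.ones(len(t), dtype=bool)
    for axis, (lo, hi) in roi.box.items():
        vals = t[axis].to_numpy(dtype=float)
        mask &= (vals >= lo) & (vals <= hi)
    return t[mask].copy()


def signed_ml_displacement(members: pd.DataFrame, roi: ROI) -> np.ndarray:
    """Per-window medial-lateral displacement, positive toward the midline.

    Defined as |start - midline| - |end - midline| on the ML axis, which is
    side-agnostic: a left cell moving right and a right cell moving left
    both score positive.
    """
    start = members[roi.ml_axis].to_numpy(dtype=float)
    end = members[f"end_{roi.ml_axis}"].to_numpy(dtype=float)
    return np.abs(start - roi.midline) - np.abs(end - roi.midline)


def ml_displacement_series(members: pd.DataFrame, roi: ROI) -> pd.DataFrame:
    """Per-frame mean and SD of signed ML displacement over member windows.

    Returns columns ``frame, side, ml_mean, ml_sd, n``; only frames with at
    least one member appear (absent frames mean no data, not zero motion).
    """
    members = members.copy()
    members["_ml"] = signed_ml_displacement(members, roi)
    rows = []
    for frame, group in members.groupby("start_frame"):
        v = group["_ml"].to_numpy()
        rows.append((int(frame), roi.side, float(v.mean()), float(v.std()), len(v)))
    return pd.DataFrame(rows, columns=["frame", "side", "ml_mean", "ml_sd", "n"])


def pz_abundance_series(
    members: pd.DataFrame, pz_state_label: int, side: str = ""
) -> pd.DataFrame:
    """Per-frame fraction of member windows carrying the PZ-type label."""
    if "state" not in members.columns:
        raise ValueError("members table lacks state labels")
    rows = []
    for frame, group in members.groupby("start_frame"):
        frac = float((group["state"] == pz_state_label).mean())
        rows.append((int(frame), side, frac, len(group)))
    return pd.DataFrame(rows, columns=["frame", "side", "pz_fraction", "n"])


def roi_series(states: StateTable, roi: ROI, pz_state_label: int) -> pd.DataFrame:
    """Combined export: ``frame, side, pz_fraction, ml_mean, ml_sd, n``."""
    members = assign_to_roi(states, roi)
    ml = ml_displacement_series(members, roi)
    pz = pz_abundance_series(members, pz_state_label, side=roi.side)
    merged = pd.merge(pz, ml.drop(columns="side"), on="frame", how="outer")
    return merged[["frame", "side", "pz_fraction", "ml_mean", "ml_sd", "n_x"]].rename(
        columns={"n_x": "n"}
    )


def default_psm_rois(
    states: StateTable,
    psm_state_label: int,
    midline: float,
    ml_axis: str = "x",
    ap_axis: str = "y",
    ap_extent: float = DEFAULT_AP_EXTENT,
    posterior_sign: int = 1,
) -> tuple[ROI, ROI]:
    """Derive left/right anterior-PSM ROI boxes from labeled windows.

    For each side of the midline, takes the PSM-labeled windows and keeps
    the anterior-most ``ap_extent`` um (anterior = decreasing AP coordinate
    when ``posterior_sign`` is +1). Intended as a starting point; the boxes
    the analysis uses can always be supplied explicitly.
    """
    t = states.table
    psm = t[t["state"] == psm_state_label]
    if psm.empty:
        raise ValueError("no windows carry the PSM state label")
    rois = []
    for side, mask in (
        ("left", psm[ml_axis] < midline),
        ("right", psm[ml_axis] >= midline),
    ):
        sub = psm[mask]
        if sub.empty:
            raise ValueError(f"no PSM windows on the {side} side of the midline")
        ap = sub[ap_axis].to_numpy(dtype=float)
        anterior = ap.min() if posterior_sign > 0 else ap.max()
        ap_box = (
            (anterior, anterior + ap_extent)
            if posterior_sign > 0
            else (anterior - ap_extent, anterior)
        )
        ml_vals = sub[ml_axis].to_numpy(dtype=float)
        rois.append(
            ROI(
                side=side,
                box={ml_axis: (ml_vals.min(), ml_vals.max()), ap_axis: ap_box},
                midline=midline,
                ml_axis=ml_axis,
            )
        )
    return rois[0], rois[1]
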