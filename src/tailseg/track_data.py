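"""Cell track tables, sliding windows, distance matrices and motion statistics.

A *track* is one cell's time-ordered 3D trajectory (positions in micrometres)
from time-lapse confocal imaging. The base unit of all downstream analysis is
a sliding window of ``L`` consecutive time points (default 8, spanning 21 min
at a 3-min frame interval). Each window is summarised two ways:

* a symmetric ``L x L`` distance matrix whose ``(i, j)`` entry is the cell's
  displacement between the window's i-th and j-th time points — the input to
  the variational-autoencoder pseudotime embedding;
* scalar motion statistics (net displacement, path length, speed,
  straightness) — the features that are segmented into motion states.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default column mapping for track tables (TrackMate/Imaris exports can be
#: remapped onto these via the ``axis_config`` argument of :func:`read_tracks`).
DEFAULT_COLUMNS = {
    "embryo": "embryo",
    "track": "track",
    "frame": "frame",
    "x": "x",
    "y": "y",
    "z": "z",
}

#: Anatomical axis convention: which coordinate column is medial-lateral,
#: anterior-posterior and dorsal-ventral.
DEFAULT_AXES = {"ml": "x", "ap": "y", "dv": "z"}

#: Default acquisition interval in minutes (8 points span 21 min -> 7
#: intervals of 3 min).
DEFAULT_FRAME_INTERVAL = 3.0


class TrackFormatError(ValueError):
    """Raised when a track table is malformed (missing columns, duplicates)."""


@dataclass(frozen=True)
class Track:
    """One cell's time-ordered 3D positions within one embryo.

    Frames must be strictly increasing; positions are in micrometres.
    """

    embryo_id: str
    track_id: str
    frames: np.ndarray  # (n,) int
    positions: np.ndarray  # (n, 3) float, micrometres

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=int)
        positions = np.asarray(self.positions, dtype=float)
        if frames.ndim != 1 or len(frames) < 1:
            raise ValueError("track must contain at least one frame")
        if positions.shape != (len(frames), 3):
            raise ValueError("positions must be (n_frames, 3)")
        if len(frames) > 1 and not np.all(np.diff(frames) > 0):
            raise ValueError("frames must be strictly increasing")
        if not np.all(np.isfinite(positions)):
            raise ValueError("positions must be finite")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "positions", positions)

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class TrackWindow:
    """``L`` gap-free consecutive time points cut from a parent track."""

    embryo_id: str
    track_id: str
    start_frame: int
    positions: np.ndarray  # (L, 3)

    def __post_init__(self) -> None:
        positions = np.asarray(self.positions, dtype=float)
        if positions.ndim != 2 or positions.shape[0] < 2 or positions.shape[1] != 3:
            raise ValueError("window needs >= 2 three-dimensional positions")
        if not np.all(np.isfinite(positions)):
            raise ValueError("window positions must be finite")
        object.__setattr__(self, "positions", positions)

    @property
    def length(self) -> int:
        return self.positions.shape[0]

    @property
    def start_position(self) -> np.ndarray:
        return self.positions[0]

    @property
    def end_position(self) -> np.ndarray:
        return self.positions[-1]


@dataclass(frozen=True)
class MotionStats:
    """Scalar motion summary of one window.

    ``straightness`` is net displacement over path length: 1 for ballistic
    motion, near 0 for confined or closed-loop motion, and defined as 0 when
    the cell does not move at all.
    """

    displacement: float
    path_length: float
    speed: float
    straightness: float


def read_tracks(path, axis_config: dict | None = None) -> list[Track]:
    """Read a CSV/TSV track table into one :class:`Track` per (embryo, track).

    Parameters
    ----------
    path:
        CSV (or TSV, sniffed from the extension) with one row per cell per
        time point.
    axis_config:
        Optional overrides for :data:`DEFAULT_COLUMNS`, e.g.
        ``{"track": "TRACK_ID", "frame": "FRAME"}`` for TrackMate exports.

    Raises
    ------
    TrackFormatError
        If a required column is missing, a coordinate fails to parse, or a
        (track, frame) pair is duplicated.
    """
    cols = dict(DEFAULT_COLUMNS)
    if axis_config:
        cols.update({k: v for k, v in axis_config.items() if k in cols})
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    table = pd.read_csv(path, sep=sep)
    missing = [v for v in cols.values() if v not in table.columns]
    if missing:
        raise TrackFormatError(f"missing required column(s): {missing}")

    for axis in ("x", "y", "z"):
        coerced = pd.to_numeric(table[cols[axis]], errors="coerce")
        bad = coerced.isna() & table[cols[axis]].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, counting the header line
            raise TrackFormatError(
                f"non-numeric value in column {cols[axis]!r} at file row {row}"
            )
        table[cols[axis]] = coerced
    if table[[cols["x"], cols["y"], cols["z"], cols["frame"]]].isna().any().any():
        raise TrackFormatError("track table contains missing coordinates or frames")

    dup = table.duplicated(
        subset=[cols["embryo"], cols["track"], cols["frame"]], keep=False
    )
    if dup.any():
        first = table.loc[dup].iloc[0]
        raise TrackFormatError(
            "duplicate (track, frame) row: "
            f"embryo={str(first[cols['embryo']])!r} "
            f"track={str(first[cols['track']])!r} "
            f"frame={int(first[cols['frame']])}"
        )

    tracks = []
    for (embryo, track), group in table.groupby(
        [cols["embryo"], cols["track"]], sort=True
    ):
        group = group.sort_values(cols["frame"])
        tracks.append(
            Track(
                embryo_id=str(embryo),
                track_id=str(track),
                frames=group[cols["frame"]].to_numpy(dtype=int),
                positions=group[[cols["x"], cols["y"], cols["z"]]].to_numpy(float),
            )
        )
    return tracks


def write_tracks(tracks: list[Track], path) -> None:
    """Write tracks back to the default CSV layout (round-trips read_tracks)."""
    rows = []
    for t in tracks:
        for f, p in zip(t.frames, t.positions):
            rows.append((t.embryo_id, t.track_id, int(f), p[0], p[1], p[2]))
    pd.DataFrame(rows, columns=list(DEFAULT_COLUMNS.values())).to_csv(
        path, index=False
    )


def make_windows(track: Track, L: int = 8, step: int = 1) -> list[TrackWindow]:
    """Slide a length-``L`` window along the gap-free runs of a track.

    Tracks shorter than ``L`` yield no windows; a gap in the frame sequence
    breaks the track into runs and windows never span a gap (no
    interpolation).
    """
    if L < 2:
        raise ValueError("window length must be >= 2")
    if step < 1:
        raise ValueError("step must be >= 1")
    windows = []
    breaks = np.flatnonzero(np.diff(track.frames) != 1)
    run_starts = np.concatenate(([0], breaks + 1))
    run_ends = np.concatenate((breaks + 1, [len(track)]))
    for lo, hi in zip(run_starts, run_ends):
        for s in range(lo, hi - L + 1, step):
            windows.append(
                TrackWindow(
                    embryo_id=track.embryo_id,
                    track_id=track.track_id,
                    start_frame=int(track.frames[s]),
                    positions=track.positions[s : s + L],
                )
            )
    return windows


def make_all_windows(
    tracks: list[Track], L: int = 8, step: int = 1
) -> list[TrackWindow]:
    """Windows for every track; logs how many tracks were too short."""
    windows: list[TrackWindow] = []
    skipped = 0
    for t in tracks:
        w = make_windows(t, L=L, step=step)
        if not w:
            skipped += 1
        windows.extend(w)
    if skipped:
        logger.info("%d track(s) shorter than L=%d yielded no windows", skipped, L)
    return windows


def distance_matrix(window: TrackWindow) -> np.ndarray:
    """Pairwise-displacement matrix D of one window.

    ``D[i, j]`` is the Euclidean distance (um) between the cell's positions at
    the window's i-th and j-th time points; symmetric with a zero diagonal.
    """
    p = window.positions
    diff = p[:, None, :] - p[None, :, :]
    return np.linalg.norm(diff, axis=-1)


def motion_stats(
    window: TrackWindow, frame_interval: float = DEFAULT_FRAME_INTERVAL
) -> MotionStats:
    """Displacement, path length, speed (um/min) and straightness of a window."""
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    p = window.positions
    displacement = float(np.linalg.norm(p[-1] - p[0]))
    steps = np.linalg.norm(np.diff(p, axis=0), axis=1)
    path_length = float(steps.sum())
    speed = path_length / ((window.length - 1) * frame_interval)
    straightness = displacement / path_length if path_length > 0 else 0.0
    return MotionStats(
        displacement=displacement,
        path_length=path_length,
        speed=speed,
        straightness=straightness,
    )


def windows_table(
    windows: list[TrackWindow], frame_interval: float = DEFAULT_FRAME_INTERVAL
) -> pd.DataFrame:
    """Per-window motion statistics as a DataFrame (the CSV export layout)."""
    rows = []
    for w in windows:
        s = motion_stats(w, frame_interval)
        rows.append(
            (
                w.embryo_id,
                w.track_id,
                w.start_frame,
                s.displacement,
                s.path_length,
                s.speed,
                s.straightness,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "embryo",
            "track",
            "start_frame",
            "displacement",
            "path_length",
            "speed",
            "straightness",
        ],
    )
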