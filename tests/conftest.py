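import numpy as np
import pandas as pd
import pytest

from tailseg import pipeline, track_data


@pytest.fixture
def straight_track() -> track_data.Track:
    """Constant-velocity track: 1 um/frame along x for 10 frames."""
    n = 10
    pos = np.zeros((n, 3))
    pos[:, 0] = np.arange(n)
    return track_data.Track("e1", "t1", np.arange(n), pos)


@pytest.fixture
def zigzag_window() -> track_data.TrackWindow:
    """Three unit steps: +x, +y, +x. Path 3, net displacement sqrt(5)."""
    pos = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [2, 1, 0]], dtype=float)
    return track_data.TrackWindow("e1", "t1", 0, pos)


def make_state_table(rows) -> pipeline.StateTable:
    """StateTable from (track, frame, x, y, end_x, end_y, state) tuples."""
    df = pd.DataFrame(
        rows, columns=["track", "start_frame", "x", "y", "end_x", "end_y", "state"]
    )
    df.insert(0, "embryo", "e1")
    df["z"] = 0.0
    df["end_z"] = 0.0
    df["displacement"] = np.hypot(df.end_x - df.x, df.end_y - df.y)
    df["rank"] = np.arange(len(df))
    return pipeline.StateTable(
        table=df,
        segmentation=None,
        error_curve=None,
        feature_set=("displacement",),
        zscore_constants={},
    )
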