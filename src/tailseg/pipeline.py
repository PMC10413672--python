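"""End-to-end cell-state calling.

Motion route: tracks -> sliding windows -> distance matrices -> VAE latent
-> pseudotime ranks -> z-scored motion features -> 30-bin change-point
segmentation with elbow K selection -> state labels joined back to the
windows' start positions for spatial mapping. States are relabeled by
descending mean net displacement, so state 0 is always the
highest-displacement (dorsal-medial-like) state; when three states are
found, the middle state is the progenitor-zone (PZ) type.

Expression route: the same binned segmentation applied to per-cell feature
vectors over an externally supplied 1D ordering (e.g. PCA z-scores ordered
by a 1D embedding from an scRNA-seq workflow).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import changepoint as cp
from . import track_data as td
from . import vae as vae_mod


class PipelineError(RuntimeError):
    """A stage of the state-calling pipeline failed; message names the stage."""


@dataclass
class PipelineConfig:
    """Knobs of the motion-state pipeline (units: um, minutes)."""

    window_length: int = 8
    frame_interval: float = td.DEFAULT_FRAME_INTERVAL
    n_bins: int = 30
    k_max: int = 8  # elbow search range for motion states
    feature_set: tuple[str, ...] = ("displacement",)
    zscore_scope: str = "pooled"  # or "per-embryo"
    vae: vae_mod.VAEConfig = field(default_factory=vae_mod.VAEConfig)
    seed: int = 0


@dataclass
class StateTable:
    """Per-window state calls plus the segmentation that produced them.

    ``table`` columns: embryo, track, start_frame, x, y, z (window start
    position), end_x, end_y, end_z, displacement, rank, state. State labels
    are 0..K with 0 the highest-displacement state.
    """

    table: pd.DataFrame
    segmentation: cp.Segmentation
    error_curve: np.ndarray
    feature_set: tuple[str, ...]
    zscore_constants: dict

    @property
    def n_states(self) -> int:
        return self.segmentation.K + 1

    def pz_state_label(self) -> int:
        """The PZ-type state: the middle state when there are three."""
        if self.n_states != 3:
            raise ValueError(
                "PZ-type state is only defined for 3-state segmentations; "
                f"got {self.n_states} states (reference states by index)"
            )
        return 1


def zscore_features(
    stats: pd.DataFrame,
    feature_set: tuple[str, ...] = ("displacement",),
    scope: str = "pooled",
) -> tuple[np.ndarray, dict]:
    """Standardize selected motion features to mean 0, sd 1.

    ``stats`` is a :func:`tailseg.track_data.windows_table` frame. Scope
    "pooled" standardizes over all windows together; "per-embryo" within
    each embryo. Returns the feature matrix (rows aligned with ``stats``)
    and the constants used, keyed by (scope key, feature).
    """
    if len(stats) < 2:
        raise ValueError("need at least two windows to standardize")
    for f in feature_set:
        if f not in stats.columns:
            raise ValueError(f"unknown feature {f!r}")
    out = np.empty((len(stats), len(feature_set)))
    constants: dict = {}
    groups = (
        [("pooled", np.ones(len(stats), dtype=bool))]
        if scope == "pooled"
        else [(e, (stats["embryo"] == e).to_numpy()) for e in stats["embryo"].unique()]
    )
    for key, mask in groups:
        for j, f in enumerate(feature_set):
            vals = stats.loc[mask, f].to_numpy(dtype=float)
            mu, sd = vals.mean(), vals.std()
            if sd == 0:
                raise ValueError(f"feature {f!r} has zero variance in scope {key!r}")
            out[mask, j] = (vals - mu) / sd
            constants[(key, f)] = (float(mu), float(sd))
    return out, constants


def _segment_binned(features, ranks, n_bins, k_max, K=None):
    """bin -> error curve -> (elbow or fixed K) -> optimal segmentation."""
    profile = cp.bin_by_rank(features, ranks, n_bins=n_bins)
    curve = cp.error_curve(profile, k_max)
    if K is None:
        K = cp.select_k_elbow(curve)
    seg = cp.segment_dp(profile, K)
    bin_of_item = cp.bin_of_rank(len(ranks), n_bins)
    labels = seg.segment_of_bin()[bin_of_item[np.asarray(ranks)]]
    return seg, curve, labels


def segment_motion_states(
    tracks: list[td.Track],
    config: PipelineConfig | None = None,
    model: vae_mod.VAEModel | None = None,
    reference: vae_mod.PseudotimeSequence | None = None,
) -> StateTable:
    """Run the full motion-state pipeline on a set of tracks.

    A pre-trained VAE ``model`` skips training; a ``reference`` pseudotime
    instead maps windows onto an existing sequence by nearest-matrix lookup
    (how additional embryos were analyzed without re-embedding).
    """
    config = config or PipelineConfig()

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise PipelineError(f"stage {name!r}: {exc}") from exc

    windows = stage(
        "windows", td.make_all_windows, tracks, L=config.window_length
    )
    if len(windows) < config.n_bins:
        raise PipelineError(
            f"stage 'windows': {len(windows)} windows < n_bins={config.n_bins}"
        )
    matrices = stage(
        "distance_matrices",
        lambda ws: np.stack([td.distance_matrix(w) for w in ws]),
        windows,
    )
    stats = stage("motion_stats", td.windows_table, windows, config.frame_interval)
    ids = list(zip(stats["track"], stats["start_frame"]))
    disp = stats["displacement"].to_numpy()

    if reference is not None:
        z, _ = stage("map_to_reference", vae_mod.map_to_reference, matrices, reference)
        order = sorted(range(len(z)), key=lambda i: (z[i], ids[i]))
        ranks = np.empty(len(z), dtype=int)
        ranks[order] = np.arange(len(z))
    else:
        if model is None:
            vcfg = replace(config.vae, seed=config.seed)
            model = stage("train_vae", vae_mod.train_vae, matrices, vcfg)
        pt = stage(
            "assign_pseudotime",
            vae_mod.assign_pseudotime,
            model,
            matrices,
            ids,
            disp,
        )
        ranks = pt.ranks

    feats, constants = stage(
        "zscore", zscore_features, stats, config.feature_set, config.zscore_scope
    )
    seg, curve, labels = stage(
        "segmentation", _segment_binned, feats, ranks, config.n_bins, config.k_max
    )
    labels = _relabel_by_displacement(labels, disp)

    table = stats[["embryo", "track", "start_frame", "displacement"]].copy()
    starts = np.stack([w.start_position for w in windows])
    ends = np.stack([w.end_position for w in windows])
    table[["x", "y", "z"]] = starts
    table[["end_x", "end_y", "end_z"]] = ends
    table["rank"] = ranks
    table["state"] = labels
    return StateTable(
        table=table,
        segmentation=seg,
        error_curve=curve,
        feature_set=tuple(config.feature_set),
        zscore_constants=constants,
    )


def _relabel_by_displacement(labels: np.ndarray, displacement: np.ndarray):
    """Relabel states so label 0 has the highest mean displacement (idempotent)."""
    present = np.unique(labels)
    means = np.array([displacement[labels == s].mean() for s in present])
    order = present[np.argsort(-means)]
    remap = {int(old): new for new, old in enumerate(order)}
    return np.array([remap[int(s)] for s in labels])


def segment_expression(
    features: np.ndarray,
    ordering: np.ndarray,
    n_bins: int = 30,
    K: int | None = None,
    k_max: int = 10,
) -> tuple[cp.Segmentation, np.ndarray, np.ndarray]:
    """Segment per-cell features over a supplied pseudotime ordering.

    ``K=None`` selects the change-point count by the elbow rule. Returns
    ``(segmentation, per-cell labels, transition ranks)`` where transition
    ranks are the last member rank of each state but the final one — the
    positions of the vertical transition lines on the rank axis.
    """
    features = np.asarray(features, dtype=float)
    ordering = np.asarray(ordering)
    if len(features) != len(ordering):
        raise ValueError("features and ordering differ in length")
    seg, _, labels = _segment_binned(features, ordering, n_bins, k_max, K=K)
    sizes = cp.bin_sizes(len(ordering), n_bins)
    cum = np.cumsum(sizes)
    transitions = np.array([cum[b] - 1 for b in seg.break_points], dtype=int)
    return seg, labels, transitions


def state_abundance(states: StateTable) -> pd.DataFrame:
    """Fraction of each frame's windows in each state (long-format frame)."""
    if len(states.table) == 0:
        raise ValueError("empty state table")
    n_states = (
        states.n_states
        if states.segmentation is not None
        else int(states.table["state"].max()) + 1
    )
    rows = []
    for frame, group in states.table.groupby("start_frame"):
        counts = np.bincount(group["state"], minlength=n_states)
        frac = counts / counts.sum()
        rows.extend((int(frame), s, float(frac[s])) for s in range(n_states))
    return pd.DataFrame(rows, columns=["frame", "state", "fraction"])


def sample_windows_for_display(
    states: StateTable, mode: str = "first-frame", n: int | None = None, seed: int = 0
) -> pd.DataFrame:
    """Subset the state table for plotting.

    ``first-frame`` keeps the windows starting at the earliest frame (like
    showing a single time point); ``random`` samples ``n`` windows uniformly
    without replacement from the whole time lapse (a time average).
    """
    t = states.table
    if mode == "first-frame":
        sub = t[t["start_frame"] == t["start_frame"].min()]
        if n is not None:
            if n > len(sub):
                raise ValueError(f"n={n} exceeds {len(sub)} first-frame windows")
            sub = sub.iloc[:n]
        return sub.copy()
    if mode == "random":
        if n is None or n > len(t):
            raise ValueError(f"n={n} exceeds table size {len(t)}")
        rng = np.random.default_rng(seed)
        return t.iloc[rng.choice(len(t), size=n, replace=False)].copy()
    raise ValueError(f"unknown sampling mode {mode!r}")
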