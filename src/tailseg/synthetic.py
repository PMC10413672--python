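"""Seeded generators of tracks, expression features and intensity profiles
with planted ground truth.

These emulate the three kinds of data the analysis consumes:

* **Tracks** — correlated random walks in three motion regimes patterned on
  the tailbud: a fast, directionally persistent regime (dorsal-medial-like),
  an intermediate disordered regime (progenitor-zone-like) and a slow regime
  (presomitic-mesoderm-like). Regimes can optionally be laid out in
  left/right boxes around a midline so region-of-interest statistics can be
  exercised end to end.
* **Expression features** — cells assigned to contiguous state blocks along
  an ordering, each state with its own mean marker vector plus isotropic
  noise (piecewise-constant structure along pseudotime).
* **Intensity profiles** — 1D plateau/ramp/decay profiles shaped like a
  posterior-to-anterior tbx6 signal, with the analytic threshold-crossing
  indices returned alongside.

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .track_data import Track


@dataclass(frozen=True)
class MotionRegime:
    """A motion archetype: step-length distribution plus directionality."""

    name: str
    step_mean: float  # um per frame
    step_sd: float
    persistence: float  # 1 = ballistic, 0 = isotropic random walk
    drift: tuple[float, float, float] | None = None  # preferred direction

    def __post_init__(self) -> None:
        if self.step_mean < 0:
            raise ValueError("step mean must be >= 0")
        if not 0.0 <= self.persistence <= 1.0:
            raise ValueError("persistence must lie in [0, 1]")


#: The three tailbud-like regimes: fast directed, intermediate disordered,
#: slow. Step means are in the ratio 5 : 2.5 : 1 um/frame; persistence values
#: give window-scale straightness near 0.98, 0.84 and 0.40, so net window
#: displacements sit on three distinct high/intermediate/low plateaus.
DEFAULT_REGIMES = (
    MotionRegime("fast_directed", 5.0, 0.5, 0.8, drift=(0.0, 1.0, 0.0)),
    MotionRegime("intermediate_disordered", 2.5, 0.5, 0.6),
    MotionRegime("slow", 1.0, 0.3, 0.2),
)


@dataclass(frozen=True)
class SimConfig:
    regimes: tuple[MotionRegime, ...] = DEFAULT_REGIMES
    tracks_per_regime: int = 150
    frames_per_track: int = 10
    frame_interval: float = 3.0
    origin_spread: float = 50.0  # um, uniform box for track starts
    layout: dict | None = None  # optional {regime name: (lo, hi) corner boxes}
    seed: int = 0


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def simulate_tracks(config: SimConfig) -> tuple[list[Track], dict[str, str]]:
    """Correlated-random-walk tracks; returns (tracks, {track_id: regime name}).

    Each step is ``persistence * previous_direction + (1 - persistence) *
    random_unit_vector`` (re-normalized), scaled by a normal step-length draw
    clipped at zero. A regime's ``drift`` seeds the initial direction;
    otherwise the initial direction is random.
    """
    rng = np.random.default_rng(config.seed)
    tracks: list[Track] = []
    labels: dict[str, str] = {}
    for regime in config.regimes:
        if config.layout and regime.name in config.layout:
            lo, hi = (np.asarray(c, float) for c in config.layout[regime.name])
        else:
            lo = np.zeros(3)
            hi = np.full(3, config.origin_spread)
        for i in range(config.tracks_per_regime):
            track_id = f"{regime.name}_{i:04d}"
            pos = np.empty((config.frames_per_track, 3))
            pos[0] = rng.uniform(lo, hi)
            if regime.drift is not None:
                direction = _unit(np.asarray(regime.drift, float))
            else:
                direction = _unit(rng.standard_normal(3))
            for t in range(1, config.frames_per_track):
                rand_dir = _unit(rng.standard_normal(3))
                direction = _unit(
                    regime.persistence * direction
                    + (1.0 - regime.persistence) * rand_dir
                )
                step = max(0.0, rng.normal(regime.step_mean, regime.step_sd))
                pos[t] = pos[t - 1] + step * direction
            tracks.append(
                Track(
                    embryo_id="sim",
                    track_id=track_id,
                    frames=np.arange(config.frames_per_track),
                    positions=pos,
                )
            )
            labels[track_id] = regime.name
    return tracks, labels


def simulate_speed_gradient(
    n_windows: int = 400,
    step_range: tuple[float, float] = (1.0, 5.0),
    persistence: float = 0.6,
    window_length: int = 8,
    seed: int = 0,
) -> tuple[list[Track], np.ndarray]:
    """One-window tracks whose step lengths follow a monotone speed gradient.

    Track ``i`` walks with mean step length interpolated linearly across
    ``step_range``; the planted pseudotime order is simply ``0..n_windows-1``.
    Used to check that the learned 1D latent recovers a continuum of motion,
    not just discrete regimes.
    """
    steps = np.linspace(step_range[0], step_range[1], n_windows)
    rng = np.random.default_rng(seed)
    tracks = []
    for i, s in enumerate(steps):
        regime = MotionRegime(f"g{i:04d}", float(s), 0.1 * s, persistence)
        sub = SimConfig(
            regimes=(regime,),
            tracks_per_regime=1,
            frames_per_track=window_length,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        t, _ = simulate_tracks(sub)
        tracks.append(
            Track(
                embryo_id="grad",
                track_id=f"g{i:04d}",
                frames=t[0].frames,
                positions=t[0].positions,
            )
        )
    return tracks, np.arange(n_windows)


#: Default six-state marker means: each state expresses its own marker at
#: amplitude 3 (adjacent-state separation 3*sqrt(2) ~ 4.2); with unit noise
#: the separation-to-noise ratio matches a clean piecewise marker profile.
DEFAULT_STATE_MEANS = 3.0 * np.eye(6)


def simulate_expression(
    n_cells: int = 600,
    state_means: np.ndarray | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Piecewise-constant expression states along a planted ordering.

    Returns ``(features, ranks, boundaries)`` where ``ranks[i]`` is cell i's
    planted pseudotime rank and ``boundaries`` are the state-change positions
    on the rank scale (the rank of the last cell of each state but the last).
    Cells are equally split over states, earlier states getting the
    remainder.
    """
    means = np.asarray(
        DEFAULT_STATE_MEANS if state_means is None else state_means, dtype=float
    )
    if means.ndim != 2 or len(means) < 2:
        raise ValueError("need at least two state mean vectors")
    rng = np.random.default_rng(seed)
    n_states = len(means)
    sizes = np.full(n_states, n_cells // n_states)
    sizes[: n_cells % n_states] += 1
    state_of_rank = np.repeat(np.arange(n_states), sizes)
    features_ordered = means[state_of_rank] + noise_sd * rng.standard_normal(
        (n_cells, means.shape[1])
    )
    # present cells in shuffled order with an explicit rank vector:
    # cell i carries the feature of planted rank perm[i]
    perm = rng.permutation(n_cells)
    features = features_ordered[perm]
    ranks = perm.copy()
    boundaries = np.cumsum(sizes)[:-1] - 1
    return features, ranks, boundaries


@dataclass(frozen=True)
class ProfileSpec:
    """Piecewise tbx6-like profile: rise from the tail tip, plateau, decay.

    Indices run posterior (tail tip, index 0) to anterior. The signal ramps
    from 0 to 1 over ``[rise_start, rise_end]``, holds a plateau at 1 until
    ``plateau_end``, then decays linearly to ``tail_level`` at the anterior
    end.
    """

    length: int = 200
    rise_start: int = 20
    rise_end: int = 80
    plateau_end: int = 150
    tail_level: float = 0.1

    def __post_init__(self) -> None:
        if not 0 <= self.rise_start < self.rise_end < self.plateau_end < self.length:
            raise ValueError("profile spans must be ordered within length")


def _noiseless_profile(spec: ProfileSpec) -> np.ndarray:
    x = np.arange(spec.length, dtype=float)
    vals = np.zeros(spec.length)
    rise = (x - spec.rise_start) / (spec.rise_end - spec.rise_start)
    vals = np.clip(rise, 0.0, 1.0)
    decay_len = spec.length - 1 - spec.plateau_end
    if decay_len > 0:
        anterior = x > spec.plateau_end
        frac = (x[anterior] - spec.plateau_end) / decay_len
        vals[anterior] = 1.0 + frac * (spec.tail_level - 1.0)
    return vals


def simulate_profile(
    spec: ProfileSpec | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    low: float = 0.20,
    high: float = 0.85,
) -> tuple[np.ndarray, tuple[int, int]]:
    """Synthetic tbx6 intensity profile plus the analytic threshold bounds.

    The returned ``(boundary, anterior_end)`` are the exact first-above-
    ``low * max`` and last-above-``high * max`` indices of the noiseless
    profile, for comparison against measured bounds on the noisy one. Noise
    is truncated at zero (intensities are nonnegative).
    """
    spec = spec or ProfileSpec()
    clean = _noiseless_profile(spec)
    mx = clean.max()
    boundary = int(np.argmax(clean > low * mx))
    anterior = int(len(clean) - 1 - np.argmax(clean[::-1] > high * mx))
    rng = np.random.default_rng(seed)
    noisy = np.clip(clean + noise_sd * rng.standard_normal(spec.length), 0.0, None)
    return noisy, (boundary, anterior)
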