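"""Quantification of PZ/PSM extent from fluorescent in situ images.

The posterior tbx6 expression boundary defines the transition from the
progenitor zone (PZ) to the presomitic mesoderm (PSM). Working on a 1D
intensity profile oriented posterior (tail tip, index 0) to anterior:

* the PZ/PSM boundary is the first point exceeding 20% of the maximum tbx6
  intensity, and the anterior end of the PSM is the last point exceeding
  85% of the maximum (strict inequalities, thresholds relative to the
  profile's own maximum so the rule is intensity-scale invariant);
* the scaled PZ length is the boundary position divided by the distance
  from the tail tip to the anterior PSM boundary.

Profiles come either from a straight-axis projection (per-column mean of a
Gaussian-smoothed, masked 2D image, split into left and right halves and
normalized per side) or, for bent embryos, from projecting masked pixels
onto a Savitzky-Golay-smoothed body-axis polyline and averaging along arc
length with a sliding window. In the bent case areas replace lengths: the
scaled PZ area is the PZ pixel count over the PZ + PSM pixel count, with
region boundaries realized as the arc-length cutoffs of each pixel's
closest-point projection (equivalent to perpendiculars for a straight axis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from skimage.filters import gaussian as _gaussian_filter
from skimage.filters import threshold_otsu

DEFAULT_LOW = 0.20
DEFAULT_HIGH = 0.85
DEFAULT_SMOOTH_SIGMA = 2.0  # px, Gaussian image smoothing
DEFAULT_SAVGOL_WINDOW = 21  # axis-polyline smoothing
DEFAULT_SAVGOL_ORDER = 3
DEFAULT_PROFILE_WINDOW = 10  # px, sliding-window mean along arc length


@dataclass(frozen=True)
class RegionBounds:
    """Indices of the PZ/PSM boundary and the anterior PSM end on a profile."""

    pz_psm_boundary: int
    anterior_end: int
    length: int

    def __post_init__(self) -> None:
        if not 0 <= self.pz_psm_boundary <= self.anterior_end < self.length:
            raise ValueError(
                f"invalid bounds: boundary={self.pz_psm_boundary}, "
                f"anterior_end={self.anterior_end}, length={self.length}"
            )


def find_bounds(
    profile: np.ndarray, low: float = DEFAULT_LOW, high: float = DEFAULT_HIGH
) -> RegionBounds:
    """Threshold a tbx6 profile into PZ and PSM extents.

    ``profile`` runs posterior (index 0) to anterior. Boundary = first index
    with value > ``low * max``; anterior end = last index with value >
    ``high * max``.
    """
    p = np.asarray(profile, dtype=float)
    if p.ndim != 1 or len(p) < 3:
        raise ValueError("profile must be 1D with length >= 3")
    if not 0 <= low < high:
        raise ValueError("need 0 <= low < high")
    mx = p.max()
    if mx <= 0:
        raise ValueError("profile has no positive signal; cannot normalize")
    above_low = p > low * mx
    above_high = p > high * mx
    boundary = int(np.argmax(above_low))
    anterior = int(len(p) - 1 - np.argmax(above_high[::-1]))
    if boundary > anterior:
        raise ValueError(
            f"pathological profile: PZ/PSM boundary (index {boundary}) lies "
            f"anterior to the PSM end (index {anterior})"
        )
    return RegionBounds(boundary, anterior, len(p))


def scaled_pz_length(bounds: RegionBounds) -> float:
    """PZ length over tail-tip-to-anterior-PSM distance, in [0, 1]."""
    if bounds.anterior_end == 0:
        raise ValueError("anterior end at the tail tip; scaled length undefined")
    return bounds.pz_psm_boundary / bounds.anterior_end


def otsu_mask(image: np.ndarray) -> np.ndarray:
    """Foreground mask by Otsu's between-class-variance threshold."""
    image = np.asarray(image, dtype=float)
    if np.unique(image).size < 2:
        raise ValueError("constant image has no Otsu threshold")
    return image > threshold_otsu(image)


def straight_axis_profile(
    image: np.ndarray,
    mask: np.ndarray,
    midline_row: int,
    sigma: float = DEFAULT_SMOOTH_SIGMA,
    normalize: bool = True,
) -> dict[str, np.ndarray]:
    """Left/right AP intensity profiles of a straight embryo.

    The image is Gaussian-smoothed, then for each side (rows above/below
    ``midline_row``) the per-column mean over masked pixels is taken and
    normalized to that side's maximum. Columns run posterior to anterior.
    Columns with no masked pixel on a side are NaN.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    smoothed = (
        _gaussian_filter(image, sigma=sigma, preserve_range=True)
        if sigma > 0
        else image
    )
    profiles = {}
    for side, rows in (
        ("left", slice(0, midline_row)),
        ("right", slice(midline_row, image.shape[0])),
    ):
        sub, m = smoothed[rows], mask[rows]
        if not m.any():
            raise ValueError(f"empty mask on the {side} side")
        with np.errstate(invalid="ignore"):
            prof = np.where(
                m.sum(axis=0) > 0, np.nansum(sub * m, axis=0) / m.sum(axis=0), np.nan
            )
        if normalize:
            prof = prof / np.nanmax(prof)
        profiles[side] = prof
    return profiles


def smooth_axis(
    perimeter: np.ndarray,
    window: int = DEFAULT_SAVGOL_WINDOW,
    order: int = DEFAULT_SAVGOL_ORDER,
) -> np.ndarray:
    """Savitzky-Golay-smooth an ordered 2D polyline (the embryo's axis)."""
    pts = np.asarray(perimeter, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("perimeter must be an (n >= 3, 2) polyline")
    if np.any(np.all(np.diff(pts, axis=0) == 0, axis=1)):
        raise ValueError("perimeter has repeated consecutive points")
    w = min(window, len(pts) if len(pts) % 2 else len(pts) - 1)
    if w <= order:
        return pts.copy()
    return np.column_stack(
        [savgol_filter(pts[:, 0], w, order), savgol_filter(pts[:, 1], w, order)]
    )


def _arc_positions(curve: np.ndarray) -> np.ndarray:
    steps = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    return np.concatenate(([0.0], np.cumsum(steps)))


def project_to_axis(
    points: np.ndarray, curve: np.ndarray
) -> np.ndarray:
    """Arc-length position of each point's closest curve vertex.

    Ties (a point equidistant to several vertices) resolve to the earlier
    arc-length position, i.e. the first minimum along the ordered curve.
    """
    arc = _arc_positions(curve)
    # chunked nearest-vertex scan keeps memory bounded on large masks
    out = np.empty(len(points))
    for start in range(0, len(points), 4096):
        chunk = points[start : start + 4096]
        d2 = ((chunk[:, None, :] - curve[None, :, :]) ** 2).sum(-1)
        out[start : start + len(chunk)] = arc[np.argmin(d2, axis=1)]
    return out


def curved_axis_profile(
    image: np.ndarray,
    perimeter: np.ndarray,
    mask: np.ndarray | None = None,
    window: float = DEFAULT_PROFILE_WINDOW,
    savgol_window: int = DEFAULT_SAVGOL_WINDOW,
    savgol_order: int = DEFAULT_SAVGOL_ORDER,
    normalize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean intensity along a curved body axis.

    Masked pixels are projected to their closest point on the smoothed
    perimeter; the profile at each integer arc-length position is the mean
    intensity of pixels projecting within ``window / 2`` of it (a sliding-
    window mean along arc length). Returns ``(profile, arc_positions)``;
    empty windows are NaN.
    """
    image = np.asarray(image, dtype=float)
    mask = np.ones_like(image, dtype=bool) if mask is None else np.asarray(mask, bool)
    curve = smooth_axis(perimeter, savgol_window, savgol_order)
    arc = _arc_positions(curve)
    if arc[-1] <= window:
        raise ValueError("perimeter arc length must exceed the sliding window")
    rows, cols = np.nonzero(mask)
    if len(rows) == 0:
        raise ValueError("empty mask")
    pix = np.column_stack([cols, rows]).astype(float)  # (x, y) order
    s = project_to_axis(pix, curve)
    vals = image[rows, cols]
    positions = np.arange(0.0, arc[-1] + 1.0)
    half = window / 2.0
    profile = np.full(len(positions), np.nan)
    order_s = np.argsort(s, kind="stable")
    s_sorted, v_sorted = s[order_s], vals[order_s]
    lo = np.searchsorted(s_sorted, positions - half, side="left")
    hi = np.searchsorted(s_sorted, positions + half, side="right")
    csum = np.concatenate(([0.0], np.cumsum(v_sorted)))
    counts = hi - lo
    nonzero = counts > 0
    profile[nonzero] = (csum[hi] - csum[lo])[nonzero] / counts[nonzero]
    if normalize and np.nanmax(profile) > 0:
        profile = profile / np.nanmax(profile)
    return profile, positions


def scaled_pz_area(
    mask: np.ndarray,
    perimeter: np.ndarray,
    bounds_arc: tuple[float, float],
    savgol_window: int = DEFAULT_SAVGOL_WINDOW,
    savgol_order: int = DEFAULT_SAVGOL_ORDER,
) -> float:
    """PZ area over PZ + PSM area on a curved axis.

    ``bounds_arc`` gives the PZ/PSM boundary and anterior PSM end as
    arc-length positions along the smoothed perimeter. Region membership of
    each masked pixel follows its closest-point projection: PZ is arc length
    below the boundary, PSM between boundary and anterior end.
    """
    mask = np.asarray(mask, dtype=bool)
    boundary, anterior = bounds_arc
    if not 0 <= boundary <= anterior:
        raise ValueError("need 0 <= boundary <= anterior arc positions")
    curve = smooth_axis(perimeter, savgol_window, savgol_order)
    rows, cols = np.nonzero(mask)
    if len(rows) == 0:
        raise ValueError("empty mask")
    s = project_to_axis(np.column_stack([cols, rows]).astype(float), curve)
    pz = int(np.sum(s < boundary))
    psm = int(np.sum((s >= boundary) & (s <= anterior)))
    if pz + psm == 0:
        raise ValueError("no pixels fall in the PZ + PSM region")
    return pz / (pz + psm)
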