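"""Cell-width estimation from cell-wall fluorescence.

Calcofluor White stains the chitinous cell wall, so a straight line through
a hypha perpendicular to its axis sees two bright wall peaks separated by
the cell diameter. Width is therefore defined primarily as the distance
between the innermost opposing pair of wall peaks of an intensity profile;
where the walls are not resolved (axial blur, thin cells), the full width at
half maximum of the background-subtracted profile serves as fallback. Both
definitions are invariant under uniform intensity scaling.

Per cell, profiles are taken at several axial positions away from the septa
and in several radial directions perpendicular to the local axis; directions
close to the optical (z) axis are excluded because the elongated confocal
point-spread function inflates apparent widths there. The per-cell width is
the median of all successful per-profile widths.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import NamedTuple, Optional

import numpy as np
from scipy import ndimage, signal

from .core import (
    CellSegment,
    ConfigurationError,
    DegenerateGeometryError,
    HyphalSkeleton,
    ImageStack,
)
from .geometry import cell_polyline

# profiles whose direction lies within this angle of the optical axis are
# skipped: the axial PSF (sigma_z ~ 3x lateral) would dominate the estimate
Z_EXCLUSION_DEG = 30.0


@dataclass(frozen=True)
class WidthParams:
    """Tunable parameters of the width estimator (lengths in µm).

    n_axial_samples
        Number of positions sampled along the cell axis.
    end_margin_fraction
        Fraction of the cell length excluded at each end, keeping profiles
        away from the bright septa.
    n_radial_directions
        Number of evenly spaced profile directions per axial position
        (spread over 180°; a profile covers both sides of the axis).
    profile_halfwidth_um, profile_step_um
        Half-extent and sampling step of each intensity profile.
    background_quantile
        Quantile of the profile used as the background estimate.
    min_peak_prominence_fraction
        Minimum peak prominence, as a fraction of the profile's dynamic
        range above background, for a local maximum to count as a wall.
    smoothing_sigma_um
        Gaussian smoothing applied to the profile before peak detection,
        suppressing shot/readout noise maxima that would otherwise register
        as spurious inner wall peaks; the default matches the lateral PSF
        width, so no real structure is lost.
    """

    n_axial_samples: int = 5
    end_margin_fraction: float = 0.15
    n_radial_directions: int = 8
    profile_halfwidth_um: float = 5.0
    profile_step_um: float = 0.05
    background_quantile: float = 0.2
    min_peak_prominence_fraction: float = 0.2
    smoothing_sigma_um: float = 0.2

    def __post_init__(self) -> None:
        if self.n_axial_samples < 1 or self.n_radial_directions < 1:
            raise ConfigurationError("sample counts must be positive")
        if not (0 < self.end_margin_fraction < 0.5):
            raise ConfigurationError("end_margin_fraction must lie in (0, 0.5)")
        if self.profile_halfwidth_um <= 0 or self.profile_step_um <= 0:
            raise ConfigurationError("profile extent and step must be positive")
        if not (0 < self.background_quantile < 1):
            raise ConfigurationError("background_quantile must lie in (0, 1)")
        if self.min_peak_prominence_fraction <= 0:
            raise ConfigurationError("min_peak_prominence_fraction must be positive")
        if self.smoothing_sigma_um < 0:
            raise ConfigurationError("smoothing_sigma_um must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "WidthParams":
        return cls(**d)


class Profile(NamedTuple):
    """An intensity profile: signed offsets (µm) and interpolated intensities."""

    offsets: np.ndarray
    intensities: np.ndarray


def sample_profile(
    stack: ImageStack,
    center_um: np.ndarray,
    direction: np.ndarray,
    halfwidth_um: float,
    step_um: float,
) -> Profile:
    """Trilinearly interpolated intensity profile through ``center_um``.

    Samples at ``center + t·direction`` for t in −halfwidth…+halfwidth at the
    given step (µm). Samples falling outside the physical volume are dropped
    from the ends.
    """
    direction = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValueError("direction must be a non-zero vector")
    direction = direction / norm

    n_half = int(np.floor(halfwidth_um / step_um + 1e-9))
    offsets = np.arange(-n_half, n_half + 1) * step_um
    points_um = np.asarray(center_um, dtype=float)[None, :] + offsets[:, None] * direction
    voxels = points_um / stack.grid.spacing  # (x, y, z) continuous voxel coords

    upper = stack.grid.counts - 1
    inside = np.all((voxels >= 0) & (voxels <= upper), axis=1)
    offsets = offsets[inside]
    voxels = voxels[inside]

    # map_coordinates wants (z, y, x) index order
    coords = voxels[:, ::-1].T
    values = ndimage.map_coordinates(
        np.asarray(stack.intensities, dtype=float), coords, order=1, mode="nearest"
    )
    return Profile(offsets=offsets, intensities=values)


def _parabolic_refine(x: np.ndarray, y: np.ndarray, i: int) -> float:
    """Sub-step peak position by a 3-point parabola around sample ``i``."""
    if i == 0 or i == len(y) - 1:
        return float(x[i])
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom >= 0:  # not a strict local maximum in curvature terms
        return float(x[i])
    shift = 0.5 * (y[i - 1] - y[i + 1]) / denom
    step = x[i + 1] - x[i]
    return float(x[i] - shift * step)


def _fwhm(offsets: np.ndarray, y: np.ndarray) -> Optional[float]:
    """Full width at half maximum of a background-subtracted profile."""
    i_max = int(np.argmax(y))
    y_max = y[i_max]
    if y_max <= 0:
        return None
    half = y_max / 2.0

    left = None
    for i in range(i_max, 0, -1):
        if y[i - 1] < half <= y[i]:
            frac = (half - y[i - 1]) / (y[i] - y[i - 1])
            left = offsets[i - 1] + frac * (offsets[i] - offsets[i - 1])
            break
    right = None
    for i in range(i_max, len(y) - 1):
        if y[i] >= half > y[i + 1]:
            frac = (y[i] - half) / (y[i] - y[i + 1])
            right = offsets[i] + frac * (offsets[i + 1] - offsets[i])
            break
    if left is None or right is None:
        return None
    return float(right - left)


def width_from_profile(profile: Profile, params: WidthParams) -> Optional[float]:
    """Width (µm) from one intensity profile, or ``None`` on failure.

    Wall peaks are local maxima whose prominence exceeds
    ``min_peak_prominence_fraction`` of the dynamic range above the
    background (the ``background_quantile`` quantile), refined to sub-step
    precision by a 3-point parabolic fit. With at least one peak on each side
    of the centre, the width is the distance between the innermost opposing
    pair; otherwise the FWHM of the background-subtracted profile; otherwise
    failure.
    """
    offsets, y_raw = profile.offsets, profile.intensities
    if len(y_raw) < 5:
        raise ValueError("profile needs at least 5 samples")

    # smoothing is for peak *detection* only; the FWHM fallback measures the
    # raw profile so the smoothing kernel cannot widen it
    y = np.asarray(y_raw, dtype=float)
    if params.smoothing_sigma_um > 0 and len(offsets) > 1:
        step = float(np.median(np.diff(offsets)))
        y = ndimage.gaussian_filter1d(y, params.smoothing_sigma_um / step, mode="nearest")

    background = float(np.quantile(y, params.background_quantile))
    peak_value = float(np.max(y))
    dynamic = peak_value - background
    # relative guard: an essentially constant profile has no structure, even
    # when interpolation leaves femto-scale wiggles on it
    if dynamic <= 1e-9 * max(abs(peak_value), abs(background), 1e-300):
        return None

    peaks, _ = signal.find_peaks(
        y, prominence=params.min_peak_prominence_fraction * dynamic
    )
    if len(peaks) >= 2:
        positions = np.array([_parabolic_refine(offsets, y, i) for i in peaks])
        left = positions[positions < 0]
        right = positions[positions > 0]
        if len(left) >= 1 and len(right) >= 1:
            return float(right.min() - left.max())

    return _fwhm(offsets, np.asarray(y_raw, dtype=float) - background)


def _perpendicular_basis(tangent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two orthonormal vectors spanning the plane perpendicular to ``tangent``."""
    t = tangent / np.linalg.norm(tangent)
    helper = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(t, helper)) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    u = np.cross(t, helper)
    u /= np.linalg.norm(u)
    v = np.cross(t, u)
    return u, v


def _axial_samples(
    polyline_um: np.ndarray, fractions: np.ndarray
) -> list[tuple[np.ndarray, np.ndarray]]:
    """(point, unit tangent) pairs at given arc-length fractions of a polyline."""
    seg = np.diff(polyline_um, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    total = float(seg_len.sum())
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    out = []
    for f in fractions:
        s = f * total
        i = int(np.searchsorted(cum, s, side="right") - 1)
        i = min(max(i, 0), len(seg) - 1)
        if seg_len[i] == 0:
            continue
        local = (s - cum[i]) / seg_len[i]
        point = polyline_um[i] + local * seg[i]
        tangent = seg[i] / seg_len[i]
        out.append((point, tangent))
    return out


def estimate_cell_width(
    stack: ImageStack,
    cell: CellSegment,
    skeleton: HyphalSkeleton,
    params: Optional[WidthParams] = None,
) -> Optional[float]:
    """Median wall-to-wall width of one cell, in µm, or ``None`` on failure.

    Profiles are sampled at ``n_axial_samples`` positions uniformly spaced
    over the central part of the cell axis (excluding ``end_margin_fraction``
    at each end, which keeps clear of the septa) in ``n_radial_directions``
    directions perpendicular to the local axis; directions within 30° of the
    optical axis are excluded. The estimate fails when fewer than one third
    of the attempted profiles yield a width.
    """
    if params is None:
        params = WidthParams()
    polyline_um = cell_polyline(cell, skeleton) * skeleton.grid.spacing
    length = float(np.sum(np.linalg.norm(np.diff(polyline_um, axis=0), axis=1)))
    if length <= 0:
        raise DegenerateGeometryError(f"cell {cell.id!r} has zero length")

    fractions = np.linspace(
        params.end_margin_fraction, 1 - params.end_margin_fraction, params.n_axial_samples
    )
    cos_limit = np.cos(np.deg2rad(Z_EXCLUSION_DEG))
    angles = np.pi * np.arange(params.n_radial_directions) / params.n_radial_directions

    widths: list[float] = []
    attempted = 0
    for point, tangent in _axial_samples(polyline_um, fractions):
        u, v = _perpendicular_basis(tangent)
        for angle in angles:
            direction = np.cos(angle) * u + np.sin(angle) * v
            if abs(direction[2]) > cos_limit:
                continue  # too close to the optical axis
            attempted += 1
            profile = sample_profile(
                stack, point, direction, params.profile_halfwidth_um, params.profile_step_um
            )
            if len(profile.intensities) < 5:
                continue
            w = width_from_profile(profile, params)
            if w is not None and w > 0:
                widths.append(w)

    if attempted == 0 or len(widths) < attempted / 3:
        return None
    return float(np.median(widths))
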