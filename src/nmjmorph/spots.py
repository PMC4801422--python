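"""Active-zone counting: 3D local maxima of the spot (Brp) channel.

The stack is smoothed by a 3D grey closing (fills sub-structuring-
element dark gaps inside puncta), then local maxima are detected in
full 26-connectivity.  Touching maximal voxels collapse into one spot;
a spot survives only if its peak rises above its surrounding saddle by
more than the noise tolerance (flood-fill prominence, implemented via
the h-maxima transform) and strictly exceeds a minimum intensity floor.
Spots whose x/y position falls outside the terminal footprint are
discarded.

Presets mirror the two acquisition regimes: wide-field uses a
Huang-derived automatic floor and a tolerance of 10% of the dynamic
range; confocal uses tolerance 100 and floor 250 (intensity units).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology

from .io_stack import NmjStackPair
from .outline import OutlineMask
from .roi import RoiMask
from .thresholds import DegenerateHistogramError, histogram_256, huang_threshold

__all__ = ["SpotParams", "SpotSet", "grey_close_3d", "find_maxima_3d", "count_active_zones"]

AUTO_HUANG = "auto-huang"

CONFOCAL_NOISE_TOLERANCE = 100.0
CONFOCAL_MIN_INTENSITY = 250.0


@dataclass(frozen=True)
class SpotParams:
    """Detection parameters for active-zone counting.

    ``min_intensity`` may be a number or ``"auto-huang"``; ``noise_tolerance``
    of None means 10% of the within-footprint dynamic range.
    """

    closing_radius_px: int = 1
    noise_tolerance: float | None = None
    min_intensity: float | str = AUTO_HUANG

    def __post_init__(self):
        if self.closing_radius_px < 0:
            raise ValueError("closing_radius_px must be >= 0")
        if self.noise_tolerance is not None and self.noise_tolerance < 0:
            raise ValueError("noise_tolerance must be >= 0")

    @classmethod
    def widefield(cls) -> "SpotParams":
        return cls()

    @classmethod
    def confocal(cls) -> "SpotParams":
        return cls(
            noise_tolerance=CONFOCAL_NOISE_TOLERANCE,
            min_intensity=CONFOCAL_MIN_INTENSITY,
        )

    def with_overrides(self, **kwargs) -> "SpotParams":
        return replace(self, **kwargs)


@dataclass
class SpotSet:
    coordinates: list  # (z, y, x) voxel centroids
    count: int
    flags: set = field(default_factory=set)


def grey_close_3d(stack, radius_px: int = 1) -> np.ndarray:
    """Grey-level morphological closing with a discrete ball of given radius."""
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("expected a 3D stack")
    if radius_px < 0:
        raise ValueError("radius must be >= 0")
    if radius_px == 0:
        return stack.copy()
    footprint = morphology.ball(radius_px)
    return ndi.grey_closing(stack, footprint=footprint)


def _resolve_floor(stack, footprint, min_intensity):
    if min_intensity == AUTO_HUANG:
        values = stack[:, footprint]
        try:
            counts, lo, width = histogram_256(values)
            t = huang_threshold(counts)
        except DegenerateHistogramError:
            return None  # flat image: no meaningful floor
        return lo + (t + 1) * width
    return float(min_intensity)


def find_maxima_3d(stack, params: SpotParams, footprint) -> SpotSet:
    """Detect spots as prominent 3D local maxima within a 2D footprint.

    A voxel is maximal if it is >= all 26 neighbors; mutually touching
    maximal voxels merge into one spot whose centroid is reported.
    """
    stack = np.asarray(stack, dtype=np.float64)
    footprint = np.asarray(footprint, dtype=bool)
    if stack.ndim != 3:
        raise ValueError("expected a 3D stack")
    if footprint.shape != stack.shape[1:]:
        raise ValueError("footprint shape must match stack x/y shape")
    if not footprint.any():
        raise ValueError("empty footprint")

    flags: set = set()
    tol = params.noise_tolerance
    if tol is None:
        inside = stack[:, footprint]
        tol = 0.1 * float(inside.max() - inside.min())

    conn = np.ones((3, 3, 3), dtype=bool)
    if tol > 0:
        maxima = morphology.h_maxima(stack, tol, footprint=conn).astype(bool)
    else:
        maxima = stack >= ndi.maximum_filter(stack, footprint=conn, mode="nearest")

    floor = _resolve_floor(stack, footprint, params.min_intensity)
    if floor is None:
        flags.add("spot_floor_failed")
        return SpotSet([], 0, flags)

    labels, n = ndi.label(maxima, structure=conn)
    coords: list[tuple[float, float, float]] = []
    if n:
        peaks = ndi.maximum(stack, labels=labels, index=np.arange(1, n + 1))
        centroids = ndi.center_of_mass(maxima, labels=labels, index=np.arange(1, n + 1))
        for peak, (cz, cy, cx) in zip(np.atleast_1d(peaks), centroids):
            if peak <= floor:  # spots must *exceed* the minimum intensity
                continue
            iy = int(round(cy))
            ix = int(round(cx))
            if not (0 <= iy < footprint.shape[0] and 0 <= ix < footprint.shape[1]):
                continue
            if not footprint[iy, ix]:
                continue
            coords.append((float(cz), float(cy), float(cx)))
    return SpotSet(coords, len(coords), flags)


def count_active_zones(
    pair: NmjStackPair, outline: OutlineMask, roi: RoiMask, params: SpotParams
) -> SpotSet:
    """Full spot stage: 3D grey closing then maxima within outline AND ROI."""
    foot = outline.mask & roi.mask
    closed = grey_close_3d(pair.spot_stack, params.closing_radius_px)
    return find_maxima_3d(closed, params, foot)
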