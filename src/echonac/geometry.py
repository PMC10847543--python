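"""Scale-bar-calibrated tumor geometry from binary lesion masks.

Given a segmentation mask and a pixels-per-centimeter calibration, computes
the clinical measurement quantities: tumor count, total area (cm^2), longest
axis (cm, the LAM size), product of the longest axis and its perpendicular
extent (cm^2, the DAM size), equivalent diameter, length-to-width ratio and
lesion-to-image area ratio.  Multifocal disease is summed per measurement
model's own size definition.

Conventions (the clinical papers leave these open): lengths are measured
center-to-center between pixel centers; the perpendicular width is the
projection extent onto the normal of the longest-axis direction, clamped to
a minimum of one pixel so degenerate one-pixel-thin components keep a
physical width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage import measure as skmeasure


@dataclass(frozen=True)
class Calibration:
    px_per_cm: float

    def __post_init__(self):
        if self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be positive")


@dataclass(frozen=True)
class Component:
    """One 8-connected lesion component: pixel coordinates and area."""

    coords: np.ndarray  # (n, 2) int (row, col)

    @property
    def area_px(self) -> int:
        return len(self.coords)


@dataclass(frozen=True)
class TumorMeasurements:
    tumor_count: int
    total_area: float            # cm^2, summed over components
    longest_axis: float          # cm, largest component (LAM, largest mode)
    longest_axis_sum: float      # cm, summed over components (LAM, multifocal)
    dual_axis_product: float     # cm^2, summed over components (DAM)
    equivalent_diameter: float   # cm, 2*sqrt(total_area/pi)
    length_to_width_ratio: float  # >= 1, largest component
    area_ratio: float            # lesion pixels / image pixels


def extract_components(mask, min_area_px: int = 10) -> list[Component]:
    """8-connected components with at least ``min_area_px`` pixels, largest first."""
    mask = np.asarray(mask) > 0
    labeled = skmeasure.label(mask, connectivity=2)
    comps = [Component(coords=np.argwhere(labeled == lab))
             for lab in range(1, labeled.max() + 1)]
    comps = [c for c in comps if c.area_px >= min_area_px]
    return sorted(comps, key=lambda c: c.area_px, reverse=True)


def _axis_endpoints(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Pixel-center pair realizing the maximum Euclidean distance.

    The maximum over all pairs is attained on the convex hull, so the search
    runs over hull vertices (falling back to all pairs for tiny or collinear
    sets where Qhull degenerates).
    """
    pts = coords.astype(np.float64)
    if len(pts) == 1:
        return pts[0], pts[0], 0.0
    if len(pts) > 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # collinear: brute force below
    diff = pts[:, None, :] - pts[None, :, :]
    d2 = (diff**2).sum(axis=2)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    return pts[i], pts[j], float(np.sqrt(d2[i, j]))


def longest_axis(component: Component, calib: Calibration) -> float:
    """Longest center-to-center distance within the component, in cm."""
    if component.area_px == 0:
        raise ValueError("empty component")
    _, _, dist = _axis_endpoints(component.coords)
    return dist / calib.px_per_cm


def _perpendicular_width_px(component: Component) -> float:
    p, q, dist = _axis_endpoints(component.coords)
    if dist == 0:
        return 1.0
    u = (q - p) / dist
    normal = np.array([-u[1], u[0]])
    proj = component.coords.astype(np.float64) @ normal
    return max(float(proj.max() - proj.min()), 1.0)


def dual_axis_product(component: Component, calib: Calibration) -> float:
    """Longest axis times its maximum perpendicular extent, in cm^2."""
    if component.area_px == 0:
        raise ValueError("empty component")
    _, _, dist = _axis_endpoints(component.coords)
    width = _perpendicular_width_px(component)
    return dist * width / calib.px_per_cm**2


def measure(mask, calib: Calibration, min_area_px: int = 10) -> TumorMeasurements:
    """Full measurement record for one mask (zeroed for an empty mask)."""
    mask = np.asarray(mask) > 0
    comps = extract_components(mask, min_area_px=min_area_px)
    n_image_px = mask.size
    if not comps:
        return TumorMeasurements(0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    ppc = calib.px_per_cm
    areas_cm2 = [c.area_px / ppc**2 for c in comps]
    axes_cm = [longest_axis(c, calib) for c in comps]
    total_area = float(sum(areas_cm2))
    largest = comps[0]
    _, _, l_px = _axis_endpoints(largest.coords)
    w_px = _perpendicular_width_px(largest)
    ratio = max(l_px, w_px, 1.0) / max(min(l_px, w_px), 1.0)
    return TumorMeasurements(
        tumor_count=len(comps),
        total_area=total_area,
        longest_axis=float(axes_cm[0]),
        longest_axis_sum=float(sum(axes_cm)),
        dual_axis_product=float(sum(dual_axis_product(c, calib) for c in comps)),
        equivalent_diameter=float(2.0 * np.sqrt(total_area / np.pi)),
        length_to_width_ratio=float(ratio),
        area_ratio=float(sum(c.area_px for c in comps) / n_image_px),
    )
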