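"""2-D shape features of the PCAT mask.

Shape descriptors are gray-level independent: they see only the binary
mask and the in-plane spacing.  The mask (possibly several disconnected
fat patches) is treated as a single region; a separate connected-
component count captures fragmentation.

Perimeters use the 4-direction Crofton estimator, which is an
approximately unbiased estimate of the true boundary length of the
underlying continuous region; circularity ``4*pi*A / P**2`` is clamped
to 1 because discretization can push the estimate marginally above the
ideal disc value.

In-plane spacing must be isotropic (dy == dx); anisotropic in-plane
reconstruction is not supported for shape descriptors.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage import measure

SHAPE_FEATURES = (
    "area",
    "convex_area",
    "perimeter",
    "convex_perimeter",
    "perimeter_area_ratio",
    "circularity",
    "compactness",
    "feret_diameter_max",
    "feret_diameter_min",
    "major_axis_length",
    "minor_axis_length",
    "elongation",
    "eccentricity",
    "orientation",
    "extent",
    "solidity",
    "equivalent_diameter",
    "bbox_width",
    "bbox_height",
    "euler_number",
    "n_components",
)

_EIGHT_CONN = np.ones((3, 3), dtype=int)


def _pixel_corner_hull(coords: np.ndarray) -> np.ndarray | None:
    """Convex hull vertices of the pixel-corner point cloud, or None if flat."""
    corners = np.concatenate(
        [coords + np.array(shift) for shift in ((-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5))]
    )
    try:
        hull = ConvexHull(corners)
    except QhullError:
        return None
    return corners[hull.vertices]


def _feret_diameters(coords: np.ndarray, pixel_mm: float) -> tuple[float, float]:
    """(max, min) Feret diameters via rotating calipers on the corner hull."""
    verts = _pixel_corner_hull(coords)
    if verts is None:  # degenerate (collinear) region
        span = coords.max(axis=0) - coords.min(axis=0) + 1.0
        return float(span.max() * pixel_mm), float(span.min() * pixel_mm)
    diffs = verts[:, None, :] - verts[None, :, :]
    feret_max = float(np.sqrt((diffs**2).sum(axis=-1)).max())
    edges = np.roll(verts, -1, axis=0) - verts
    lengths = np.linalg.norm(edges, axis=1)
    normals = np.column_stack([-edges[:, 1], edges[:, 0]]) / lengths[:, None]
    proj = normals @ verts.T
    widths = proj.max(axis=1) - proj.min(axis=1)
    return feret_max * pixel_mm, float(widths.min()) * pixel_mm


def shape_features(mask: np.ndarray, spacing_mm: tuple[float, float]) -> dict[str, float]:
    """The 21 shape features of a nonempty 2-D binary mask."""
    mask = np.asarray(mask, dtype=bool)
    dy, dx = spacing_mm
    if abs(dy - dx) > 1e-9:
        raise ValueError("shape features require isotropic in-plane spacing")
    if not mask.any():
        raise ValueError("shape features need a nonempty mask")
    px = dx
    px_area = dy * dx

    props = measure.regionprops(mask.astype(np.uint8))[0]
    n_pixels = int(mask.sum())
    area = n_pixels * px_area
    convex_img = props.image_convex
    convex_area = int(convex_img.sum()) * px_area
    perimeter = float(measure.perimeter_crofton(mask, directions=4)) * px
    convex_perimeter = float(measure.perimeter_crofton(convex_img, directions=4)) * px

    circularity = 1.0 if perimeter == 0 else min(1.0, 4.0 * np.pi * area / perimeter**2)
    compactness = 1.0 if area == 0 else perimeter**2 / (4.0 * np.pi * area)

    feret_max, feret_min = _feret_diameters(np.argwhere(mask).astype(float), px)

    major = float(props.axis_major_length) * px
    minor = float(props.axis_minor_length) * px
    elongation = 1.0 if major == 0 else minor / major

    _, n_components = ndimage.label(mask, structure=_EIGHT_CONN)
    r0, c0, r1, c1 = props.bbox

    return {
        "area": area,
        "convex_area": convex_area,
        "perimeter": perimeter,
        "convex_perimeter": convex_perimeter,
        "perimeter_area_ratio": perimeter / area,
        "circularity": circularity,
        "compactness": compactness,
        "feret_diameter_max": feret_max,
        "feret_diameter_min": feret_min,
        "major_axis_length": major,
        "minor_axis_length": minor,
        "elongation": elongation,
        "eccentricity": float(props.eccentricity),
        "orientation": float(props.orientation),
        "extent": float(props.extent),
        "solidity": float(props.solidity),
        "equivalent_diameter": float(2.0 * np.sqrt(area / np.pi)),
        "bbox_width": (c1 - c0) * px,
        "bbox_height": (r1 - r0) * px,
        "euler_number": float(props.euler_number),
        "n_components": float(n_components),
    }
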