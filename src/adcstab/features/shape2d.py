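"""2D shape features of a segmentation mask.

Perimeter and mesh surface are measured on the marching-squares boundary of
the binary mask (contours at the 0.5 iso-level of the padded mask), the
same sub-pixel mesh convention reference radiomics tools use.  Axis lengths
derive from the principal components of the foreground pixel coordinates.
"""

from __future__ import annotations

import numpy as np
from skimage import measure

SHAPE2D_NAMES = (
    "MeshSurface",
    "PixelSurface",
    "Perimeter",
    "PerimeterSurfaceRatio",
    "Sphericity",
    "MaximumDiameter",
    "MajorAxisLength",
    "MinorAxisLength",
    "Elongation",
)


def _boundary_contours(mask: np.ndarray) -> list[np.ndarray]:
    padded = np.pad(mask.astype(float), 1)
    return measure.find_contours(padded, 0.5)


def _signed_area(contour: np.ndarray) -> float:
    y, x = contour[:, 0], contour[:, 1]
    return 0.5 * float(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1]))


def shape2d(mask: np.ndarray, pixel_spacing: float) -> dict[str, float]:
    """Compute the nine 2D shape features (lengths in mm, areas in mm^2).

    For a single-pixel mask the principal axes collapse; the axis lengths are
    0 and Elongation is NaN (degenerate).
    """
    mask = np.asarray(mask, dtype=bool)
    n_px = int(mask.sum())
    if n_px < 1:
        raise ValueError("shape2d requires a nonempty mask")
    s = float(pixel_spacing)

    contours = _boundary_contours(mask)
    perimeter = 0.0
    area = 0.0
    vertices = []
    for c in contours:
        perimeter += float(np.sum(np.hypot(*(np.diff(c, axis=0).T)))) * s
        # signed areas make holes subtract from the enclosed surface
        area += _signed_area(c) * s * s
        vertices.append(c[:-1])
    mesh_surface = abs(area)
    verts = np.concatenate(vertices) * s

    # maximum pairwise distance between boundary vertices; reduce via hull
    if len(verts) > 3:
        try:
            from scipy.spatial import ConvexHull

            verts = verts[ConvexHull(verts).vertices]
        except Exception:
            pass
    diff = verts[:, None, :] - verts[None, :, :]
    max_diameter = float(np.sqrt((diff**2).sum(-1)).max())

    coords = np.column_stack(np.nonzero(mask)).astype(float) * s
    if n_px > 1:
        eigvals = np.sort(np.linalg.eigvalsh(np.cov(coords.T)))
        eigvals = np.clip(eigvals, 0.0, None)
        minor, major = 4.0 * np.sqrt(eigvals)
        elongation = np.sqrt(eigvals[0] / eigvals[1]) if eigvals[1] > 0 else np.nan
    else:
        minor = major = 0.0
        elongation = np.nan

    return {
        "MeshSurface": mesh_surface,
        "PixelSurface": n_px * s * s,
        "Perimeter": perimeter,
        "PerimeterSurfaceRatio": perimeter / mesh_surface,
        "Sphericity": 2.0 * np.sqrt(np.pi * mesh_surface) / perimeter,
        "MaximumDiameter": max_diameter,
        "MajorAxisLength": float(major),
        "MinorAxisLength": float(minor),
        "Elongation": float(elongation),
    }
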