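"""Homography utilities shared across the package.

Conventions
-----------
* Coordinates are 0-based pixel centres, ``(x, y)`` with x along columns.
* Corner order is top-left, top-right, bottom-right, bottom-left.
* A homography ``h`` (3x3, ``h[2,2] == 1``) maps **target**-image coordinates
  into the **reference** frame; warping the target onto the reference grid
  therefore samples the target at ``h⁻¹(q)``.
* The 4-point parameterisation stores, for each target corner, its pixel
  displacement ``(dx, dy)`` into the reference frame, flattened in corner
  order to a vector of length 8.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import Polygon

from .nn.ops import _dlt_system

__all__ = [
    "corner_points",
    "apply_homography",
    "homography_from_offsets",
    "offsets_from_homography",
    "svd_dlt",
    "invert_homography",
    "overlap_rate",
    "corner_error",
    "quad_is_convex",
    "normalized_condition_number",
]

_SINGULAR_TOL = 1e-12


def corner_points(size: int) -> np.ndarray:
    """The four corner pixel centres of a ``size``-pixel square image."""
    s = float(size - 1)
    return np.array([[0, 0], [s, 0], [s, s], [0, s]], dtype=np.float64)


def apply_homography(h: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Apply a 3x3 homography to (..., 2) points."""
    pts = np.asarray(pts, dtype=np.float64)
    ph = np.concatenate([pts, np.ones(pts.shape[:-1] + (1,))], axis=-1)
    out = ph @ np.asarray(h, dtype=np.float64).T
    w = out[..., 2:3]
    if np.any(np.abs(w) < _SINGULAR_TOL):
        raise ValueError("homography sends a point to infinity")
    return out[..., :2] / w


def homography_from_offsets(offsets: np.ndarray, size: int) -> np.ndarray:
    """Solve the 8x8 DLT system mapping base corners onto displaced corners."""
    offsets = np.asarray(offsets, dtype=np.float64).reshape(1, 8)
    a, b, _ = _dlt_system(offsets, size)
    cond = np.linalg.cond(a[0])
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError("degenerate corner configuration for DLT")
    h8 = np.linalg.solve(a[0], b[0])
    return np.concatenate([h8, [1.0]]).reshape(3, 3)


def offsets_from_homography(h: np.ndarray, size: int) -> np.ndarray:
    """Corner displacements induced by ``h`` (inverse of the DLT)."""
    base = corner_points(size)
    return (apply_homography(h, base) - base).reshape(8)


def svd_dlt(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Classic DLT via the smallest right singular vector of the 8x9 system.

    Independent of the linear-solve formulation; used as a cross-check.
    """
    src = np.asarray(src, dtype=np.float64)
    dst = np.asarray(dst, dtype=np.float64)
    rows = []
    for (x, y), (u, v) in zip(src, dst):
        rows.append([x, y, 1, 0, 0, 0, -x * u, -y * u, -u])
        rows.append([0, 0, 0, x, y, 1, -x * v, -y * v, -v])
    _, _, vt = np.linalg.svd(np.asarray(rows))
    h = vt[-1].reshape(3, 3)
    if abs(h[2, 2]) < _SINGULAR_TOL:
        raise ValueError("degenerate corner configuration")
    return h / h[2, 2]


def invert_homography(h: np.ndarray) -> np.ndarray:
    """Inverse homography, normalised so the bottom-right entry is 1."""
    h = np.asarray(h, dtype=np.float64)
    if abs(np.linalg.det(h)) < _SINGULAR_TOL:
        raise ValueError("singular homography")
    inv = np.linalg.inv(h)
    return inv / inv[2, 2]


def overlap_rate(h: np.ndarray, size: int) -> float:
    """Shared-area fraction between the image square and its h-projection.

    The image footprint is the square ``[0, size]²`` (pixel boundaries, so a
    pure translation by ``t`` gives exactly ``(size-t)/size``).  The target
    footprint is projected into the reference frame through ``h`` and the two
    convex polygons are clipped exactly.
    """
    h = np.asarray(h, dtype=np.float64)
    if abs(np.linalg.det(h)) < _SINGULAR_TOL:
        raise ValueError("non-invertible homography")
    s = float(size)
    square = np.array([[0, 0], [s, 0], [s, s], [0, s]], dtype=np.float64)
    projected = apply_homography(h, square)
    inter = Polygon(square).intersection(Polygon(projected))
    return float(inter.area / (s * s))


def corner_error(h_est: np.ndarray, h_true: np.ndarray, size: int) -> float:
    """Mean Euclidean distance between corners projected by both homographies."""
    base = corner_points(size)
    d = apply_homography(h_est, base) - apply_homography(h_true, base)
    return float(np.mean(np.linalg.norm(d, axis=1)))


def quad_is_convex(quad: np.ndarray) -> bool:
    """True when the quadrilateral's traversal keeps a consistent orientation."""
    q = np.asarray(quad, dtype=np.float64)
    cross = []
    for i in range(4):
        a = q[(i + 1) % 4] - q[i]
        b = q[(i + 2) % 4] - q[(i + 1) % 4]
        cross.append(a[0] * b[1] - a[1] * b[0])
    cross = np.asarray(cross)
    return bool(np.all(cross > 0) or np.all(cross < 0))


def quad_preserves_orientation(quad: np.ndarray) -> bool:
    """True when the quad's signed (shoelace) area keeps the source sign.

    A mirrored projection stays convex but reverses the traversal
    orientation; such homographies cannot arise from a physical camera
    motion between overlapping views.
    """
    q = np.asarray(quad, dtype=np.float64)
    area2 = 0.0
    for i in range(4):
        x0, y0 = q[i]
        x1, y1 = q[(i + 1) % 4]
        area2 += x0 * y1 - x1 * y0
    return area2 > 0


def normalized_condition_number(h: np.ndarray, size: int) -> float:
    """Condition number of ``h`` after similarity-normalising pixel coords.

    In raw pixel coordinates even a benign translation dominates the singular
    values, so the matrix is conjugated to the ``[-1, 1]²`` frame first.
    """
    s = (size - 1) / 2.0
    n = np.array([[1 / s, 0, -1.0], [0, 1 / s, -1.0], [0, 0, 1]])
    hn = n @ np.asarray(h, dtype=np.float64) @ np.linalg.inv(n)
    return float(np.linalg.cond(hn / np.cbrt(abs(np.linalg.det(hn)))))
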