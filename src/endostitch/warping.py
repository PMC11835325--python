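"""Canvas placement and backward warping — the double-H transformer.

Both images of a pair are placed on a shared black canvas large enough to
contain the reference rectangle and the projected target quadrilateral: the
reference is moved by an integer translation only (so it is never resampled)
and the target is warped by the translation composed with the estimated
homography.  Masks record each image's warped footprint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import geometry
from .nn import Tensor
from .nn.ops import grid_sample, homography_grid

__all__ = [
    "CanvasSpec",
    "WarpedCanvas",
    "canvas_geometry",
    "warp_to_canvas",
    "double_h_transform",
    "invert_homography",
]

invert_homography = geometry.invert_homography

MASK_THRESHOLD = 0.999


@dataclass
class CanvasSpec:
    width: int
    height: int
    translation: tuple  # integer (tx, ty): canvas = image/reference coords + t

    @property
    def matrix(self) -> np.ndarray:
        tx, ty = self.translation
        return np.array([[1.0, 0, tx], [0, 1.0, ty], [0, 0, 1.0]])


@dataclass
class WarpedCanvas:
    warped_reference: np.ndarray
    warped_target: np.ndarray
    mask_reference: np.ndarray
    mask_target: np.ndarray
    spec: CanvasSpec
    h: np.ndarray

    @property
    def overlap_mask(self) -> np.ndarray:
        return self.mask_reference * self.mask_target


def canvas_geometry(h: np.ndarray, size: int) -> CanvasSpec:
    """Tight bounding box of the reference square and the projected target."""
    ref = geometry.corner_points(size)
    proj = geometry.apply_homography(h, ref)  # raises if a corner is at infinity
    allc = np.concatenate([ref, proj], axis=0)
    lo = np.floor(allc.min(axis=0)).astype(int)
    hi = np.ceil(allc.max(axis=0)).astype(int)
    return CanvasSpec(
        width=int(hi[0] - lo[0] + 1),
        height=int(hi[1] - lo[1] + 1),
        translation=(int(-lo[0]), int(-lo[1])),
    )


def _bilinear_sample(image: np.ndarray, m: np.ndarray, out_hw: tuple):
    """Sample `image` (H,W,C) at M·q for canvas pixels q; also warp a ones image."""
    x = Tensor(np.concatenate([image, np.ones(image.shape[:2] + (1,))], axis=2)
               .transpose(2, 0, 1)[None].astype(np.float32))
    hmat = Tensor(np.asarray(m, dtype=np.float64)[None])
    grid = homography_grid(hmat, out_hw, invert=False)
    out = grid_sample(x, grid).data[0].transpose(1, 2, 0)
    return out[:, :, :-1], out[:, :, -1]


def warp_to_canvas(image: np.ndarray, h: np.ndarray, spec: CanvasSpec):
    """Backward-warp ``image`` onto the canvas through ``T·h``.

    ``h`` maps image coordinates into reference coordinates; each canvas pixel
    ``q`` samples the image at ``(T·h)⁻¹ q`` with bilinear interpolation.
    Returns the warped image and its binary footprint mask.
    """
    image = np.asarray(image, dtype=np.float32)
    if image.ndim == 2:
        image = image[:, :, None]
    m = geometry.invert_homography(spec.matrix @ np.asarray(h, dtype=np.float64))
    warped, cover = _bilinear_sample(image, m, (spec.height, spec.width))
    mask = (cover >= MASK_THRESHOLD).astype(np.float32)
    warped = warped * mask[:, :, None]
    return warped, mask


def double_h_transform(pair, h: np.ndarray) -> WarpedCanvas:
    """Place both images of ``pair`` (reference, target) on a shared canvas.

    The reference is warped by the integer canvas translation only; the target
    by the translation composed with ``h``.  An empty overlap is legal (the
    canvas is still returned) so callers can diagnose failed alignments.
    """
    reference, target = pair
    if reference.shape != target.shape:
        raise ValueError("pair images must have identical shapes")
    size = reference.shape[0]
    spec = canvas_geometry(h, size)
    eye = np.eye(3)
    warped_ref, mask_ref = warp_to_canvas(reference, eye, spec)
    warped_tgt, mask_tgt = warp_to_canvas(target, h, spec)
    return WarpedCanvas(
        warped_reference=warped_ref,
        warped_target=warped_tgt,
        mask_reference=mask_ref,
        mask_target=mask_tgt,
        spec=spec,
        h=np.asarray(h, dtype=np.float64),
    )
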