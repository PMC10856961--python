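"""IR-based body segmentation and depth-mask fusion.

The body silhouette is detected in the IR image by thresholding (Otsu by
default) followed by region growth from a seed inside the body, the
reflective standing platform is excluded, the mask is cleaned by
morphological opening/closing, and finally the mask is fused with the depth
image into a masked depth frame — the 2.5D representation each view
contributes to the 3D reconstruction.

Conventions: pixel coordinates are 0-based ``(row, col)``; masks are boolean
arrays with the same shape as their source frames; depth is uint16
millimetres with 0 marking an invalid pixel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology
from skimage.filters import threshold_otsu
from skimage.segmentation import flood

from .errors import (
    BadSeedError,
    EmptyMaskError,
    MaskShapeError,
    NoBodyFoundError,
)

__all__ = [
    "BodyMask",
    "MaskedDepth",
    "segment_body",
    "exclude_platform",
    "clean_mask",
    "apply_mask",
]

log = logging.getLogger(__name__)


@dataclass
class BodyMask:
    """Binary body silhouette for one view."""

    mask: np.ndarray
    view: str = "anterior"

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass
class MaskedDepth:
    """Depth frame restricted to a body mask (non-mask pixels zeroed)."""

    depth_mm: np.ndarray
    mask: np.ndarray
    view: str = "anterior"

    def __post_init__(self):
        self.depth_mm = np.asarray(self.depth_mm)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.depth_mm.shape != self.mask.shape:
            raise MaskShapeError("depth and mask dimensions differ")
        if np.any((self.depth_mm > 0) & ~self.mask):
            raise MaskShapeError("masked depth contains pixels outside the mask")

    @property
    def valid_count(self) -> int:
        return int((self.depth_mm > 0).sum())


def _component_tiebreak(labels: np.ndarray, candidates: list[int]) -> int:
    """Keep-largest tie-break: equal sizes resolved by the smallest row-major
    index of a component's first pixel."""
    sizes = {c: int((labels == c).sum()) for c in candidates}
    best = max(sizes.values())
    tied = [c for c in candidates if sizes[c] == best]
    if len(tied) == 1:
        return tied[0]
    firsts = {c: int(np.flatnonzero(labels.ravel() == c)[0]) for c in tied}
    return min(tied, key=lambda c: firsts[c])


def segment_body(
    ir: np.ndarray,
    threshold_policy="otsu",
    seed_point: tuple[int, int] | None = None,
    grow_tolerance_frac: float = 0.25,
    view: str = "anterior",
    platform_ir_min: float = 235.0,
) -> BodyMask:
    """Detect the body silhouette in an IR frame.

    *threshold_policy* is ``"otsu"`` or a fixed intensity; pixels strictly
    above the threshold form the candidate foreground.  Region growth floods
    from *seed_point* (default: centroid of the candidate blob with the
    highest summed intensity, i.e. the body) with an intensity tolerance of
    ``grow_tolerance_frac * threshold``, which keeps one connected component
    and, in the default scene, already excludes the distinctly brighter
    platform.
    """
    ir = np.asarray(ir, dtype=float)
    if ir.size == 0:
        raise NoBodyFoundError("empty IR frame")
    if threshold_policy == "otsu":
        if np.ptp(ir) == 0:
            raise NoBodyFoundError("IR frame is constant; no body found")
        thr = float(threshold_otsu(ir))
    else:
        thr = float(threshold_policy)
    candidate = ir > thr
    if not candidate.any():
        raise NoBodyFoundError(f"no pixel above threshold {thr:.1f}")

    labels, n = ndimage.label(candidate, structure=np.ones((3, 3), dtype=int))
    if seed_point is None:
        # brightest body blob = largest summed intensity over body-reflectance
        # pixels (near-saturated platform paint does not count, so a large
        # platform band cannot out-vote a small body); the blob's
        # intensity-weighted centroid is snapped to its nearest body pixel
        body_like = ir * (ir < platform_ir_min)
        sums = ndimage.sum_labels(body_like, labels, index=np.arange(1, n + 1))
        if sums.max() <= 0:
            raise NoBodyFoundError("only platform-reflectance pixels above threshold")
        blob = int(np.argmax(sums)) + 1
        rr, cc = np.nonzero((labels == blob) & (body_like > 0))
        w = ir[rr, cc]
        r0 = float(np.average(rr, weights=w))
        c0 = float(np.average(cc, weights=w))
        k = int(np.argmin((rr - r0) ** 2 + (cc - c0) ** 2))
        seed_point = (int(rr[k]), int(cc[k]))
    else:
        seed_point = (int(seed_point[0]), int(seed_point[1]))
        if not candidate[seed_point]:
            raise BadSeedError(f"seed {seed_point} is outside the thresholded foreground")

    tol = grow_tolerance_frac * thr
    grown = flood(ir, seed_point, tolerance=tol, connectivity=2)
    mask = grown & candidate
    if not mask.any():
        raise NoBodyFoundError("region growth produced an empty mask")
    return BodyMask(mask, view=view)


def exclude_platform(
    body: BodyMask,
    depth_mm: np.ndarray,
    platform_rows: int | None = None,
    depth_offset_mm: float = 150.0,
    ir: np.ndarray | None = None,
    platform_ir_min: float = 235.0,
) -> BodyMask:
    """Remove the reflective-platform band from a body mask.

    The platform shows up as a mask region contiguous with the bottom-most
    mask rows that is either distinctly brighter than the body in the IR
    frame (the high-reflectance paint, when *ir* is supplied) or whose depth
    departs from the silhouette's median by more than *depth_offset_mm* (the
    platform stands proud of the leg surface).  Feet pixels share the legs'
    reflectance and depth and are kept.  When nothing matches the rule the
    mask is returned unchanged (logged at INFO).
    """
    mask = body.mask
    depth = np.asarray(depth_mm, dtype=float)
    if depth.shape != mask.shape:
        raise MaskShapeError("depth and mask dimensions differ")
    if not mask.any():
        log.info("exclude_platform: empty mask, nothing to do")
        return body
    rows = np.nonzero(mask.any(axis=1))[0]
    bottom = rows[-1]
    band_top = bottom - (platform_rows if platform_rows is not None else mask.shape[0])
    valid = mask & (depth > 0)
    if not valid.any():
        log.info("exclude_platform: no valid depth under the mask")
        return body
    med = float(np.median(depth[valid]))
    deviant = mask & (depth > 0) & (np.abs(depth - med) > depth_offset_mm)
    if ir is not None:
        if np.asarray(ir).shape != mask.shape:
            raise MaskShapeError("ir and mask dimensions differ")
        deviant |= mask & (np.asarray(ir, dtype=float) >= platform_ir_min)
    # platform candidates must be contiguous with the bottom rows of the mask
    labels, n = ndimage.label(deviant, structure=np.ones((3, 3), dtype=int))
    out = mask.copy()
    removed = 0
    for c in range(1, n + 1):
        comp = labels == c
        comp_rows = np.nonzero(comp.any(axis=1))[0]
        if comp_rows[-1] >= max(bottom - 2, band_top):
            out &= ~comp
            removed += int(comp.sum())
    if removed == 0:
        log.info("exclude_platform: no platform detected, mask unchanged")
        return body
    if not out.any():
        log.warning("exclude_platform: mask was platform-only; returning empty mask")
    return BodyMask(out, view=body.view)


def clean_mask(
    body: BodyMask,
    open_radius_px: int = 1,
    close_radius_px: int = 1,
    min_component_px: int = 64,
) -> BodyMask:
    """Morphological cleanup: opening then closing with disk structuring
    elements, small-component removal, and reduction to a single component
    (largest; ties broken by smallest row-major first-pixel index).

    With both radii 0 and no removable component this is the identity; the
    open–close filter is idempotent, so re-cleaning a cleaned mask is a
    no-op.  Raises :class:`EmptyMaskError` if nothing survives.
    """
    if open_radius_px < 0 or close_radius_px < 0:
        raise ValueError("radii must be >= 0")
    mask = body.mask
    if open_radius_px > 0:
        mask = morphology.opening(mask, morphology.disk(open_radius_px))
    if close_radius_px > 0:
        mask = morphology.closing(mask, morphology.disk(close_radius_px))
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise EmptyMaskError("cleaning removed every foreground pixel")
    keep = [
        c for c in range(1, n + 1) if int((labels == c).sum()) >= max(min_component_px, 1)
    ]
    if not keep:
        raise EmptyMaskError(
            f"all components smaller than min_component_px={min_component_px}"
        )
    winner = _component_tiebreak(labels, keep)
    return BodyMask(labels == winner, view=body.view)


def apply_mask(
    depth_mm: np.ndarray,
    body: BodyMask,
    near_mm: float = 500.0,
    far_mm: float = 4500.0,
) -> MaskedDepth:
    """Fuse a depth frame with a body mask into a masked depth image.

    Pixels outside the mask, invalid pixels (0) and pixels outside the
    ``[near, far]`` working range are zeroed.
    """
    depth = np.asarray(depth_mm)
    if depth.shape != body.mask.shape:
        raise MaskShapeError(
            f"depth {depth.shape} and mask {body.mask.shape} dimensions differ"
        )
    keep = body.mask & (depth >= near_mm) & (depth <= far_mm)
    out = np.where(keep, depth, 0)
    return MaskedDepth(out.astype(depth.dtype), body.mask, view=body.view)
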