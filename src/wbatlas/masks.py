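"""Binary masks and the registration regularisation weight map.

Pre-processing for whole-body registration: a body mask from thresholded
water+fat signal with standard morphology (optional arm removal), an
"inside SAT" mask that peels the boundary-connected subcutaneous fat shell
off the body, a physically-dilated body mask delimiting the registration
cost region, and a per-voxel regularisation weight map blended from WF/FF
content (stiff lean tissue, elastic adipose tissue).

The SAT peel is a deterministic rule-based segmentation: high-FF voxels
connected to the body boundary form the shell; high-FF islands deep inside
the body (visceral fat) are retained. An externally produced SAT mask can
be substituted wherever a MaskSet is consumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .volume import Volume

__all__ = [
    "MaskSet",
    "body_mask",
    "inside_sat_mask",
    "dilated_body_mask",
    "regularization_weight_map",
    "make_mask_set",
    "WeightMap",
]


@dataclass(frozen=True)
class MaskSet:
    """Nested binary masks: inside_sat <= body <= dilated_body."""

    body: Volume
    inside_sat: Volume
    dilated_body: Volume
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        b = np.asarray(self.body.values, dtype=bool)
        i = np.asarray(self.inside_sat.values, dtype=bool)
        d = np.asarray(self.dilated_body.values, dtype=bool)
        if (i & ~b).any() or (b & ~d).any():
            raise ValueError("mask nesting violated: inside_sat <= body <= dilated_body")


@dataclass(frozen=True)
class WeightMap:
    """Per-voxel regularisation weights in [w_fat, w_lean]."""

    weights: Volume
    w_lean: float
    w_fat: float


def _ball(radius_mm: float, spacing: tuple[float, float, float]) -> np.ndarray:
    """Digital ellipsoid structuring element of physical radius radius_mm."""
    r_vox = [int(np.floor(radius_mm / s)) for s in spacing]
    grids = np.meshgrid(
        *[np.arange(-r, r + 1) * s for r, s in zip(r_vox, spacing)], indexing="ij"
    )
    dist2 = sum(g**2 for g in grids)
    return dist2 <= radius_mm**2 + 1e-9


def body_mask(
    water: Volume,
    fat: Volume,
    threshold_policy: str | float = "otsu",
    *,
    closing_radius_mm: float = 5.0,
    arm_removal: bool = False,
    arm_slice_range: tuple[int, int] | None = None,
    arm_lateral_fraction: float = 0.40,
) -> Volume:
    """Segment the body from background on the W+F image.

    Thresholding (Otsu on non-zero voxels by default, or a fixed value, or
    ``'quantile:q'`` for a scale-invariant quantile threshold) is followed
    by morphological closing, slice-wise hole filling and retention of the
    largest connected component. When ``arm_removal`` is on, in-plane
    components whose centroid lies laterally outside ``arm_lateral_fraction``
    of the torso bounding-box half-width are removed in the given z range.
    """
    if not water.same_grid(fat):
        raise ValueError("water and fat must share one grid")
    total = np.asarray(water.values, dtype=float) + np.asarray(fat.values, dtype=float)
    nz = total[total > 0]
    if nz.size == 0:
        raise ValueError("empty foreground: W+F image is all zero")
    if threshold_policy == "otsu":
        if nz.min() == nz.max():
            thr = float(nz.min())
        else:
            # Otsu on log intensities: separates the noise floor from tissue
            # even when tissue classes span an order of magnitude (SAT vs brain)
            thr = float(np.expm1(threshold_otsu(np.log1p(nz))))
        thr *= 1.0 - 1e-9  # keep voxels sitting exactly at the threshold
    elif isinstance(threshold_policy, str) and threshold_policy.startswith("quantile:"):
        thr = float(np.quantile(nz, float(threshold_policy.split(":")[1])))
    else:
        thr = float(threshold_policy)
    fg = total >= thr  # inclusive: a single-valued foreground sits at its own threshold
    if not fg.any():
        raise ValueError("empty foreground after thresholding")

    st = _ball(closing_radius_mm, water.spacing)
    pad = [(s // 2, s // 2) for s in st.shape]  # avoid border clipping in the closing
    fg = np.pad(fg, pad)
    fg = ndimage.binary_closing(fg, structure=st)
    fg = fg[tuple(slice(p, n + p) for (p, _), n in zip(pad, total.shape))]
    # fill interior holes slice-wise (axial) then retain the largest component
    for k in range(fg.shape[2]):
        fg[:, :, k] = ndimage.binary_fill_holes(fg[:, :, k])
    labels, n = ndimage.label(fg)
    if n == 0:
        raise ValueError("empty foreground after morphology")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    mask = labels == keep

    if arm_removal:
        z0, z1 = arm_slice_range if arm_slice_range is not None else (0, mask.shape[2])
        for k in range(z0, z1):
            sl = mask[:, :, k]
            if not sl.any():
                continue
            xs = np.where(sl.any(axis=1))[0]
            cx = 0.5 * (xs.min() + xs.max())
            half_w = max(0.5 * (xs.max() - xs.min()), 1.0)
            lab2, m = ndimage.label(sl)
            if m <= 1:
                continue
            areas = ndimage.sum_labels(np.ones_like(lab2), lab2, index=np.arange(1, m + 1))
            main = int(np.argmax(areas)) + 1
            centroids = ndimage.center_of_mass(sl, lab2, index=np.arange(1, m + 1))
            for j, (cxx, _cyy) in enumerate(centroids, start=1):
                if j == main:
                    continue
                if abs(cxx - cx) > arm_lateral_fraction * half_w:
                    sl[lab2 == j] = False
            mask[:, :, k] = sl
    return water.with_values(mask.astype(np.uint8))


def inside_sat_mask(
    body: Volume,
    ff: Volume,
    slice_range: tuple[int, int] | None = None,
    *,
    ff_cut: float = 0.5,
) -> Volume:
    """Peel the boundary-connected subcutaneous fat shell off the body.

    Within ``slice_range`` (start inclusive, end exclusive; the whole
    volume when None) voxels with FF > ``ff_cut`` that are 26-connected to
    the body boundary are removed; high-FF islands with no path to the
    boundary (visceral fat) are kept. Outside the range the body mask is
    returned unchanged.
    """
    b = np.asarray(body.values, dtype=bool)
    f = np.asarray(ff.values, dtype=float)
    nz = b.shape[2]
    if slice_range is None:
        slice_range = (0, nz)
    z0, z1 = slice_range
    if not (0 <= z0 < z1 <= nz):
        raise ValueError(f"invalid slice_range {slice_range} for {nz} slices")
    if not b[:, :, z0:z1].any():
        raise ValueError("body mask empty within slice_range")

    boundary = b & ~ndimage.binary_erosion(b, structure=np.ones((3, 3, 3)))
    high_ff = b & (f > ff_cut)
    labels, n = ndimage.label(high_ff, structure=np.ones((3, 3, 3)))
    shell = np.zeros_like(b)
    if n:
        touches = np.unique(labels[boundary & (labels > 0)])
        shell = np.isin(labels, touches[touches > 0])
    out = b.copy()
    out[:, :, z0:z1] &= ~shell[:, :, z0:z1]
    return body.with_values(out.astype(np.uint8))


def dilated_body_mask(body: Volume, radius_mm: float) -> Volume:
    """Dilate the body mask by a ball of physical radius ``radius_mm``."""
    if radius_mm < 0:
        raise ValueError("radius_mm must be >= 0")
    b = np.asarray(body.values, dtype=bool)
    if radius_mm == 0:
        return body.with_values(b.astype(np.uint8))
    out = ndimage.binary_dilation(b, structure=_ball(radius_mm, body.spacing))
    return body.with_values(out.astype(np.uint8))


def regularization_weight_map(
    wf: Volume, ff: Volume, w_lean: float = 1.0, w_fat: float = 0.2
) -> WeightMap:
    """Blend per-voxel regularisation weights from water/fat content.

    weights = (w_fat*FF + w_lean*WF) / (WF+FF) where WF+FF > 0, else
    w_lean (background default). Lean tissue (high WF) is regularised
    harder than adipose tissue (high FF), which is allowed more
    inter-subject elasticity.
    """
    if w_lean < w_fat:
        raise ValueError("w_lean must be >= w_fat")
    if w_fat <= 0:
        raise ValueError("weights must be positive")
    w = np.asarray(wf.values, dtype=float)
    f = np.asarray(ff.values, dtype=float)
    if np.any(w + f > 1.0 + 1e-6):
        raise ValueError("WF + FF must not exceed 1")
    total = w + f
    with np.errstate(invalid="ignore", divide="ignore"):
        blended = np.where(
            total > 0,
            (w_fat * f + w_lean * w) / np.where(total > 0, total, 1.0),
            w_lean,
        )
    return WeightMap(weights=wf.with_values(blended), w_lean=float(w_lean), w_fat=float(w_fat))


def make_mask_set(
    water: Volume,
    fat: Volume,
    *,
    dilation_mm: float = 10.0,
    ff: Volume | None = None,
    slice_range: tuple[int, int] | None = None,
    **body_kwargs,
) -> MaskSet:
    """Convenience builder for the full pre-processing MaskSet."""
    from .dwi import compute_fractions

    body = body_mask(water, fat, **body_kwargs)
    if ff is None:
        _, ff = compute_fractions(water, fat)
    isat = inside_sat_mask(body, ff, slice_range)
    dil = dilated_body_mask(body, dilation_mm)
    return MaskSet(
        body=body,
        inside_sat=isat,
        dilated_body=dil,
        provenance={"dilation_mm": dilation_mm, **{k: str(v) for k, v in body_kwargs.items()}},
    )
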