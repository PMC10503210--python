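"""Atlas-based voxel-wise anomaly detection and lesion-wise evaluation.

A patient image (Gaussian-smoothed b=900 DWI or vcDWI) is compared with
the transported atlas mean/SD using a single-case (Crawford-Howell)
one-sided t-test per voxel: t = (x - mean) / (sd * sqrt((n+1)/n)) with
df = n - 1, which degenerates to the classical z-score for large atlas
size n. Hard-coded rules turn the p-map into a lesion-candidate mask:
(i) threshold p < 0.001, (ii) morphological opening to remove small
clusters, (iii) removal of clusters whose maximum normalised intensity
falls below the 95th within-body percentile, plus an optional removal of
adipose voxels (FF > 50%). Candidate masks are reduced to lesions by
connected-components analysis with a > 0.5 ml size threshold, matched
against the reference segmentation by a Dice > 0.01% criterion, and
summarised as TP/FP/FN, sensitivity, precision, foreground Dice and
total diffusion volume (tDV).

The downstream consumer of the prepared channels (a 3D segmentation
network) is out of scope; this module's contract ends at normalised
channel stacks in [0, 1] and the lesion-wise metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy import stats as sps

from .volume import Volume

__all__ = [
    "TMapResult",
    "AnomalyMask",
    "Lesion",
    "LesionSet",
    "MatchSummary",
    "smooth",
    "compute_tmap",
    "rule_filter",
    "scale_channel",
    "extract_lesions",
    "match_lesions",
    "summary_from_counts",
]


@dataclass(frozen=True)
class TMapResult:
    """Voxel-wise single-case t-scores and one-sided p-values."""

    t_map: Volume
    p_map: Volume  # one-sided, upper tail (x > atlas mean)
    df: int
    channel: str = "b900"
    defined_mask: Volume | None = None  # 0 where atlas sd = 0


@dataclass(frozen=True)
class AnomalyMask:
    """Rule-filtered candidate mask with per-rule removal accounting."""

    mask: Volume
    rule_trace: dict[str, int]


@dataclass(frozen=True)
class Lesion:
    label: int
    volume_ml: float
    n_voxels: int
    status: str = "unmatched"  # TP / FP / FN / unmatched
    dice: float | None = None


@dataclass(frozen=True)
class MatchSummary:
    tp: int
    fp: int
    fn: int
    sensitivity: float | None
    precision: float | None
    foreground_dice: float
    tdv_ml: float


@dataclass(frozen=True)
class LesionSet:
    """Labelled connected components above the minimum lesion volume."""

    labels: Volume  # integer labels, 0 = background
    lesions: list[Lesion] = field(default_factory=list)
    summary: MatchSummary | None = None

    @property
    def foreground(self) -> np.ndarray:
        return np.asarray(self.labels.values) > 0

    @property
    def tdv_ml(self) -> float:
        return sum(l.volume_ml for l in self.lesions)


def smooth(volume: Volume, sigma_mm: float = 1.7) -> Volume:
    """Gaussian smoothing with a physical sigma (converted per axis)."""
    if sigma_mm < 0:
        raise ValueError("sigma_mm must be >= 0")
    if sigma_mm == 0:
        return volume
    sig = [sigma_mm / s for s in volume.spacing]
    return volume.with_values(
        ndimage.gaussian_filter(np.asarray(volume.values, dtype=float), sig, mode="nearest")
    )


def compute_tmap(
    patient: Volume,
    atlas_mean: Volume,
    atlas_sd: Volume,
    n: int,
    channel: str = "b900",
) -> TMapResult:
    """Single-case one-sided t-test of a patient image against the atlas.

    t = (x - mean) / (sd * sqrt((n+1)/n)), df = n - 1; the one-sided
    p-value covers the x > mean tail. Voxels with sd = 0 are flagged
    undefined (t and p set to NaN).
    """
    if n < 2:
        raise ValueError("atlas must have n >= 2 components")
    if not (patient.same_grid(atlas_mean) and patient.same_grid(atlas_sd)):
        raise ValueError("patient and atlas volumes must share one grid")
    x = np.asarray(patient.values, dtype=float)
    mu = np.asarray(atlas_mean.values, dtype=float)
    sd = np.asarray(atlas_sd.values, dtype=float)
    defined = sd > 0
    scale = np.sqrt((n + 1.0) / n)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(defined, (x - mu) / (np.where(defined, sd, 1.0) * scale), np.nan)
    df = n - 1
    p = np.where(defined, sps.t.sf(np.where(defined, t, 0.0), df), np.nan)
    return TMapResult(
        t_map=patient.with_values(t),
        p_map=patient.with_values(p),
        df=df,
        channel=channel,
        defined_mask=patient.with_values(defined.astype(np.uint8)),
    )


def _ball_vox(radius: int) -> np.ndarray:
    r = int(radius)
    g = np.meshgrid(*[np.arange(-r, r + 1)] * 3, indexing="ij")
    return sum(x**2 for x in g) <= r**2 + 1e-9


def rule_filter(
    p_map: Volume,
    intensity: Volume,
    body_mask: Volume,
    ff: Volume | None = None,
    *,
    p_threshold: float = 1e-3,
    opening_radius_vox: int = 1,
    intensity_percentile: float = 95.0,
    ff_cut: float = 0.5,
    remove_fat: bool = False,
    connectivity: int = 26,
) -> AnomalyMask:
    """Sequential hard-coded rules turning a p-map into a candidate mask.

    (i) keep in-body voxels with p < ``p_threshold``; (ii) morphological
    opening with a ball of ``opening_radius_vox`` voxels removes small
    clusters; (iii) remove clusters whose maximum normalised intensity is
    below the ``intensity_percentile``-th percentile of in-body
    intensities; optionally remove adipose voxels (FF > ``ff_cut``).
    Every removal is accounted voxel-wise in ``rule_trace``.
    """
    body = np.asarray(body_mask.values, dtype=bool)
    if not body.any():
        raise ValueError("empty body mask")
    p = np.asarray(p_map.values, dtype=float)
    inten = np.asarray(intensity.values, dtype=float)

    m1 = body & (np.nan_to_num(p, nan=1.0) < p_threshold)
    trace = {"initial": int(m1.sum())}

    if opening_radius_vox > 0:
        m2 = ndimage.binary_opening(m1, structure=_ball_vox(opening_radius_vox))
    else:
        m2 = m1
    trace["opening_removed"] = int(m1.sum() - m2.sum())

    structure = np.ones((3, 3, 3)) if connectivity == 26 else None
    labels, nlab = ndimage.label(m2, structure=structure)
    cutoff = np.percentile(inten[body], intensity_percentile)
    m3 = m2.copy()
    removed = 0
    for lab in range(1, nlab + 1):
        sel = labels == lab
        if inten[sel].max() < cutoff:
            m3[sel] = False
            removed += int(sel.sum())
    trace["low_intensity_removed"] = removed

    m4 = m3
    if remove_fat:
        if ff is None:
            raise ValueError("remove_fat requires an FF volume")
        fat = np.asarray(ff.values, dtype=float) > ff_cut
        m4 = m3 & ~fat
        trace["fat_removed"] = int(m3.sum() - m4.sum())
    trace["final"] = int(m4.sum())
    return AnomalyMask(mask=body_mask.with_values(m4.astype(np.uint8)), rule_trace=trace)


def scale_channel(volume: Volume, source_range: tuple[float, float]) -> Volume:
    """Linear map of ``source_range`` to [0, 1] with clipping outside it."""
    lo, hi = source_range
    if hi <= lo:
        raise ValueError("degenerate source range")
    vals = (np.asarray(volume.values, dtype=float) - lo) / (hi - lo)
    return volume.with_values(np.clip(vals, 0.0, 1.0))


def extract_lesions(
    mask: Volume, min_volume_ml: float = 0.5, connectivity: int = 26
) -> LesionSet:
    """Connected components strictly larger than ``min_volume_ml``.

    26-connectivity by default (corner-touching voxels join clusters);
    pass ``connectivity=6`` for the face-connected convention.
    """
    m = np.asarray(mask.values, dtype=bool)
    structure = np.ones((3, 3, 3)) if connectivity == 26 else None
    labels, nlab = ndimage.label(m, structure=structure)
    vox_ml = mask.voxel_volume_ml
    out = np.zeros_like(labels)
    lesions = []
    next_id = 0
    for lab in range(1, nlab + 1):
        sel = labels == lab
        nvox = int(sel.sum())
        vol_ml = nvox * vox_ml
        if vol_ml > min_volume_ml:
            next_id += 1
            out[sel] = next_id
            lesions.append(Lesion(label=next_id, volume_ml=vol_ml, n_voxels=nvox))
    return LesionSet(labels=mask.with_values(out), lesions=lesions)


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    s = a.sum() + b.sum()
    return 2.0 * float(np.sum(a & b)) / float(s) if s else 0.0


def summary_from_counts(
    tp: int, fp: int, fn: int, foreground_dice: float = float("nan"), tdv_ml: float = float("nan")
) -> MatchSummary:
    """Lesion-wise summary metrics from raw TP/FP/FN counts.

    sensitivity = TP / (TP + FN); precision = TP / (TP + FP); either is
    None when its denominator is zero.
    """
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    prec = tp / (tp + fp) if (tp + fp) > 0 else None
    return MatchSummary(
        tp=int(tp),
        fp=int(fp),
        fn=int(fn),
        sensitivity=sens,
        precision=prec,
        foreground_dice=foreground_dice,
        tdv_ml=tdv_ml,
    )


def match_lesions(
    predicted: LesionSet, reference: LesionSet, tp_dice_min: float = 1e-4
) -> LesionSet:
    """Match predicted lesions against the reference segmentation.

    A predicted lesion is a TP when its Dice against the reference
    foreground exceeds ``tp_dice_min`` (default 10^-4, i.e. 0.01% on the
    percentage scale), otherwise an FP. Reference lesions whose Dice
    against the predicted foreground does not exceed the threshold are
    FNs. The summary carries sensitivity TP/(TP+FN), precision
    TP/(TP+FP), whole-mask foreground Dice and predicted tDV.
    """
    if predicted.labels.shape != reference.labels.shape:
        raise ValueError("predicted and reference masks must share one grid")
    pred_lab = np.asarray(predicted.labels.values)
    ref_lab = np.asarray(reference.labels.values)
    pred_fg = pred_lab > 0
    ref_fg = ref_lab > 0

    matched = []
    tp = fp = 0
    for les in predicted.lesions:
        sel = pred_lab == les.label
        d = _dice(sel, ref_fg)
        status = "TP" if d > tp_dice_min else "FP"
        tp += status == "TP"
        fp += status == "FP"
        matched.append(Lesion(les.label, les.volume_ml, les.n_voxels, status, d))
    fn = 0
    for les in reference.lesions:
        sel = ref_lab == les.label
        if _dice(sel, pred_fg) <= tp_dice_min:
            fn += 1
    summary = summary_from_counts(
        tp, fp, fn, foreground_dice=_dice(pred_fg, ref_fg), tdv_ml=predicted.tdv_ml
    )
    return LesionSet(labels=predicted.labels, lesions=matched, summary=summary)
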