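"""T1w/T2w ratio maps and equivolumetric depth profiles.

The T1w/T2w ratio is computed by voxelwise division of co-registered T1w
and T2w volumes; dividing cancels the receive-coil sensitivity profile and
doubles the myelin-related contrast (which is inverted between the two
images).  Ratio units are arbitrary, so per-subject maps are calibrated by
a two-point affine map anchored on a low-intensity reference structure
(ventricles) and a high-intensity one (corpus callosum in humans, pons in
macaques), pulling each subject's reference means onto the group means.

Cortical depth is handled under the equi-volume principle: depth surfaces
are placed so each of the K compartments between the white and pial
surfaces holds the same tissue volume, compensating cortical curvature.
For a column whose cross-sectional area varies linearly from the white
area ``A_w`` to the pial area ``A_p``, the depth fraction rho at cumulative
volume fraction alpha has the closed form

    rho(alpha) = (-A_w + sqrt((1 - alpha) A_w^2 + alpha A_p^2)) / (A_p - A_w)

(with rho = alpha when A_p = A_w).  Bin 1 is the deepest bin (adjacent to
white matter) throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import PhantomRibbon

T2W_FLOOR = 1e-6  # guard against division blow-up, native units


@dataclass
class RatioVolume:
    values: np.ndarray
    mask: np.ndarray
    voxel_size: float = 1.0
    space_tag: str = "template"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")


@dataclass
class CalibrationRefs:
    """Subject and group mean ratios in the two reference structures."""

    subject_low_mean: float
    subject_high_mean: float
    group_low_mean: float
    group_high_mean: float
    ref_low_label: str = "ventricles"
    ref_high_label: str = "corpus_callosum"

    def __post_init__(self) -> None:
        if self.subject_high_mean == self.subject_low_mean:
            raise ValueError("degenerate refs: subject reference means are equal")
        if not self.group_high_mean > self.group_low_mean:
            raise ValueError("group_high_mean must exceed group_low_mean")


def compute_ratio(t1w, t2w, mask, t2w_floor: float = T2W_FLOOR, **kw) -> RatioVolume:
    """Voxelwise T1w / T2w inside ``mask``.

    Any in-mask T2w voxel at or below ``t2w_floor`` is an error (the count
    of offending voxels is reported); outside the mask values are NaN.
    """
    t1w = np.asarray(t1w, dtype=float)
    t2w = np.asarray(t2w, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not (t1w.shape == t2w.shape == mask.shape):
        raise ValueError("t1w, t2w and mask grids do not match")
    bad = int(np.count_nonzero(mask & (t2w <= t2w_floor)))
    if bad:
        raise ValueError(f"{bad} in-mask T2w voxels at or below the floor {t2w_floor}")
    values = np.full(t1w.shape, np.nan)
    values[mask] = t1w[mask] / t2w[mask]
    return RatioVolume(values=values, mask=mask, **kw)


def calibrate_ratio(ratio: RatioVolume, refs: CalibrationRefs) -> RatioVolume:
    """Two-point affine calibration onto the group reference means.

    Maps the subject's own low/high reference means exactly onto the group
    low/high means: ``f(x) = a x + b`` with
    ``a = (group_high - group_low) / (subject_high - subject_low)``.
    Pure per-voxel map, hence order-preserving (for a > 0) and permutation
    equivariant.
    """
    a = (refs.group_high_mean - refs.group_low_mean) / (
        refs.subject_high_mean - refs.subject_low_mean
    )
    b = refs.group_low_mean - a * refs.subject_low_mean
    values = np.where(ratio.mask, a * ratio.values + b, np.nan)
    return RatioVolume(values, ratio.mask.copy(), ratio.voxel_size, ratio.space_tag)


# ---------------------------------------------------------------------------
# equivolume depth


@dataclass
class EquivolumeColumn:
    """Cortical column with linearly varying cross-sectional area."""

    A_w: float  # inner (white) bounding area, mm^2
    A_p: float  # outer (pial) bounding area, mm^2
    K: int = 6

    def __post_init__(self) -> None:
        if self.A_w <= 0 or self.A_p <= 0:
            raise ValueError("bounding areas must be > 0")
        if self.K < 1:
            raise ValueError("K must be >= 1")


def equivolume_rho(column: EquivolumeColumn, alpha):
    """Depth fraction rho at cumulative volume fraction alpha (closed form).

    The sub-column below rho contains exactly the fraction alpha of the
    column volume; rho(0) = 0, rho(1) = 1, strictly increasing.
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any((alpha < 0) | (alpha > 1)):
        raise ValueError("alpha must lie in [0, 1]")
    aw, ap = column.A_w, column.A_p
    if aw == ap:
        return alpha + 0.0
    rho = (-aw + np.sqrt((1.0 - alpha) * aw**2 + alpha * ap**2)) / (ap - aw)
    return rho


def equivolume_alpha(column: EquivolumeColumn, rho):
    """Cumulative volume fraction alpha at geometric depth fraction rho
    (inverse of :func:`equivolume_rho`)."""
    rho = np.asarray(rho, dtype=float)
    if np.any((rho < 0) | (rho > 1)):
        raise ValueError("rho must lie in [0, 1]")
    aw, ap = column.A_w, column.A_p
    if aw == ap:
        return rho + 0.0
    return ((aw + rho * (ap - aw)) ** 2 - aw**2) / (ap**2 - aw**2)


def assign_depth_bins(ribbon_or_alpha, K: int, column: EquivolumeColumn | None = None):
    """Label every ribbon voxel with its equivolume depth bin 1..K.

    Accepts either a :class:`~myelindev.synthetic.PhantomRibbon` (whose
    exact volume-fraction coordinate is known analytically) or a volume of
    geometric depth fractions rho in [0, 1] (NaN outside the ribbon), which
    is converted to volume fractions through ``column`` (identity when no
    column is given, i.e. a flat slab).  Voxel gets bin ``k`` iff its alpha
    lies in ``[(k-1)/K, k/K)`` (alpha = 1 goes to bin K); 0 marks
    background.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if isinstance(ribbon_or_alpha, PhantomRibbon):
        alpha = ribbon_or_alpha.alpha_volume()
    else:
        rho = np.asarray(ribbon_or_alpha, dtype=float)
        inside = ~np.isnan(rho)
        if np.any((rho[inside] < 0) | (rho[inside] > 1)):
            raise ValueError("depth coordinate must lie in [0, 1] inside the ribbon")
        if column is None:
            alpha = rho
        else:
            alpha = np.where(inside, 0.0, np.nan)
            alpha[inside] = equivolume_alpha(column, rho[inside])
    bins = np.zeros(alpha.shape, dtype=np.int32)
    inside = ~np.isnan(alpha)
    k = np.floor(alpha[inside] * K).astype(np.int32) + 1
    bins[inside] = np.clip(k, 1, K)
    return bins


def extract_depth_profiles(
    ratio: RatioVolume,
    bins: np.ndarray,
    parcels: np.ndarray,
    subject_id: str = "sub0000",
    trim_extremes: bool = False,
) -> pd.DataFrame:
    """Mean in-mask ratio per (parcel, depth bin).

    With ``trim_extremes`` the first and last bins are removed before
    output (the standard guard against partial-volume contamination from
    white matter and CSF: a 7-bin segmentation yields 5 analysis bins,
    which keep their original labels 2..K-1).  Empty cells are *reported*
    as rows with ``n_voxels = 0`` and NaN mean, never silently dropped.
    """
    bins = np.asarray(bins)
    parcels = np.asarray(parcels)
    if not (ratio.values.shape == bins.shape == parcels.shape):
        raise ValueError("ratio, bins and parcel grids do not match")
    K = int(bins.max()) if bins.size else 0
    sel = ratio.mask & (bins > 0)
    df = pd.DataFrame(
        {
            "parcel": parcels[sel],
            "depth_bin": bins[sel],
            "ratio": ratio.values[sel],
        }
    )
    grouped = df.groupby(["parcel", "depth_bin"])["ratio"].agg(["mean", "size"])
    parcel_ids = np.unique(parcels[sel])
    full = pd.MultiIndex.from_product([parcel_ids, np.arange(1, K + 1)], names=["parcel", "depth_bin"])
    grouped = grouped.reindex(full)
    out = grouped.reset_index().rename(columns={"mean": "mean_ratio", "size": "n_voxels"})
    out["n_voxels"] = out["n_voxels"].fillna(0).astype(int)
    out.insert(0, "subject_id", subject_id)
    if trim_extremes:
        out = out[(out["depth_bin"] > 1) & (out["depth_bin"] < K)].reset_index(drop=True)
    return out
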