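"""Registration-accuracy metrics.

Dice coefficient, directional and generalized Hausdorff distance (over voxel
centres, in world mm, anisotropic spacing honoured), kappa-style agreement
bins, and region volume / body extent measurement.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import LabelVolume

__all__ = [
    "dice",
    "hausdorff_directional",
    "hausdorff",
    "agreement_category",
    "region_volume",
    "body_extent",
    "overlap_report",
]


def dice(source: np.ndarray, target: np.ndarray) -> float:
    """Dice overlap 2|S∩T| / (|S|+|T|) of two boolean masks on one grid.

    Returns NaN (with a warning) when both masks are empty.
    """
    s = np.asarray(source, dtype=bool)
    t = np.asarray(target, dtype=bool)
    ns, nt = int(s.sum()), int(t.sum())
    if ns + nt == 0:
        warnings.warn("Dice undefined: both regions empty", stacklevel=2)
        return float("nan")
    return 2.0 * int(np.logical_and(s, t).sum()) / (ns + nt)


def _check_nonempty(s, t):
    if not s.any() or not t.any():
        warnings.warn("Hausdorff undefined for an empty region", stacklevel=3)
        return False
    return True


def hausdorff_directional(source, target, spacing=(1.0, 1.0, 1.0)) -> float:
    """Directed Hausdorff HD_{S->T} = max over s of min over t of d(s, t), mm.

    Distances are Euclidean between voxel centres of the two masks; computed
    exactly via the Euclidean distance transform of the target (anisotropic
    ``spacing`` as the per-axis sampling).
    """
    s = np.asarray(source, dtype=bool)
    t = np.asarray(target, dtype=bool)
    if not _check_nonempty(s, t):
        return float("nan")
    # EDT of ~t gives, at each voxel centre, the distance to the nearest
    # target voxel centre — exact for point sets at voxel centres.
    dist_to_t = ndimage.distance_transform_edt(~t, sampling=spacing)
    return float(dist_to_t[s].max())


def hausdorff(source, target, spacing=(1.0, 1.0, 1.0)) -> float:
    """Generalized (symmetric) Hausdorff: max(HD_{S->T}, HD_{T->S}), mm."""
    a = hausdorff_directional(source, target, spacing)
    b = hausdorff_directional(target, source, spacing)
    return float(max(a, b))


_BINS = [
    (0.20, "poor"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "good"),
    (1.00 + 1e-12, "excellent"),
]


def agreement_category(d: float) -> str:
    """Kappa-style agreement bin for a Dice value.

    <0.20 poor, 0.20–0.40 fair, 0.40–0.60 moderate, 0.60–0.80 good,
    0.80–1.00 excellent; a boundary value falls in the upper bin (0.20 is
    "fair").
    """
    if not 0.0 <= d <= 1.0:
        raise ValueError(f"Dice value out of range [0, 1]: {d}")
    for hi, name in _BINS:
        if d < hi:
            return name
    return "excellent"


def region_volume(labels: LabelVolume, region) -> float:
    """Region volume in ml: voxel count x voxel volume (mm^3) / 1000."""
    mask = labels.mask(region)
    return float(mask.sum()) * labels.voxel_volume_mm3 / 1000.0


def body_extent(labels: LabelVolume, axis: int) -> float:
    """Object extent along ``axis`` in mm: number of slices containing any
    nonzero label times the slice spacing."""
    nz = labels.data != 0
    if not nz.any():
        raise ValueError("label volume is empty")
    other = tuple(a for a in range(3) if a != axis)
    n_slices = int(nz.any(axis=other).sum())
    return n_slices * labels.spacing[axis]


def overlap_report(source: LabelVolume, target: LabelVolume) -> pd.DataFrame:
    """Per-region Dice/Hausdorff report between two label maps on one grid.

    One row per region ID present in either region table; regions empty on
    either side carry NaN metrics.  Trailing ``mean``/``sd`` rows summarize
    the per-region values (NaN-aware).
    """
    if not source.same_grid(target):
        raise ValueError("source and target label volumes must share a grid")
    ids = sorted(set(source.region_table) | set(target.region_table))
    if not ids:
        raise ValueError("no regions to compare")
    rows = []
    for rid in ids:
        name = source.region_table.get(rid, target.region_table.get(rid, f"region_{rid}"))
        s = source.data == rid
        t = target.data == rid
        if not s.any() or not t.any():
            rows.append({"region": name, "dice": np.nan, "hd_st_mm": np.nan,
                         "hd_ts_mm": np.nan, "hd_mm": np.nan, "agreement": "missing"})
            continue
        d = dice(s, t)
        h_st = hausdorff_directional(s, t, source.spacing)
        h_ts = hausdorff_directional(t, s, source.spacing)
        rows.append({
            "region": name, "dice": d, "hd_st_mm": h_st, "hd_ts_mm": h_ts,
            "hd_mm": max(h_st, h_ts), "agreement": agreement_category(d),
        })
    df = pd.DataFrame(rows)
    numeric = ["dice", "hd_st_mm", "hd_ts_mm", "hd_mm"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mean_row = {"region": "mean", "agreement": ""}
        sd_row = {"region": "sd", "agreement": ""}
        for col in numeric:
            mean_row[col] = float(np.nanmean(df[col])) if df[col].notna().any() else np.nan
            sd_row[col] = float(np.nanstd(df[col], ddof=1)) if df[col].notna().sum() > 1 else np.nan
    return pd.concat([df, pd.DataFrame([mean_row, sd_row])], ignore_index=True)
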