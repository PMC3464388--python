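"""Automated PET activity quantification in atlas-defined VOIs.

The normalized mean activity (NMA) of a region is its mean PET value divided
by a maximum activity concentration; by default the maximum is taken over all
labelled (body) voxels, which keeps the measure dose-independent while
excluding background noise spikes.  The reference NMA comes from the subject's
own PET and segmentation before transformation; the automated NMA from the
transformed PET sampled through the atlas segmentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .volumes import ImageVolume, LabelVolume

__all__ = [
    "nma",
    "relative_error",
    "quantify_study",
    "hnma_regression",
    "NMARecord",
    "RegressionSummary",
]


@dataclass
class NMARecord:
    region: str
    nma_reference: float
    nma_automated: float
    relative_error_pct: float


@dataclass
class RegressionSummary:
    slope: float
    intercept: float
    r_squared: float
    n: int


def _body_max(pet: ImageVolume, labels: LabelVolume, scope: str) -> float:
    if scope == "body":
        body = labels.data != 0
        if not body.any():
            raise ValueError("label volume has no foreground voxels")
        return float(pet.data[body].max())
    if scope == "image":
        return float(pet.data.max())
    raise ValueError(f"unknown normalization scope {scope!r}")


def nma(pet: ImageVolume, labels: LabelVolume, region, scope: str = "body") -> float:
    """Normalized mean activity: mean over the region / max over the body.

    ``scope`` selects the normalization denominator: ``"body"`` (default, max
    over all nonzero-label voxels) or ``"image"`` (global maximum).
    Returns NaN with a warning for an empty region.
    """
    if not pet.same_grid(labels):
        raise ValueError("PET and label volumes must share a grid")
    mask = labels.mask(region)
    denom = _body_max(pet, labels, scope)
    if denom <= 0:
        raise ValueError("maximum activity is non-positive; cannot normalize")
    if not mask.any():
        warnings.warn(f"region {region!r} is empty; NMA undefined", stacklevel=2)
        return float("nan")
    return float(pet.data[mask].mean()) / denom


def relative_error(nma_ref: float, nma_auto: float) -> float:
    """Signed relative error in %: 100 (auto - ref) / ref; negative means
    underestimation by the automated measurement."""
    if not np.isfinite(nma_ref) or nma_ref == 0:
        warnings.warn("reference NMA is zero/undefined; relative error undefined",
                      stacklevel=2)
        return float("nan")
    return 100.0 * (nma_auto - nma_ref) / nma_ref


def quantify_study(pet_reference: ImageVolume, labels_reference: LabelVolume,
                   pet_transformed: ImageVolume, atlas_labels: LabelVolume,
                   scope: str = "body") -> list[NMARecord]:
    """Per-region NMA comparison: reference (subject space) vs automated
    (atlas space), with signed relative error in %.

    Regions present in only one segmentation, or empty on either side, are
    reported with NaN entries rather than zeros.
    """
    if not pet_reference.same_grid(labels_reference):
        raise ValueError("reference PET and labels must share a grid")
    if not pet_transformed.same_grid(atlas_labels):
        raise ValueError("transformed PET and atlas labels must share a grid")
    ref_names = set(labels_reference.region_table.values())
    atlas_names = set(atlas_labels.region_table.values())
    shared = sorted(ref_names & atlas_names)
    if not shared:
        raise ValueError("no overlapping regions between segmentations")
    records = []
    for region in shared:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = nma(pet_reference, labels_reference, region, scope)
            a = nma(pet_transformed, atlas_labels, region, scope)
            err = relative_error(r, a) if np.isfinite(r) and np.isfinite(a) else float("nan")
        records.append(NMARecord(region, r, a, err))
    return records


def hnma_regression(truth: dict, estimated: dict) -> RegressionSummary:
    """OLS of estimated activity on ground-truth ("harvested") activity.

    ``truth`` and ``estimated`` map region name -> activity concentration;
    regression uses the regions present in both (>= 3 required).  R^2 is the
    squared Pearson correlation of the paired values.
    """
    shared = sorted(set(truth) & set(estimated))
    x = np.array([truth[r] for r in shared], dtype=float)
    y = np.array([estimated[r] for r in shared], dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError(f"need >= 3 shared regions for regression, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in ground-truth activities")
    fit = stats.linregress(x, y)
    return RegressionSummary(float(fit.slope), float(fit.intercept),
                             float(fit.rvalue) ** 2, int(x.size))
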