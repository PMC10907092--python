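"""Regional SUVR extraction, similarity metrics and ROC analyses.

The evaluation layout works on regional values rather than raw voxels: for
each scan the median uptake within every atlas ROI is extracted, the
meta-ROI value is the arithmetic mean of its member-ROI medians, and
ground-truth vs synthesized volumes are compared per ROI across scans with
Pearson's r and the mean absolute percentage error (MAPE). Voxel-level
agreement is summarized by an RMSE map over scans and by the multi-scale
structural similarity index (MS-SSIM).

Tau positivity dichotomizes the meta-ROI SUVR at the published cut-offs
1.11, 1.21, 1.33 and 1.46 (strictly greater than the cut-off counts as
positive); ROC/AUROC analyses cover both positivity and diagnostic-group
contrasts (e.g. CU vs AD-spectrum) using the meta-ROI value of any
predictor volume as the score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .volio import ROIAtlas, Volume, check_aligned

__all__ = [
    "TAU_CUTOFFS",
    "META_COLUMN",
    "ROCResult",
    "extract_regional_suvr",
    "regional_suvr_table",
    "mape",
    "pearson_r",
    "rmse_map",
    "ms_ssim",
    "max_ms_ssim_scales",
    "positivity_labels",
    "roc_auc",
    "group_classification",
]

#: published meta-ROI tau-positivity cut-offs (SUVR units)
TAU_CUTOFFS = (1.11, 1.21, 1.33, 1.46)
META_COLUMN = "meta_roi"

#: diagnostic-group shorthand: "CU" covers both amyloid strata
GROUP_EXPANSIONS = {"CU": frozenset({"CU-", "CU+"})}

#: canonical five-scale MS-SSIM exponents, renormalized over the scales used
_MSSSIM_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)


def extract_regional_suvr(volume: Volume, atlas: ROIAtlas) -> pd.Series:
    """Median uptake per ROI plus the meta-ROI mean-of-medians.

    Returns a Series indexed by ROI label with a final ``meta_roi`` entry.
    """
    check_aligned(volume, atlas)
    medians: dict[int | str, float] = {}
    for lab in atlas.roi_labels:
        vox = volume.values[atlas.mask(lab)]
        if vox.size == 0:
            raise ValueError(f"ROI label {lab} is empty")
        medians[lab] = float(np.median(vox))
    missing = atlas.meta_members - set(atlas.roi_labels)
    if missing:
        raise ValueError(f"meta-ROI members absent from atlas: {sorted(missing)}")
    medians[META_COLUMN] = float(
        np.mean([medians[m] for m in sorted(atlas.meta_members)])
    )
    return pd.Series(medians)


def regional_suvr_table(volumes: dict[str, Volume], atlas: ROIAtlas) -> pd.DataFrame:
    """Scans x ROIs table of median uptake (rows indexed by scan id)."""
    rows = {sid: extract_regional_suvr(v, atlas) for sid, v in volumes.items()}
    return pd.DataFrame(rows).T.rename_axis("scan_id")


def mape(pred, truth) -> float:
    """Mean absolute percentage error, 100 * mean(|pred - truth| / truth)."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.size == 0:
        raise ValueError("pred and truth must be equal-length non-empty vectors")
    if (truth <= 0).any():
        raise ValueError("MAPE requires strictly positive truth values")
    return float(100.0 * np.mean(np.abs(pred - truth) / truth))


def pearson_r(x, y) -> float:
    """Product-moment correlation; requires length >= 3 and nonzero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors of at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input; correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def rmse_map(preds: list[Volume], truths: list[Volume]) -> Volume:
    """Per-voxel sqrt(mean over scans of squared error)."""
    if len(preds) != len(truths) or not preds:
        raise ValueError("need >= 1 prediction/truth pair, equal counts")
    shape = preds[0].shape
    acc = np.zeros(shape, dtype=np.float64)
    for p, t in zip(preds, truths):
        if p.shape != shape or t.shape != shape:
            raise ValueError(f"misaligned pair: {p.shape} / {t.shape} vs {shape}")
        acc += (p.values.astype(np.float64) - t.values) ** 2
    return Volume(values=np.sqrt(acc / len(preds)), voxel_size=preds[0].voxel_size,
                  space=preds[0].space)


def _ssim_components(a: np.ndarray, b: np.ndarray, window: int, data_range: float):
    """Mean SSIM and mean contrast-structure term over valid windows.

    Uniform filter window, sample covariance, K1=0.01 / K2=0.03 — the
    conventional parameterization for volumetric comparisons.
    """
    a = a.astype(np.float64)
    b = b.astype(np.float64)
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    npix = window ** a.ndim
    cov_norm = npix / (npix - 1)
    f = lambda v: ndimage.uniform_filter(v, size=window)
    ua, ub = f(a), f(b)
    vaa = cov_norm * (f(a * a) - ua * ua)
    vbb = cov_norm * (f(b * b) - ub * ub)
    vab = cov_norm * (f(a * b) - ua * ub)
    lum = (2 * ua * ub + c1) / (ua**2 + ub**2 + c1)
    cs = (2 * vab + c2) / (vaa + vbb + c2)
    pad = (window - 1) // 2
    core = tuple(slice(pad, s - pad) for s in a.shape)
    return float((lum * cs)[core].mean()), float(cs[core].mean())


def _downsample2(v: np.ndarray) -> np.ndarray:
    """2x average pooling; trailing odd voxels are dropped."""
    s = [(d // 2) * 2 for d in v.shape]
    v = v[: s[0], : s[1], : s[2]]
    return v.reshape(s[0] // 2, 2, s[1] // 2, 2, s[2] // 2, 2).mean(axis=(1, 3, 5))


def max_ms_ssim_scales(shape, window: int = 7) -> int:
    """Largest scale count M with min(side) / 2**(M-1) >= window."""
    m = 1
    while min(shape) / 2**m >= window:
        m += 1
    return m


def ms_ssim(a: Volume, b: Volume, scales: int | None = None, window: int = 7,
            data_range: float | None = None) -> float:
    """Multi-scale SSIM between two aligned volumes.

    Contrast-structure terms from the coarser scales multiply the full
    SSIM of the finest retained scale, each raised to the conventional
    exponent (renormalized over the scales actually used, which are
    auto-reduced for small volumes). Negative factors — possible only for
    anticorrelated inputs — clamp the result to 0, keeping the index in
    [0, 1] for non-negative images. ``scales=1`` reduces to plain SSIM.
    """
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    feasible = max_ms_ssim_scales(a.shape, window)
    if scales is None:
        scales = min(5, feasible)
    if scales < 1 or scales > feasible:
        raise ValueError(
            f"{scales} scales do not fit shape {a.shape} with window {window}; "
            f"maximum feasible is {feasible}"
        )
    if data_range is None:
        lo = min(a.values.min(), b.values.min())
        hi = max(a.values.max(), b.values.max())
        data_range = float(hi - lo) or 1.0
    x, y = a.values, b.values
    weights = np.asarray(_MSSSIM_WEIGHTS[:scales])
    weights = weights / weights.sum()
    factors = []
    for level in range(scales):
        ssim_mean, cs_mean = _ssim_components(x, y, window, data_range)
        factors.append(ssim_mean if level == scales - 1 else cs_mean)
        if level < scales - 1:
            x, y = _downsample2(x), _downsample2(y)
    if scales == 1:
        return factors[0]
    if min(factors) <= 0:
        return 0.0
    return float(np.prod([f**w for f, w in zip(factors, weights)]))


@dataclass
class ROCResult:
    """One ROC curve: threshold sweep, AUROC and the contrast it scores."""

    predictor: str
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auroc: float
    positivity_cutoff: float | None = None


def positivity_labels(table: pd.DataFrame, cutoff: float = TAU_CUTOFFS[0]) -> pd.Series:
    """Binary tau-positivity per scan: meta-ROI SUVR strictly above the cut-off."""
    if META_COLUMN not in table.columns:
        raise ValueError(f"table lacks the {META_COLUMN!r} column")
    if len(table) == 0:
        raise ValueError("empty regional table")
    return (table[META_COLUMN] > cutoff).astype(int)


def roc_auc(scores, labels, predictor: str = "score",
            positivity_cutoff: float | None = None) -> ROCResult:
    """ROC curve and AUROC from an all-threshold sweep.

    The trapezoidal area equals the Mann-Whitney pair-ordering probability
    with ties counted half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if len(np.unique(labels)) != 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thr = _roc_curve(labels, scores)
    return ROCResult(
        predictor=predictor,
        thresholds=thr,
        fpr=fpr,
        tpr=tpr,
        auroc=float(_trapezoid_auc(fpr, tpr)),
        positivity_cutoff=positivity_cutoff,
    )


def group_classification(
    table: pd.DataFrame,
    group_labels: pd.Series,
    positive_group: str,
    negative_group: str,
    predictor: str = META_COLUMN,
    flip_sign: bool = False,
) -> ROCResult:
    """ROC of the meta-ROI SUVR for a named diagnostic contrast.

    ``positive_group`` / ``negative_group`` name diagnostic groups ("CU"
    expands to CU- and CU+). ``flip_sign`` negates the score for predictors
    where *lower* values indicate the positive class (e.g. FDG
    hypometabolism).
    """
    def expand(name: str) -> frozenset[str]:
        return GROUP_EXPANSIONS.get(name, frozenset({name}))

    pos, neg = expand(positive_group), expand(negative_group)
    present = set(group_labels.unique())
    for name, members in (("positive", pos), ("negative", neg)):
        if not members & present:
            raise ValueError(
                f"{name} group {sorted(members)} absent from cohort groups {sorted(present)}"
            )
    aligned = group_labels.reindex(table.index)
    keep = aligned.isin(pos | neg)
    scores = table.loc[keep, predictor].to_numpy(dtype=float)
    if flip_sign:
        scores = -scores
    labels = aligned[keep].isin(pos).astype(int).to_numpy()
    return roc_auc(scores, labels,
                   predictor=f"{predictor}:{positive_group}-vs-{negative_group}")
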