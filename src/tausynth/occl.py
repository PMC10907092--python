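"""ROI-occlusion sensitivity: which input regions drive the synthesis?

One ROI at a time is zeroed in the source image, the network re-imputes
the tau-like target, and the change in each region's mean absolute
percentage error is recorded:

    dMAPE[R1 -> R2] = MAPE(R1 occluded, evaluated at R2) - MAPE(R2)

where the baseline MAPE(R2) comes from un-occluded inputs over the same
scans. Rows index the occluded ROI, columns the evaluated ROI; the
diagonal captures local influence and off-diagonal structure reveals
physically remote couplings the network exploits. Entries may be negative
(occlusion can reduce error) and are never clamped. Row sums give the
total influence of occluding each ROI.

Occlusion is applied after SUVR normalization, so zeroing an ROI cannot
corrupt the reference-region median that defines the scale of every other
region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .evaluate import META_COLUMN, mape, regional_suvr_table
from .net import DenseUNet, impute
from .phantom import ScanPair
from .prep import CropPadSpec, crop_pad, invert_crop_pad, normalize_suvr
from .volio import ROIAtlas, Volume

__all__ = ["OcclusionMatrix", "occlude_roi", "occlusion_matrix"]


def occlude_roi(volume: Volume, atlas: ROIAtlas, label: int) -> Volume:
    """Zero the voxels of one atlas label; every other voxel is untouched."""
    if not np.any(atlas.labels == label):
        raise ValueError(f"label {label} not present in atlas")
    out = volume.values.copy()
    out[atlas.labels == label] = 0.0
    return volume.with_values(out)


@dataclass
class OcclusionMatrix:
    """R x R grid of dMAPE values plus the un-occluded baseline."""

    delta: np.ndarray  # [occluded ROI, evaluated ROI]
    baseline_mape: np.ndarray  # MAPE(R2) per evaluated ROI
    roi_order: list[int]
    meta_delta: np.ndarray | None = None  # dMAPE of the meta-ROI per occluded ROI

    @property
    def row_sums(self) -> np.ndarray:
        """Total influence of occluding each ROI (horizontal summation)."""
        return self.delta.sum(axis=1)

    def occluded_mape(self, occluded: int) -> np.ndarray:
        """Reconstruct MAPE(R1 -> R2) for one occluded ROI from baseline + delta."""
        i = self.roi_order.index(occluded)
        return self.baseline_mape + self.delta[i]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.delta, index=self.roi_order, columns=self.roi_order)
        df.index.name = "occluded_roi"
        df["row_sum"] = self.row_sums
        return df


def _regional_predictions(
    predict: Callable[[Volume], Volume],
    sources: dict[str, Volume],
    atlas: ROIAtlas,
    croppad: CropPadSpec | None,
) -> pd.DataFrame:
    preds = {}
    for sid, src in sources.items():
        net_in = crop_pad(src, croppad) if croppad is not None else src
        out = predict(net_in)
        preds[sid] = invert_crop_pad(out, croppad) if croppad is not None else out
    return regional_suvr_table(preds, atlas)


def _per_roi_mape(pred_table: pd.DataFrame, truth_table: pd.DataFrame,
                  roi_order: list[int]) -> np.ndarray:
    return np.array(
        [mape(pred_table[r].to_numpy(), truth_table[r].to_numpy()) for r in roi_order]
    )


def occlusion_matrix(
    model: DenseUNet | Callable[[Volume], Volume],
    scans: list[ScanPair],
    atlas: ROIAtlas,
    croppad: CropPadSpec | None = None,
    normalize: bool = True,
) -> OcclusionMatrix:
    """Full dMAPE adjacency matrix over a set of (test-partition) scans.

    ``model`` is either a trained Dense-U-Net or any ``Volume -> Volume``
    callable (e.g. an identity "copy" model, the analytic oracle for which
    all off-diagonal influence vanishes). MAPE is computed per ROI across
    scans against each scan's ground-truth target, both on the regional
    SUVR scale; the meta-ROI response is tracked alongside.
    """
    if not scans:
        raise ValueError("need at least one scan for occlusion analysis")
    predict: Callable[[Volume], Volume]
    if isinstance(model, DenseUNet):
        predict = lambda v: impute(model, v)
    else:
        predict = model

    if normalize:
        sources = {sc.scan_id: normalize_suvr(sc.source, atlas) for sc in scans}
        truths = {sc.scan_id: normalize_suvr(sc.target, atlas) for sc in scans}
    else:
        sources = {sc.scan_id: sc.source for sc in scans}
        truths = {sc.scan_id: sc.target for sc in scans}
    truth_table = regional_suvr_table(truths, atlas)
    roi_order = atlas.roi_labels
    R = len(roi_order)

    base_table = _regional_predictions(predict, sources, atlas, croppad)
    baseline = _per_roi_mape(base_table, truth_table, roi_order)
    base_meta = mape(base_table[META_COLUMN].to_numpy(), truth_table[META_COLUMN].to_numpy())

    delta = np.zeros((R, R))
    meta_delta = np.zeros(R)
    for i, occluded in enumerate(roi_order):
        occluded_sources = {
            sid: occlude_roi(vol, atlas, occluded) for sid, vol in sources.items()
        }
        occ_table = _regional_predictions(predict, occluded_sources, atlas, croppad)
        delta[i] = _per_roi_mape(occ_table, truth_table, roi_order) - baseline
        meta_delta[i] = (
            mape(occ_table[META_COLUMN].to_numpy(), truth_table[META_COLUMN].to_numpy())
            - base_meta
        )
    return OcclusionMatrix(
        delta=delta, baseline_mape=baseline, roi_order=roi_order, meta_delta=meta_delta
    )
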