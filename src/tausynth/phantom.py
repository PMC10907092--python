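"""Synthetic paired-modality phantom cohorts with known cross-ROI coupling.

The real cohorts behind cross-modal tau-PET synthesis are access-restricted,
so this module generates phantoms in which the ground truth is known by
construction: a latent disease stage ``s`` in [0, 1] per subject drives a
tau-like target modality, the source modality carries per-ROI signal that
couples into the target both locally and from physically remote ROIs, and
every scan adds independent voxel noise. That makes training, regional
evaluation, ROC analyses and occlusion interpretability all testable
without any download.

Generative model (per subject, per scan):

* stage ``s ~ Uniform(0, 1)``; all scans of a subject share ``s``;
* source ROI means ``u_r = b_r + a_r * s + dev_r`` with cohort-level
  baselines ``b_r``, stage slopes ``a_r`` and per-subject deviations;
* target ROI means ``m = W^T u + c * s`` where ``W[i, j]`` is the influence
  of *source* ROI ``i`` on *target* ROI ``j`` (diagonal = local coupling)
  and ``c`` is the per-ROI stage effect;
* the reference-region means of both modalities are pinned to 1 so SUVR
  normalization is always well defined;
* voxel values are the ROI mean plus additive Gaussian noise, optionally
  times a scan-level multiplicative scale nuisance (off by default) that
  SUVR division removes.

ROIs are axis-aligned blocks separated by at least two background voxels,
so any two distinct ROIs are physically disconnected — a prerequisite for
the occlusion analysis, which distinguishes local from remote influence.

Diagnostic group labels reuse the field's names (CU-, CU+, MCI, AD-spec,
FTD-spec, DLB-spec) as deterministic stage bins; no clinical semantics are
claimed beyond "meta-ROI tau rises with stage".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .volio import ROIAtlas, Volume, read_atlas, read_volume, write_atlas, write_volume

__all__ = [
    "PhantomConfig",
    "SubjectRecord",
    "ScanPair",
    "Cohort",
    "SizingError",
    "PhantomConfigError",
    "make_atlas",
    "generate_cohort",
    "save_cohort",
    "load_cohort",
    "GROUP_LABELS",
]

GROUP_LABELS = ("CU-", "CU+", "FTD-spec", "DLB-spec", "MCI", "AD-spec")
#: default stage cut points mapping stage bins onto GROUP_LABELS, ordered by
#: increasing tau-like burden (non-AD dementias sit below MCI/AD).
DEFAULT_GROUP_CUTPOINTS = (0.30, 0.45, 0.55, 0.65, 0.80)
DEFAULT_AMYLOID_THRESHOLD = 0.35


class SizingError(ValueError):
    """The grid cannot host the requested number of non-empty ROIs."""


class PhantomConfigError(ValueError):
    """A configuration that makes the generative model ill-defined."""


@dataclass
class PhantomConfig:
    """Study conditions for one phantom cohort.

    Defaults are the desk-scale conditions: a 32^3 grid, 12 ROIs (6-member
    meta-ROI, one reference region), 60 subjects with up to 2 scans each,
    identity local coupling and additive noise at 5% of the ~1.2 SUVR
    signal level.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    n_rois: int = 12
    n_subjects: int = 60
    scans_per_subject: int = 2
    coupling: np.ndarray | None = None  # W[i, j]: source ROI i -> target ROI j
    stage_effect: np.ndarray | None = None  # per-ROI slope of target on stage
    noise_sd: float = 0.06
    ref_region_id: int | None = None  # defaults to the last label (n_rois)
    seed: int = 0
    meta_size: int = 6
    min_roi_voxels: int = 27
    scale_nuisance_sd: float = 0.0  # log-sd of multiplicative scan scale; 0 = off
    group_cutpoints: tuple[float, ...] = DEFAULT_GROUP_CUTPOINTS
    amyloid_threshold: float = DEFAULT_AMYLOID_THRESHOLD
    source_baseline: tuple[float, float] = (1.0, 1.8)  # per-ROI Uniform range
    source_stage_slope: tuple[float, float] = (-0.4, 0.4)
    subject_sd: float = 0.12  # per-subject deviation of source ROI means

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        if len(self.grid_shape) != 3 or min(self.grid_shape) < 16:
            raise PhantomConfigError("grid_shape must be 3 integers, each >= 16")
        if self.n_rois < 1 or self.n_subjects < 1 or self.scans_per_subject < 1:
            raise PhantomConfigError("counts must be positive")
        if self.noise_sd < 0:
            raise PhantomConfigError("noise_sd must be >= 0")
        if self.ref_region_id is None:
            self.ref_region_id = self.n_rois
        if not (1 <= self.ref_region_id <= self.n_rois):
            raise PhantomConfigError("ref_region_id must be an ROI label in 1..R")
        R = self.n_rois
        if self.coupling is None:
            self.coupling = np.eye(R)
        self.coupling = np.asarray(self.coupling, dtype=float)
        if self.coupling.shape != (R, R):
            raise PhantomConfigError(f"coupling must be {R}x{R}")
        if (self.coupling < 0).any():
            raise PhantomConfigError("coupling weights must be non-negative")
        if self.stage_effect is None:
            se = np.full(R, 0.05)
            se[: self.meta_size] = 0.8  # tau-like rise in the meta-ROI
            self.stage_effect = se
        self.stage_effect = np.asarray(self.stage_effect, dtype=float)
        if self.stage_effect.shape != (R,):
            raise PhantomConfigError(f"stage_effect must have length {R}")

    def with_remote_coupling(self, source_roi: int, target_roi: int, weight: float) -> "PhantomConfig":
        """Copy of this config with one planted remote coupling added.

        ``source_roi -> target_roi`` (1-based labels): zeroing the source
        ROI in the input should then degrade prediction of the target ROI.
        """
        W = self.coupling.copy()
        W[source_roi - 1, target_roi - 1] += weight
        return replace(self, coupling=W)


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    stage: float
    group_label: str
    amyloid_status: str


@dataclass
class ScanPair:
    """One paired scan: source modality volume + tau-like target volume."""

    scan_id: str
    subject_id: str
    source: Volume
    target: Volume
    true_roi_means: np.ndarray  # noiseless target ROI means, label order 1..R


@dataclass
class Cohort:
    """Scans grouped by subject, with per-subject diagnosis metadata."""

    subjects: list[SubjectRecord]
    scans: list[ScanPair]
    roi_labels: list[int]

    def subject(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    def scans_of(self, subject_id: str) -> list[ScanPair]:
        return [sc for sc in self.scans if sc.subject_id == subject_id]

    def table(self) -> pd.DataFrame:
        """Cohort table: one row per scan with subject metadata."""
        recs = {s.subject_id: s for s in self.subjects}
        rows = [
            {
                "subject_id": sc.subject_id,
                "scan_id": sc.scan_id,
                "group_label": recs[sc.subject_id].group_label,
                "amyloid_status": recs[sc.subject_id].amyloid_status,
                "stage": recs[sc.subject_id].stage,
            }
            for sc in self.scans
        ]
        return pd.DataFrame(rows)


def _block_grid(n: int) -> tuple[int, int, int]:
    """Smallest near-cubic (bx, by, bz) with bx*by*bz >= n."""
    bz = max(1, math.ceil(n ** (1 / 3)))
    by = max(1, math.ceil(math.sqrt(n / bz)))
    bx = max(1, math.ceil(n / (by * bz)))
    return bx, by, bz


def _axis_bounds(length: int, parts: int) -> list[tuple[int, int]]:
    edges = np.linspace(0, length, parts + 1).round().astype(int)
    return [(int(edges[i]), int(edges[i + 1])) for i in range(parts)]


def make_atlas(config: PhantomConfig) -> ROIAtlas:
    """Partition the grid into R axis-aligned block ROIs plus background.

    Each ROI is a connected block shrunk by a one-voxel margin on every
    face, so distinct ROIs are separated by background — "physically
    remote" in the occlusion sense. The last label is the reference region
    (unless the config says otherwise) and the first ``meta_size`` labels
    form the meta-ROI.

    Raises
    ------
    SizingError
        If the grid cannot host ``n_rois`` ROIs of ``min_roi_voxels`` each.
    """
    R = config.n_rois
    if R < 8:
        raise PhantomConfigError("need n_rois >= 8 (6 meta members + reference + spare)")
    capacity = int(np.prod(config.grid_shape))
    if R * config.min_roi_voxels > capacity:
        raise SizingError(
            f"{R} ROIs x {config.min_roi_voxels} voxels exceed the "
            f"{capacity}-voxel grid"
        )
    bx, by, bz = _block_grid(R)
    cells = [
        (cx, cy, cz)
        for cx in _axis_bounds(config.grid_shape[0], bx)
        for cy in _axis_bounds(config.grid_shape[1], by)
        for cz in _axis_bounds(config.grid_shape[2], bz)
    ]
    labels = np.zeros(config.grid_shape, dtype=np.int32)
    for lab, ((x0, x1), (y0, y1), (z0, z1)) in enumerate(cells[:R], start=1):
        # one-voxel margin on each face keeps ROIs mutually disconnected
        sx, sy, sz = slice(x0 + 1, x1 - 1), slice(y0 + 1, y1 - 1), slice(z0 + 1, z1 - 1)
        block = labels[sx, sy, sz]
        if block.size < config.min_roi_voxels:
            raise SizingError(
                f"ROI {lab}: cell of {block.size} voxels after margins is below "
                f"the {config.min_roi_voxels}-voxel minimum"
            )
        labels[sx, sy, sz] = lab
    names = {lab: f"roi_{lab:02d}" for lab in range(1, R + 1)}
    names[config.ref_region_id] = "reference"
    meta = frozenset(range(1, config.meta_size + 1)) - {config.ref_region_id}
    return ROIAtlas(
        labels=labels,
        names=names,
        meta_members=meta,
        reference_label=config.ref_region_id,
    )


def assign_group(stage: float, cutpoints: tuple[float, ...] = DEFAULT_GROUP_CUTPOINTS) -> str:
    """Deterministic stage-bin -> diagnostic-group mapping."""
    for label, cut in zip(GROUP_LABELS, cutpoints):
        if stage < cut:
            return label
    return GROUP_LABELS[len(cutpoints)]


def generate_cohort(config: PhantomConfig, atlas: ROIAtlas) -> Cohort:
    """Draw a full phantom cohort under the configured study conditions.

    Deterministic for a fixed ``(config, seed)``. Scans of one subject
    share the latent stage and the source ROI-mean vector but carry
    independent voxel noise.
    """
    R = config.n_rois
    if len(atlas.roi_labels) != R:
        raise PhantomConfigError(
            f"atlas has {len(atlas.roi_labels)} ROIs, config expects {R}"
        )
    rng = np.random.default_rng(config.seed)
    ref_idx = config.ref_region_id - 1

    lo, hi = config.source_baseline
    base = rng.uniform(lo, hi, size=R)
    slo, shi = config.source_stage_slope
    slope = rng.uniform(slo, shi, size=R)

    masks = [atlas.mask(lab) for lab in range(1, R + 1)]

    subjects: list[SubjectRecord] = []
    scans: list[ScanPair] = []
    for i in range(config.n_subjects):
        sid = f"sub{i:04d}"
        stage = float(rng.uniform(0.0, 1.0))
        u = base + slope * stage + rng.normal(0.0, config.subject_sd, size=R)
        u[ref_idx] = 1.0  # pin the reference so source SUVR is well defined
        m = config.coupling.T @ u + config.stage_effect * stage
        m[ref_idx] = 1.0  # pin the reference so target SUVR is well defined
        if m[ref_idx] <= 0:
            raise PhantomConfigError("reference-region target mean must be positive")
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                stage=stage,
                group_label=assign_group(stage, config.group_cutpoints),
                amyloid_status="pos" if stage >= config.amyloid_threshold else "neg",
            )
        )
        for j in range(config.scans_per_subject):
            src = np.zeros(config.grid_shape)
            tgt = np.zeros(config.grid_shape)
            for r in range(R):
                src[masks[r]] = u[r]
                tgt[masks[r]] = m[r]
            if config.noise_sd > 0:
                in_roi = atlas.labels > 0
                src[in_roi] += rng.normal(0.0, config.noise_sd, size=int(in_roi.sum()))
                tgt[in_roi] += rng.normal(0.0, config.noise_sd, size=int(in_roi.sum()))
            if config.scale_nuisance_sd > 0:
                src *= math.exp(rng.normal(0.0, config.scale_nuisance_sd))
                tgt *= math.exp(rng.normal(0.0, config.scale_nuisance_sd))
            scans.append(
                ScanPair(
                    scan_id=f"{sid}_scan{j}",
                    subject_id=sid,
                    source=Volume(values=src),
                    target=Volume(values=tgt),
                    true_roi_means=m.copy(),
                )
            )
    return Cohort(subjects=subjects, scans=scans, roi_labels=list(range(1, R + 1)))


def save_cohort(cohort: Cohort, atlas: ROIAtlas, out_dir: str | Path) -> Path:
    """Write one NIfTI per volume, the atlas (+JSON sidecar) and the cohort CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_atlas(atlas, out / "atlas.nii.gz", out / "atlas_labels.json")
    truth = {}
    for sc in cohort.scans:
        write_volume(sc.source, out / f"{sc.scan_id}_source.nii.gz")
        write_volume(sc.target, out / f"{sc.scan_id}_target.nii.gz")
        truth[sc.scan_id] = [float(v) for v in sc.true_roi_means]
    cohort.table().to_csv(out / "cohort.csv", index=False)
    pd.DataFrame(truth).T.rename_axis("scan_id").to_csv(out / "true_roi_means.csv")
    return out


def load_cohort(out_dir: str | Path) -> tuple[Cohort, ROIAtlas]:
    out = Path(out_dir)
    atlas = read_atlas(out / "atlas.nii.gz", out / "atlas_labels.json")
    table = pd.read_csv(out / "cohort.csv")
    truth = pd.read_csv(out / "true_roi_means.csv", index_col="scan_id")
    subjects = [
        SubjectRecord(
            subject_id=row.subject_id,
            stage=float(row.stage),
            group_label=row.group_label,
            amyloid_status=row.amyloid_status,
        )
        for row in table.drop_duplicates("subject_id").itertuples()
    ]
    scans = [
        ScanPair(
            scan_id=row.scan_id,
            subject_id=row.subject_id,
            source=read_volume(out / f"{row.scan_id}_source.nii.gz"),
            target=read_volume(out / f"{row.scan_id}_target.nii.gz"),
            true_roi_means=truth.loc[row.scan_id].to_numpy(),
        )
        for row in table.itertuples()
    ]
    return Cohort(subjects=subjects, scans=scans, roi_labels=atlas.roi_labels), atlas
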