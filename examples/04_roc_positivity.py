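"""Tau-positivity cut-offs and diagnostic-group ROC on phantom data.

Extracts regional SUVR tables from ground-truth tau-like volumes, applies
the four published meta-ROI positivity cut-offs (1.11 / 1.21 / 1.33 /
1.46), and scores the CU vs AD-spectrum contrast with an ROC analysis.
"""

import pandas as pd

from tausynth import (
    TAU_CUTOFFS,
    PhantomConfig,
    generate_cohort,
    group_classification,
    make_atlas,
    normalize_suvr,
    positivity_labels,
    regional_suvr_table,
)

cfg = PhantomConfig(grid_shape=(16, 16, 16), n_subjects=120, scans_per_subject=1, seed=3)
atlas = make_atlas(cfg)
cohort = generate_cohort(cfg, atlas)

volumes = {sc.scan_id: normalize_suvr(sc.target, atlas) for sc in cohort.scans}
table = regional_suvr_table(volumes, atlas)
groups = cohort.table().set_index("scan_id")["group_label"]

print("meta-ROI SUVR by diagnostic group:")
print(table.join(groups).groupby("group_label")["meta_roi"].median().round(3).to_string())

print("\ntau-positive fraction at each cut-off:")
for cut in TAU_CUTOFFS:
    frac = positivity_labels(table, cut).mean()
    print(f"  > {cut:.2f}: {100 * frac:5.1f}%")

res = group_classification(table, groups, "AD-spec", "CU")
print(f"\nCU vs AD-spectrum AUROC of meta-ROI SUVR: {res.auroc:.3f}")
print("(stage drives meta-ROI tau, so the contrast is nearly separable by design)")
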