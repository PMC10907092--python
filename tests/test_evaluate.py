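import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm
from skimage.metrics import structural_similarity

from tausynth.evaluate import (
    TAU_CUTOFFS,
    extract_regional_suvr,
    group_classification,
    mape,
    max_ms_ssim_scales,
    ms_ssim,
    pearson_r,
    positivity_labels,
    regional_suvr_table,
    rmse_map,
    roc_auc,
)
from tausynth.volio import ROIAtlas, Volume


# ---------------------------------------------------------------- oracles

def mape_oracle(pred, truth):
    total = 0.0
    for p, t in zip(pred, truth):
        total += abs(p - t) / t
    return 100.0 * total / len(pred)


def pearson_oracle(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / (sxx * syy) ** 0.5


def auroc_oracle(scores, labels):
    """O(n^2) Mann-Whitney pair counting with ties at 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


# ---------------------------------------------------------------- regional SUVR

@pytest.fixture(scope="module")
def toy_atlas():
    labels = np.zeros((8, 8, 8), dtype=np.int32)
    for i in range(6):
        labels[i, 0, :3] = i + 1  # six 3-voxel meta members
    labels[7, 7, :5] = 7  # reference region
    return ROIAtlas(labels=labels, names={i: f"r{i}" for i in range(1, 8)},
                    meta_members={1, 2, 3, 4, 5, 6}, reference_label=7)


class TestRegionalSUVR:
    def test_constant_volume(self, toy_atlas):
        row = extract_regional_suvr(Volume(values=np.full((8, 8, 8), 1.3)), toy_atlas)
        np.testing.assert_allclose(row.to_numpy(), 1.3)

    def test_median_of_roi_voxels(self, toy_atlas):
        vals = np.zeros((8, 8, 8))
        vals[0, 0, :3] = [1.0, 2.0, 9.0]
        row = extract_regional_suvr(Volume(values=vals), toy_atlas)
        assert row[1] == 2.0

    def test_meta_is_mean_of_member_medians(self, toy_atlas):
        vals = np.zeros((8, 8, 8))
        for i, m in enumerate([1.0, 1.2, 1.4, 1.6, 1.8, 2.0]):
            vals[i, 0, :3] = m
        row = extract_regional_suvr(Volume(values=vals), toy_atlas)
        assert row["meta_roi"] == pytest.approx(1.5)

    def test_meta_recomputation_bit_exact(self, toy_atlas, rng):
        vol = Volume(values=rng.uniform(0.5, 3.0, size=(8, 8, 8)))
        row = extract_regional_suvr(vol, toy_atlas)
        recomputed = np.mean([row[m] for m in sorted(toy_atlas.meta_members)])
        assert row["meta_roi"] == recomputed  # bit-for-bit

    def test_empty_roi_names_label(self):
        labels = np.zeros((8, 8, 8), dtype=np.int32)
        labels[0, 0, 0] = 1
        atlas = ROIAtlas(labels=labels, meta_members={1, 2}, reference_label=1)
        with pytest.raises(ValueError, match="2"):
            extract_regional_suvr(Volume(values=np.ones((8, 8, 8))), atlas)


# ---------------------------------------------------------------- scalar metrics

class TestScalarMetrics:
    def test_mape_examples(self):
        assert mape([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert mape([1.1, 1.8], [1.0, 2.0]) == pytest.approx(10.0)
        with pytest.raises(ValueError, match="positive"):
            mape([1.0], [0.0])

    def test_mape_matches_loop_oracle(self, rng):
        for _ in range(100):
            truth = rng.uniform(0.1, 5.0, size=50)
            pred = truth + rng.normal(0, 0.5, size=50)
            assert mape(pred, truth) == pytest.approx(mape_oracle(pred, truth), rel=1e-12)

    def test_pearson_examples(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)
        with pytest.raises(ValueError, match="variance"):
            pearson_r(x, np.ones(10))

    def test_pearson_matches_covariance_oracle(self, rng):
        for _ in range(100):
            x = rng.normal(size=10)
            y = rng.normal(size=10) + 0.3 * x
            assert pearson_r(x, y) == pytest.approx(pearson_oracle(x, y), rel=1e-10)

    def test_rmse_map(self, rng):
        a = Volume(values=rng.normal(size=(6, 6, 6)))
        b = Volume(values=rng.normal(size=(6, 6, 6)))
        np.testing.assert_array_equal(rmse_map([a], [a]).values, 0.0)
        np.testing.assert_allclose(rmse_map([a], [b]).values, np.abs(a.values - b.values))
        c = Volume(values=rng.normal(size=(6, 6, 6)))
        d = Volume(values=rng.normal(size=(6, 6, 6)))
        expect = np.sqrt(((a.values - b.values) ** 2 + (c.values - d.values) ** 2) / 2)
        np.testing.assert_allclose(rmse_map([a, c], [b, d]).values, expect, rtol=1e-12)
        with pytest.raises(ValueError):
            rmse_map([], [])


# ---------------------------------------------------------------- MS-SSIM

class TestMsSsim:
    def test_self_similarity_is_one(self, rng):
        v = Volume(values=rng.uniform(0, 2, size=(32, 32, 32)))
        assert ms_ssim(v, v, scales=2) == pytest.approx(1.0)

    def test_symmetry(self, rng):
        a = Volume(values=rng.uniform(0, 2, size=(32, 32, 32)))
        b = Volume(values=a.values + rng.normal(0, 0.2, size=(32, 32, 32)))
        assert ms_ssim(a, b, scales=2) == pytest.approx(ms_ssim(b, a, scales=2), rel=1e-12)

    def test_single_scale_equals_independent_ssim(self, rng):
        """scales=1 reduces to plain SSIM (uniform 7-voxel window)."""
        a = rng.uniform(0, 2, size=(20, 20, 20))
        b = a + rng.normal(0, 0.3, size=(20, 20, 20))
        ours = ms_ssim(Volume(values=a), Volume(values=b), scales=1, data_range=2.0)
        ref = structural_similarity(a, b, win_size=7, data_range=2.0)
        assert ours == pytest.approx(ref, rel=1e-10)

    def test_infeasible_scales_error_names_maximum(self, rng):
        v = Volume(values=rng.uniform(0, 1, size=(16, 16, 16)))
        maxs = max_ms_ssim_scales((16, 16, 16))
        with pytest.raises(ValueError, match=f"maximum feasible is {maxs}"):
            ms_ssim(v, v, scales=maxs + 1)

    def test_bounded_for_nonnegative_inputs(self, rng):
        a = Volume(values=rng.uniform(0, 2, size=(32, 32, 32)))
        b = Volume(values=rng.uniform(0, 2, size=(32, 32, 32)))
        val = ms_ssim(a, b)
        assert 0.0 <= val <= 1.0


# ---------------------------------------------------------------- positivity & ROC

class TestPositivityAndROC:
    def test_cutoff_grid(self):
        table = pd.DataFrame({"meta_roi": [1.25]})
        expect = {1.11: 1, 1.21: 1, 1.33: 0, 1.46: 0}
        for cutoff, lab in expect.items():
            assert positivity_labels(table, cutoff).iloc[0] == lab

    def test_exact_cutoff_is_negative(self):
        table = pd.DataFrame({"meta_roi": [1.33]})
        assert positivity_labels(table, 1.33).iloc[0] == 0  # strict >

    def test_empty_and_missing_column_errors(self):
        with pytest.raises(ValueError, match="meta_roi"):
            positivity_labels(pd.DataFrame({"x": [1.0]}), 1.11)
        with pytest.raises(ValueError, match="empty"):
            positivity_labels(pd.DataFrame({"meta_roi": []}), 1.11)

    def test_published_cutoffs(self):
        assert TAU_CUTOFFS == (1.11, 1.21, 1.33, 1.46)

    def test_auroc_extremes(self):
        perfect = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert perfect.auroc == 1.0
        tied = roc_auc(np.ones(10), [0, 1] * 5)
        assert tied.auroc == 0.5

    def test_auroc_matches_pair_counting_oracle(self, rng):
        for _ in range(100):
            scores = rng.integers(0, 8, size=20).astype(float)  # force ties
            labels = rng.integers(0, 2, size=20)
            if labels.min() == labels.max():
                continue
            res = roc_auc(scores, labels)
            assert res.auroc == pytest.approx(auroc_oracle(scores, labels), rel=1e-12)

    def test_auroc_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[0], labels[1] = 0, 1
        a = roc_auc(scores, labels).auroc
        b = roc_auc(np.exp(3 * scores) + 7, labels).auroc
        assert a == pytest.approx(b, rel=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1.0, 2.0], [1, 1])


class TestGroupClassification:
    @staticmethod
    def _table(rng, n, d_prime):
        meta = np.concatenate([rng.normal(0, 1, n), rng.normal(d_prime, 1, n)])
        groups = pd.Series(["CU-"] * (n // 2) + ["CU+"] * (n - n // 2) + ["AD-spec"] * n)
        table = pd.DataFrame({"meta_roi": meta})
        groups.index = table.index
        return table, groups

    def test_large_separation_matches_gaussian_closed_form(self, rng):
        """Two-Gaussian separation d': AUROC -> Phi(d'/sqrt(2))."""
        table, groups = self._table(rng, 400, 5.0)
        res = group_classification(table, groups, "AD-spec", "CU")
        assert res.auroc > 0.99
        assert res.auroc == pytest.approx(norm.cdf(5.0 / np.sqrt(2)), abs=0.01)

    def test_permuted_labels_near_chance(self, rng):
        table, groups = self._table(rng, 100, 3.0)
        perm = pd.Series(rng.permutation(groups.to_numpy()), index=groups.index)
        res = group_classification(table, perm, "AD-spec", "CU")
        assert 0.4 <= res.auroc <= 0.6

    def test_flip_sign_mirrors_auroc(self, rng):
        table, groups = self._table(rng, 50, 2.0)
        a = group_classification(table, groups, "AD-spec", "CU").auroc
        b = group_classification(table, groups, "AD-spec", "CU", flip_sign=True).auroc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_absent_group_raises(self, rng):
        table, groups = self._table(rng, 20, 1.0)
        with pytest.raises(ValueError, match="absent"):
            group_classification(table, groups, "FTD-spec", "CU")


def test_regional_table_rows_are_scans(toy_atlas, rng):
    vols = {f"s{i}": Volume(values=rng.uniform(0.5, 2.0, size=(8, 8, 8))) for i in range(4)}
    table = regional_suvr_table(vols, toy_atlas)
    assert list(table.index) == ["s0", "s1", "s2", "s3"]
    assert "meta_roi" in table.columns
    assert len(table.columns) == 8  # 7 ROIs + meta
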