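import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from bctseg.calibration import CalibrationTable, ComponentStats
from bctseg.core_io import LabelMap, Volume
from bctseg.metrics import bias_audit, cronbach_alpha, dc, dsc, ldsc, overlap, paired_ldsc_test


def _mask(*voxels, shape=(4, 4, 4)):
    m = np.zeros(shape, bool)
    for vox in voxels:
        m[vox] = True
    return m


A2 = _mask((0, 0, 0), (0, 0, 1))
B2 = _mask((0, 0, 1), (0, 0, 2))


class TestOverlap:
    def test_dsc_hand_values(self):
        assert dsc(A2, A2) == 1.0
        assert dsc(A2, _mask((3, 3, 3))) == 0.0
        assert dsc(A2, B2) == pytest.approx(0.5)  # 2*1/4

    def test_dc_hand_values(self):
        assert dc(A2, A2) == 0.0
        assert dc(A2, _mask((3, 3, 3), (3, 3, 2))) == 2.0
        assert dc(A2, B2) == pytest.approx(1.0)  # 2/2

    def test_both_empty_rejected(self):
        empty = np.zeros((4, 4, 4), bool)
        with pytest.raises(ValueError):
            dsc(empty, empty)
        with pytest.raises(ValueError):
            dc(empty, empty)

    def test_ldsc_values_and_antisymmetry(self):
        assert ldsc(0.5) == pytest.approx(0.0)
        assert ldsc(0.75) == pytest.approx(np.log(3.0))
        for x in (0.1, 0.35, 0.62, 0.9):
            assert ldsc(x) == pytest.approx(-ldsc(1.0 - x))
        with pytest.raises(ValueError):
            ldsc(1.0)

    def test_overlap_result_counts(self):
        r = overlap(A2, B2)
        assert (r.n_a, r.n_b) == (2, 2)
        assert r.ldsc == pytest.approx(ldsc(0.5))

    @given(st.integers(0, 2**30))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_conservation_identity(self, seed):
        """dsc*(|A|+|B|)/2 + dc*(|A|+|B|)/2 == |A union B| for any masks."""
        rng = np.random.default_rng(seed)
        a = rng.random((6, 6, 6)) < 0.4
        b = rng.random((6, 6, 6)) < 0.4
        if not (a.any() or b.any()):
            a[0, 0, 0] = True
        s = a.sum() + b.sum()
        assert dsc(a, b) * s / 2 + dc(a, b) * s / 2 == pytest.approx((a | b).sum())

    @given(st.integers(0, 2**30))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_dsc_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((5, 5, 5)) < 0.5
        b = rng.random((5, 5, 5)) < 0.5
        a[0, 0, 0] = True
        assert dsc(a, b) == dsc(b, a)


class TestPairedLdscTest:
    def test_identical_lists_give_p_one(self):
        vals = [0.8, 0.85, 0.9, 0.75]
        assert paired_ldsc_test(vals, vals) == 1.0

    def test_large_offset_significant(self):
        set1 = [0.95, 0.96, 0.94, 0.97, 0.95]
        set2 = [0.60, 0.62, 0.58, 0.63, 0.61]
        assert paired_ldsc_test(set1, set2) < 0.01

    def test_matches_textbook_paired_t_on_fixture(self):
        set1 = [0.80, 0.85, 0.90, 0.75, 0.88]
        set2 = [0.70, 0.80, 0.85, 0.72, 0.80]
        t1 = np.array([ldsc(x) for x in set1])
        t2 = np.array([ldsc(x) for x in set2])
        diff = t1 - t2
        t_stat = diff.mean() / (diff.std(ddof=1) / np.sqrt(len(diff)))
        expected = 2.0 * stats.t.sf(abs(t_stat), df=len(diff) - 1)
        assert paired_ldsc_test(set1, set2) == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_ldsc_test([0.8, 0.9], [0.8])


class TestCronbachAlpha:
    def test_perfectly_correlated_raters(self):
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        scores = np.vstack([base, base + 1.0, base - 0.5])
        assert cronbach_alpha(scores) == pytest.approx(1.0)

    def test_hand_computed_3x4_fixture(self):
        scores = np.array([[1, 2, 3, 4], [2, 2, 3, 5], [1, 3, 3, 4]], dtype=float)
        # population variances: rows 1.25, 1.5, 1.1875; column sums 4,7,9,13
        # with variance 10.6875; alpha = 1.5 * (1 - 3.9375/10.6875)
        assert cronbach_alpha(scores) == pytest.approx(0.9473684210526315)

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(12)
        scores = rng.integers(1, 6, size=(5, 1000)).astype(float)
        assert abs(cronbach_alpha(scores)) < 0.15

    def test_variance_convention_invariance(self):
        """Sample-variance (ddof=1) oracle gives the same alpha."""
        rng = np.random.default_rng(4)
        common = rng.normal(size=40)
        scores = common + rng.normal(scale=0.5, size=(4, 40))
        k = scores.shape[0]
        oracle = k / (k - 1) * (1 - scores.var(axis=1, ddof=1).sum() / scores.sum(axis=0).var(ddof=1))
        assert cronbach_alpha(scores) == pytest.approx(oracle)
        assert cronbach_alpha(scores) <= 1.0

    def test_alpha_increases_with_covariance(self):
        rng = np.random.default_rng(9)
        noise = rng.normal(size=(4, 200))
        common = rng.normal(size=200)
        low = cronbach_alpha(noise + 0.3 * common)
        high = cronbach_alpha(noise + 1.5 * common)
        assert high > low

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            cronbach_alpha(np.ones((1, 5)))
        with pytest.raises(ValueError):
            cronbach_alpha(np.ones((3, 5)))  # zero total variance


class TestBiasAudit:
    @staticmethod
    def _crisp_scene(cal, glandular_fraction=0.1):
        """Crisp low-glandularity breast: labels carry exact table HU."""
        labels = np.zeros((20, 20, 20), dtype=np.uint8)
        labels[2:18, 2:18, 2:18] = 1  # fat
        n_interior = (16**3)
        k = int(glandular_fraction * n_interior)
        interior = np.argwhere(labels == 1)
        for x, y, z in interior[:k]:
            labels[x, y, z] = 2  # gland
        labels[2:18, 2:18, 2] = 3  # 1-voxel skin plate (crisp, no blur)
        data = np.full(labels.shape, -1000.0, dtype=np.float32)
        for name, code in (("fat", 1), ("gland", 2), ("skin", 3)):
            data[labels == code] = cal.mean(name)
        return Volume(data, 1.0), LabelMap(labels=labels, spacing_mm=1.0)

    def test_skin_merge_positive_at_low_glandularity(self, cal):
        v, l = self._crisp_scene(cal)
        audit = bias_audit(v, l, cal)
        assert audit["skin"] > 0.0

    def test_absent_component_omitted(self, cal):
        v, l = self._crisp_scene(cal)
        audit = bias_audit(v, l, cal)
        assert "muscle" not in audit and "skinfold" not in audit

    def test_fat_like_fold_bias_is_small(self, cal):
        v, l = self._crisp_scene(cal)
        labels = l.labels.copy()
        labels[0:2, 0:2, 5:10] = 5  # small fold at fat HU
        data = v.data.copy()
        data[labels == 5] = cal.mean("fat")
        audit = bias_audit(Volume(data, 1.0), LabelMap(labels=labels, spacing_mm=1.0), cal)
        assert abs(audit["skinfold"]) < 1.0
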