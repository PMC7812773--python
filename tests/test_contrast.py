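import numpy as np
import pytest
from scipy import stats

from confield import (
    PRFParams,
    cf_to_visual_field,
    contralaterality_index,
    laterality_test,
    rc_preference_ratio,
    state_preference,
    weighted_correlation,
    weighted_ttest_diff,
)


class TestRcPreferenceRatio:
    def test_equal_positive_gives_half(self):
        assert rc_preference_ratio(0.2, 0.2) == pytest.approx(0.5)

    def test_pure_rest_gives_one_pure_movie_zero(self):
        assert rc_preference_ratio(0.3, 0.0) == pytest.approx(1.0)
        assert rc_preference_ratio(0.0, 0.3) == pytest.approx(0.0)

    def test_negative_constituents_clamped(self):
        # a negative movie value does not push the ratio above 1
        assert rc_preference_ratio(0.3, -0.2) == pytest.approx(1.0)

    def test_below_floor_undefined(self):
        assert np.isnan(rc_preference_ratio(0.004, 0.004))
        assert np.isnan(rc_preference_ratio(-0.5, -0.5))

    def test_array_in_array_out(self):
        out = rc_preference_ratio([0.2, 0.0, -1.0], [0.2, 0.4, -1.0])
        assert out.shape == (3,)
        assert out[0] == pytest.approx(0.5)
        assert out[1] == pytest.approx(0.0)
        assert np.isnan(out[2])

    def test_state_preference_mask(self):
        pref = state_preference([0.2, -0.5], [0.2, -0.5])
        assert pref.mask.tolist() == [True, False]
        df = pref.to_dataframe()
        assert set(df.columns) == {"ratio", "rho_rs", "rho_mw", "defined"}


class TestWeightedCorrelation:
    def test_uniform_weights_reduce_to_pearson(self, rng):
        x = rng.standard_normal(40)
        y = 0.5 * x + rng.standard_normal(40)
        rho, p = weighted_correlation(x, y, np.ones(40))
        rho_ref, p_ref = stats.pearsonr(x, y)
        assert rho == pytest.approx(rho_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, rel=1e-9)

    def test_zero_weight_points_ignored(self, rng):
        x = rng.standard_normal(30)
        y = 2 * x + rng.standard_normal(30) * 0.1
        w = np.ones(30)
        x2 = np.r_[x, 100.0]
        y2 = np.r_[y, -100.0]
        w2 = np.r_[w, 0.0]
        rho_a, _ = weighted_correlation(x, y, w)
        rho_b, _ = weighted_correlation(x2, y2, w2)
        assert rho_a == pytest.approx(rho_b, abs=1e-12)

    def test_perfect_correlation_p_zero(self):
        x = np.arange(10.0)
        rho, p = weighted_correlation(x, 2 * x + 1, np.ones(10))
        assert rho == pytest.approx(1.0)
        assert p == 0.0

    def test_weight_validation(self):
        with pytest.raises(ValueError):
            weighted_correlation([1, 2], [1, 2], [1.0])
        with pytest.raises(ValueError):
            weighted_correlation([1, 2], [1, 2], [-1.0, 1.0])
        with pytest.raises(ValueError):
            weighted_correlation([1, 2], [1, 2], [0.0, 0.0])

    def test_kish_df_shrinks_p(self, rng):
        # concentrating weight on few points must weaken evidence
        x = rng.standard_normal(50)
        y = 0.6 * x + rng.standard_normal(50) * 0.5
        _, p_unif = weighted_correlation(x, y, np.ones(50))
        w = np.full(50, 1e-6)
        w[:4] = 1.0
        _, p_conc = weighted_correlation(x, y, w)
        assert p_conc > p_unif


class TestWeightedTtestDiff:
    def test_uniform_weights_reduce_to_paired_t(self, rng):
        a = rng.standard_normal(25) + 0.3
        b = rng.standard_normal(25)
        t, df, p = weighted_ttest_diff(a, b, np.ones(25))
        t_ref, p_ref = stats.ttest_rel(a, b)
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert df == pytest.approx(24)
        assert p == pytest.approx(p_ref, rel=1e-9)

    def test_zero_difference_convention(self):
        a = np.array([1.0, 2.0, 3.0])
        t, df, p = weighted_ttest_diff(a, a, np.ones(3))
        assert t == 0.0 and p == 1.0

    def test_length_mismatch_and_too_few(self):
        with pytest.raises(ValueError):
            weighted_ttest_diff([1.0, 2.0], [1.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            weighted_ttest_diff([1.0], [0.0], [1.0])


class TestVisualFieldTranslation:
    def _prfs(self):
        return {
            "L": PRFParams(x0=[1.0, 3.0], y0=[0.5, -1.0], sigma=[1.0, 1.0],
                           amplitude=[1, 1], baseline=[0, 0], r2=[0.5, 0.5],
                           vertex_ids=np.array([4, 5])),
            "R": PRFParams(x0=[-2.0], y0=[2.0], sigma=[1.0],
                           amplitude=[1], baseline=[0], r2=[0.5],
                           vertex_ids=np.array([7])),
        }

    class _FakeCF:
        def __init__(self, v0, hemisphere):
            self.v0 = np.asarray(v0)
            self.hemisphere = np.asarray(hemisphere, dtype=object)
            self.condition = "rest"

    def test_mapping_and_hemifield(self):
        cf = self._FakeCF([5, 7], ["L", "R"])
        vf = cf_to_visual_field(cf, self._prfs())
        assert vf.eccentricity[0] == pytest.approx(np.hypot(3.0, -1.0))
        assert vf.polar_angle[1] == pytest.approx(np.degrees(np.arctan2(2, -2)))
        assert vf.hemifield.tolist() == ["R", "L"]  # contralateral
        assert vf.condition == "rest"

    def test_missing_prf_raises(self):
        cf = self._FakeCF([99], ["L"])
        with pytest.raises(KeyError):
            cf_to_visual_field(cf, self._prfs())


class TestLaterality:
    def test_contralaterality_index(self):
        hemifield = ["R", "R", "L", "R"]
        cf_hemi = ["L", "L", "L", "R"]
        # contra pairs: (R,L), (R,L); ipsi: (L,L), (R,R) -> (2-2)/4
        assert contralaterality_index(hemifield, cf_hemi) == pytest.approx(0.0)
        assert contralaterality_index(["R"], ["L"]) == 1.0
        assert contralaterality_index(["L"], ["L"]) == -1.0

    def test_laterality_test_reduces_to_ttest(self, rng):
        v = rng.uniform(-1, 1, 12) + 0.4
        t, df, p = laterality_test(v)
        t_ref, p_ref = stats.ttest_1samp(v, 0.0)
        assert t == pytest.approx(t_ref) and df == 11 and p == pytest.approx(p_ref)

    def test_degenerate_and_small(self):
        t, df, p = laterality_test([1.0, 1.0, 1.0])
        assert np.isinf(t) and p == 0.0
        with pytest.raises(ValueError):
            laterality_test([0.5])
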