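import numpy as np
import pytest

from confield import (
    DEFAULT_SIGMA_GRID_MM,
    CandidateSet,
    cf_grid_fit,
    cf_predict,
    cf_profile,
    crossvalidate,
    geodesic_distances,
    make_mesh,
    null_model_correction,
    significance,
    zscore,
)


@pytest.fixture(scope="module")
def grid_setup():
    """Two small hemispheres with exact planar distance matrices."""
    meshes = {h: make_mesh(6, 7, hemisphere=h) for h in ("L", "R")}
    dists = {
        h: geodesic_distances(m, np.arange(m.n_vertices), method="dijkstra")
        for h, m in meshes.items()
    }
    return meshes, dists


class TestCfProfile:
    def test_forced_values(self, grid_setup):
        _, dists = grid_setup
        sigma = 2.0
        prof = cf_profile(9, sigma, dists["L"])
        assert prof[9] == pytest.approx(1.0)
        i_at_sigma = dists["L"].index_of(11)  # 2 mm away along a row
        assert dists["L"].dists[9, i_at_sigma] == pytest.approx(2.0)
        assert prof[i_at_sigma] == pytest.approx(np.exp(-0.5))
        i_at_2sigma = dists["L"].index_of(13)  # 4 mm away
        assert prof[i_at_2sigma] == pytest.approx(np.exp(-2.0))

    def test_bad_inputs(self, grid_setup):
        _, dists = grid_setup
        with pytest.raises(ValueError):
            cf_profile(0, 0.0, dists["L"])
        with pytest.raises(KeyError):
            cf_profile(10_000, 1.0, dists["L"])


class TestCfPredict:
    def test_indicator_profile_returns_zscored_vertex(self, rng):
        src = rng.standard_normal((5, 100))
        prof = np.zeros(5)
        prof[3] = 1.0
        assert np.allclose(cf_predict(prof, src), zscore(src[3]))

    def test_output_zscored(self, rng):
        src = rng.standard_normal((5, 100))
        out = cf_predict(np.ones(5), src)
        assert out.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.std() == pytest.approx(1.0)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            cf_predict(np.ones(4), rng.standard_normal((5, 10)))


class TestCandidateSet:
    def test_count_and_enumeration_order(self, grid_setup):
        _, dists = grid_setup
        centers = {"L": np.array([0, 1, 2]), "R": np.array([5, 6])}
        cs = CandidateSet(centers, dists, sigmas=(3.0, 1.0))
        assert cs.n_candidates == 2 * (3 + 2)
        # sigma-major ascending, then hemisphere order, then center order
        assert np.allclose(cs.cand_sigma[:5], 1.0)
        assert list(cs.cand_hemi[:5]) == ["L", "L", "L", "R", "R"]
        assert list(cs.cand_vertex[:5]) == [0, 1, 2, 5, 6]

    def test_sigma_grid_validation(self, grid_setup):
        _, dists = grid_setup
        with pytest.raises(ValueError):
            CandidateSet({"L": [0]}, dists, sigmas=(1.0, -2.0))
        with pytest.raises(ValueError):
            CandidateSet({"L": [0]}, dists, sigmas=(1.0, 1.0))

    def test_default_sigma_grid_is_paper_ladder(self):
        assert DEFAULT_SIGMA_GRID_MM == (
            0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 7.0, 10.0, 15.0, 20.0, 30.0, 40.0, 80.0
        )


def _make_targets(cs, src, picks, rng, noise=0.0):
    """Targets generated from chosen candidates of the CandidateSet."""
    preds = []
    for (hemi, v0, sigma) in picks:
        prof = cf_profile(v0, sigma, cs.dists[hemi])
        preds.append(cf_predict(prof, src[hemi]))
    y = np.vstack(preds)
    if noise:
        y = y + noise * rng.standard_normal(y.shape)
    return y


class TestCfGridFit:
    def test_noiseless_exact_recovery(self, grid_setup, rng):
        _, dists = grid_setup
        centers = {h: np.arange(42) for h in ("L", "R")}
        cs = CandidateSet(centers, dists, sigmas=(1.0, 2.0, 5.0))
        src = {h: rng.standard_normal((42, 300)) for h in ("L", "R")}
        picks = [("L", 9, 2.0), ("R", 20, 1.0), ("L", 30, 5.0)]
        y = _make_targets(cs, src, picks, rng)
        fit = cf_grid_fit(y, cs, src)
        for t, (hemi, v0, sigma) in enumerate(picks):
            assert fit.hemisphere[t] == hemi
            assert fit.v0[t] == v0
            assert fit.sigma[t] == sigma
            assert fit.r[t] == pytest.approx(1.0)

    def test_zero_variance_target_flagged(self, grid_setup, rng):
        _, dists = grid_setup
        cs = CandidateSet({"L": np.arange(42)}, dists, sigmas=(2.0,))
        src = {"L": rng.standard_normal((42, 100))}
        y = np.zeros((1, 100))
        fit = cf_grid_fit(y, cs, src)
        assert not fit.valid[0]
        assert fit.r[0] == 0.0

    def test_exact_sigma_tie_resolves_to_smallest(self, grid_setup):
        _, dists = grid_setup
        # single active source vertex AT the center: profile weight there is
        # exactly 1 for every sigma, so all sigma candidates produce
        # bit-identical predictions — a genuinely exact tie
        t = np.sin(np.arange(50.0))
        src = {"L": np.zeros((42, 50))}
        src["L"][9] = t
        cs = CandidateSet({"L": np.array([9])}, dists, sigmas=(1.0, 3.0))
        fit = cf_grid_fit(t[None, :], cs, src)
        assert fit.sigma[0] == 1.0

    def test_exact_center_tie_resolves_to_first_listed(self, grid_setup):
        _, dists = grid_setup
        # single active vertex equidistant (1 mm) from both centers: the two
        # candidate predictions are bit-identical
        t = np.sin(np.arange(50.0))
        src = {"L": np.zeros((42, 50))}
        src["L"][10] = t
        cs = CandidateSet({"L": np.array([9, 11])}, dists, sigmas=(2.0,))
        fit = cf_grid_fit(t[None, :], cs, src)
        assert fit.v0[0] == 9

    def test_selection_uses_squared_correlation(self, grid_setup, rng):
        _, dists = grid_setup
        cs = CandidateSet({"L": np.arange(42)}, dists, sigmas=(2.0,))
        src = {"L": rng.standard_normal((42, 200))}
        prof = cf_profile(15, 2.0, dists["L"])
        y = -cf_predict(prof, src["L"])  # anticorrelated generator
        fit = cf_grid_fit(y[None, :], cs, src)
        assert fit.v0[0] == 15
        assert fit.r[0] == pytest.approx(-1.0)


class TestCrossvalidate:
    def _runs(self, cs, rng, n_runs=4, noise=0.5, picks=(("L", 9, 2.0), ("R", 20, 1.0))):
        src_runs = {h: [np.random.default_rng([7, i, r]).standard_normal((42, 150))
                        for r in range(n_runs)]
                    for i, h in enumerate(("L", "R"))}
        tgt_runs = [
            _make_targets(cs, {h: src_runs[h][r] for h in src_runs}, list(picks), rng, noise)
            for r in range(n_runs)
        ]
        return tgt_runs, src_runs

    @pytest.fixture
    def cs(self, grid_setup):
        _, dists = grid_setup
        return CandidateSet({h: np.arange(42) for h in ("L", "R")}, dists,
                            sigmas=(1.0, 2.0, 5.0))

    def test_noiseless_cv_r_one_and_stable_folds(self, cs, rng):
        tgt, src = self._runs(cs, rng, noise=0.0)
        res = crossvalidate(tgt, src, cs)
        assert res.n_folds == 4
        assert np.allclose(res.cv_r, 1.0, atol=1e-9)
        # training concatenates raw (per-run-scaled) predictions against
        # per-run z-scored targets, so within-set r is near but not exactly 1
        assert np.all(res.within_r**2 > 0.97)
        assert res.hemisphere[0] == "L" and res.v0[0] == 9
        assert res.sigma_cf[0] == 2.0 and res.sigma_cf_mean[0] == 2.0

    def test_corrected_equals_cv_minus_null(self, cs, rng):
        tgt, src = self._runs(cs, rng, noise=1.0)
        res = crossvalidate(tgt, src, cs)
        assert np.allclose(res.corrected, res.cv_r - res.null_r)

    def test_no_leakage_from_test_fold(self, cs, rng):
        tgt, src = self._runs(cs, rng, noise=1.0)
        res_a = crossvalidate(tgt, src, cs)
        # replace run 0 of the targets by pure noise: fold-0 selections
        # (trained on runs 1-3) must be identical
        tgt_b = [rng.standard_normal(tgt[0].shape)] + tgt[1:]
        res_b = crossvalidate(tgt_b, src, cs)
        assert np.array_equal(res_a.within_r[:, 0], res_b.within_r[:, 0])

    def test_single_run_rejected(self, cs, rng):
        tgt, src = self._runs(cs, rng, n_runs=1)
        with pytest.raises(ValueError, match="within-set"):
            crossvalidate(tgt, src, cs)

    def test_fold_count_must_match_runs(self, cs, rng):
        tgt, src = self._runs(cs, rng)
        with pytest.raises(ValueError, match="n_folds"):
            crossvalidate(tgt, src, cs, n_folds=3)

    def test_run_count_mismatch_rejected(self, cs, rng):
        tgt, src = self._runs(cs, rng)
        src_bad = {h: runs[:-1] for h, runs in src.items()}
        with pytest.raises(ValueError, match="run counts"):
            crossvalidate(tgt, src_bad, cs)

    def test_mean_like_target_penalized_by_null_model(self, cs, rng):
        # a target equal to the global mean signal: the nontopographic null
        # model explains it perfectly, while any CF candidate (confined to
        # one hemisphere) cannot — corrected must come out negative
        src_runs = {h: [np.random.default_rng([3, i, r]).standard_normal((42, 150))
                        for r in range(4)] for i, h in enumerate(("L", "R"))}
        tgt_runs = [
            zscore(np.vstack([src_runs[h][r] for h in ("L", "R")]).mean(axis=0))[None, :]
            for r in range(4)
        ]
        res = crossvalidate(tgt_runs, src_runs, cs)
        assert res.null_r[0] == pytest.approx(1.0, abs=1e-9)
        assert res.corrected[0] < -0.1


class TestNullModelCorrection:
    def test_difference_identity(self):
        out = null_model_correction([0.5, 0.2], [0.1, 0.2])
        assert np.allclose(out, [0.4, 0.0])

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            null_model_correction([0.5], [0.1], method="ratio")


class TestSignificance:
    def test_matches_scipy(self, rng):
        from scipy import stats
        v = rng.standard_normal(30) + 0.4
        t, df, p = significance(v)
        t_ref, p_ref = stats.ttest_1samp(v, 0.0)
        assert t == pytest.approx(t_ref) and p == pytest.approx(p_ref)
        assert df == 29

    def test_degenerate_conventions(self):
        assert significance([0.0, 0.0, 0.0]) == (0.0, 2, 1.0)
        t, df, p = significance([0.3, 0.3])
        assert np.isinf(t) and t > 0 and p == 0.0

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            significance([0.5])
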