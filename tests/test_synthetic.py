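import numpy as np
import pytest

from confield import (
    GeodesicDistanceMatrix,
    GroundTruth,
    SyntheticConfig,
    cf_profile,
    expected_resting_correlation,
    make_aperture,
    make_mesh,
    make_retinotopic_map,
    plant_targets,
    prf_predict,
    simulate_dataset,
    simulate_source,
    simulate_targets,
    zscore,
)
from confield.synthetic import HEMIS


class TestSyntheticConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_runs=0)
        with pytest.raises(ValueError):
            SyntheticConfig(vertex_spacing=-1.0)
        with pytest.raises(ValueError):
            SyntheticConfig(noise_sd=-0.1)

    def test_named_streams_stable_and_distinct(self):
        c = SyntheticConfig(seed=5)
        a = c.rng("source", "rest", "L", 0).standard_normal(4)
        b = c.rng("source", "rest", "L", 0).standard_normal(4)
        d = c.rng("source", "rest", "L", 1).standard_normal(4)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, d)


class TestRetinotopicMap:
    def test_hemifield_assignment(self):
        mesh_l = make_mesh(5, 6, hemisphere="L")
        mesh_r = make_mesh(5, 6, hemisphere="R")
        pl = make_retinotopic_map(mesh_l)
        pr = make_retinotopic_map(mesh_r)
        assert np.all(pl["x0"] >= 0)  # left hemisphere -> right hemifield
        assert np.all(pr["x0"] <= 0)
        assert np.all(pl["sigma"] > 0)

    def test_size_grows_with_eccentricity(self):
        p = make_retinotopic_map(make_mesh(5, 6), sigma_intercept=0.1, sigma_slope=0.2)
        ecc = np.hypot(p["x0"], p["y0"])
        assert np.allclose(p["sigma"], 0.1 + 0.2 * ecc)


class TestApertures:
    def test_kinds_and_shapes(self):
        for kind in ("bar", "wedge"):
            ap = make_aperture(kind, 8.0, n_frames=40, grid_res=41)
            assert ap.frames.shape == (40, 41, 41)
            assert set(np.unique(ap.frames)) <= {0.0, 1.0}

    def test_noise_kind_needs_rng(self):
        with pytest.raises(ValueError, match="rng"):
            make_aperture("noise", 8.0, n_frames=5, grid_res=21)
        ap = make_aperture("noise", 8.0, n_frames=5, grid_res=41,
                           rng=np.random.default_rng(0))
        assert 0.0 < ap.frames.mean() < 0.5

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_aperture("annulus", 8.0)

    def test_padding_adds_blanks(self):
        ap = make_aperture("bar", 8.0, n_frames=20, grid_res=21, pad=3)
        assert ap.n_frames == 26
        assert ap.frames[:3].sum() == 0 and ap.frames[-3:].sum() == 0


def _stim_setup(noise_sd=0.0, rows=5, cols=6, T=40):
    cfg = SyntheticConfig(
        mesh_rows=rows, mesh_cols=cols, n_runs=2, n_timepoints_per_run=T,
        noise_sd=noise_sd, n_targets=6, seed=3,
    )
    mesh = make_mesh(rows, cols, hemisphere="L")
    gt = GroundTruth(prf={"L": make_retinotopic_map(mesh)})
    ap = make_aperture("bar", cfg.field_radius, n_frames=T, grid_res=41)
    return cfg, mesh, gt, ap


class TestSimulateSource:
    def test_noiseless_stimulated_matches_analytic_prediction(self):
        cfg, mesh, gt, ap = _stim_setup(noise_sd=0.0)
        runs = simulate_source(mesh, gt, cfg, aperture=ap)
        p = gt.prf["L"]
        v = 7
        pred = zscore(prf_predict(p["x0"][v], p["y0"][v], p["sigma"][v], ap))
        assert np.allclose(runs[0].data[v], pred, atol=1e-10)

    def test_same_seed_identical_different_runs_differ(self):
        cfg, mesh, gt, ap = _stim_setup(noise_sd=1.0)
        a = simulate_source(mesh, gt, cfg, aperture=ap)
        b = simulate_source(mesh, gt, cfg, aperture=ap)
        assert np.array_equal(a[0].data, b[0].data)
        assert not np.array_equal(a[0].data, a[1].data)

    def test_resting_correlation_decays_like_planted_length(self):
        cfg = SyntheticConfig(mesh_rows=10, mesh_cols=12, n_runs=1,
                              n_timepoints_per_run=6000, noise_sd=0.0, seed=9)
        mesh = make_mesh(10, 12, hemisphere="L")
        gt = GroundTruth(prf={"L": make_retinotopic_map(mesh)})
        runs = simulate_source(mesh, gt, cfg, resting=True)
        emp = np.corrcoef(runs[0].data)
        ana = expected_resting_correlation(mesh, cfg)
        off = ~np.eye(mesh.n_vertices, dtype=bool)
        # large-n empirical correlogram tracks the analytic one
        assert np.abs(emp[off] - ana[off]).mean() < 0.05
        # and correlation decays with distance
        d = np.linalg.norm(mesh.vertices[:, None] - mesh.vertices[None, :], axis=2)
        near = ana[(d > 0) & (d <= 2)].mean()
        far = ana[d >= 8].mean()
        assert near > 0.5 > far

    def test_stimulated_needs_aperture(self):
        cfg, mesh, gt, _ = _stim_setup()
        with pytest.raises(ValueError, match="aperture"):
            simulate_source(mesh, gt, cfg)

    def test_frame_count_mismatch_rejected(self):
        cfg, mesh, gt, _ = _stim_setup()
        ap_bad = make_aperture("bar", cfg.field_radius, n_frames=13, grid_res=41)
        with pytest.raises(ValueError, match="frames"):
            simulate_source(mesh, gt, cfg, aperture=ap_bad)

    def test_per_run_apertures(self):
        cfg, mesh, gt, ap = _stim_setup(noise_sd=0.0)
        ap2 = make_aperture("wedge", cfg.field_radius, n_frames=40, grid_res=41)
        runs = simulate_source(mesh, gt, cfg, aperture=[ap, ap2])
        assert not np.array_equal(runs[0].data, runs[1].data)
        with pytest.raises(ValueError, match="apertures"):
            simulate_source(mesh, gt, cfg, aperture=[ap])


class TestSimulateTargets:
    def _sources(self, cfg, meshes, gt):
        return {
            h: simulate_source(meshes[h], gt, cfg, resting=True)
            for h in HEMIS
        }

    def test_noiseless_uncoupled_target_correlates_one(self):
        cfg = SyntheticConfig(mesh_rows=6, mesh_cols=7, n_runs=2,
                              n_timepoints_per_run=60, noise_sd=0.0,
                              global_coupling=0.0, n_targets=4, seed=2)
        meshes = {h: make_mesh(6, 7, hemisphere=h) for h in HEMIS}
        gt = GroundTruth(prf={h: make_retinotopic_map(meshes[h]) for h in HEMIS})
        # sources must be noiseless too for the exactness check
        src = self._sources(cfg, meshes, gt)
        tgt_runs, gt = simulate_targets(src, gt, cfg, meshes=meshes)
        # exact planar distances, matching the generator's coupling kernels
        dists = {}
        for h in HEMIS:
            v = meshes[h].vertices
            d = np.linalg.norm(v[:, None] - v[None, :], axis=2)
            dists[h] = GeodesicDistanceMatrix(dists=d, vertex_ids=np.arange(42),
                                              hemisphere=h)
        for t, row in gt.targets.iterrows():
            prof = cf_profile(int(row.v0), row.sigma_cf, dists[row.hemisphere])
            pred = zscore(prof @ src[row.hemisphere][0].data)
            r = np.corrcoef(tgt_runs[0].data[t], pred)[0, 1]
            assert r > 0.9999

    def test_pure_null_targets_track_mean_signal(self):
        cfg = SyntheticConfig(mesh_rows=6, mesh_cols=7, n_runs=1,
                              n_timepoints_per_run=80, noise_sd=0.0,
                              null_fraction=1.0, n_targets=5, seed=4)
        meshes = {h: make_mesh(6, 7, hemisphere=h) for h in HEMIS}
        gt = GroundTruth(prf={h: make_retinotopic_map(meshes[h]) for h in HEMIS})
        src = self._sources(cfg, meshes, gt)
        tgt_runs, gt = simulate_targets(src, gt, cfg, meshes=meshes)
        assert gt.targets.is_null.all()
        mean_sig = zscore(np.vstack([src[h][0].data for h in HEMIS]).mean(axis=0))
        for t in range(5):
            assert np.corrcoef(tgt_runs[0].data[t], mean_sig)[0, 1] > 0.999

    def test_ground_truth_not_consumed_by_fitting(self):
        # the recovery contract: targets table records v0/sigma per target
        cfg = SyntheticConfig(mesh_rows=6, mesh_cols=7, n_targets=10, seed=1)
        meshes = {h: make_mesh(6, 7, hemisphere=h) for h in HEMIS}
        tab = plant_targets(meshes, cfg)
        assert len(tab) == 10
        assert set(tab.hemisphere) == {"L", "R"}
        assert tab.v0.between(0, 41).all()
        assert tab.sigma_cf.isin(cfg.cf_sigma_choices).all()


class TestSimulateDataset:
    def test_bit_identical_regeneration(self, tiny_config):
        a = simulate_dataset(tiny_config, ("rest",))
        b = simulate_dataset(tiny_config, ("rest",))
        assert np.array_equal(
            a.condition_targets["rest"][0].data, b.condition_targets["rest"][0].data
        )
        assert a.ground_truth.targets.equals(b.ground_truth.targets)

    def test_condition_modes(self, tiny_config):
        ds = simulate_dataset(tiny_config, ("rest", "movie"),
                              condition_modes={"movie": "stimulated"})
        assert ds.condition_source["movie"]["L"][0].condition == "movie"
        # stimulated runs see different clips: run time courses differ in
        # their clean structure, resting ones too (different latents)
        assert len(ds.condition_targets["movie"]) == tiny_config.n_runs
        with pytest.raises(ValueError, match="mode"):
            simulate_dataset(tiny_config, ("rest",), condition_modes={"rest": "nap"})

    def test_ground_truth_validation(self, tiny_config):
        ds = simulate_dataset(tiny_config, ("rest",))
        bad = ds.ground_truth
        bad.targets.loc[0, "v0"] = 10_000
        with pytest.raises(ValueError, match="v0"):
            bad.validate(ds.meshes)
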