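"""Synthetic surface data with planted pRF and connective-field structure.

The generator builds, per hemisphere, a planar retinotopically organized
source sheet (a stand-in for V1 on the midgray surface), stimulus aperture
movies, stimulus-driven or resting-state source time courses, and target
time courses coupled to the sheet through Gaussian connective-field
kernels plus a global (mean-signal) nuisance component — so every
downstream stage can be tested against known ground truth.

Planar grids keep the geometry oracles exact (geodesic = Euclidean), and
the generator computes its coupling kernels from exact planar distances,
independently of the heat-method solver used at fit time. No hemodynamic
convolution is applied: the connective-field stage correlates raw
z-scored signals.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .geometry import InvalidGeometryError, TriangleMesh
from .preprocess import TimecourseMatrix, zscore
from .prf import StimulusAperture, _gaussian_overlap

HEMIS = ("L", "R")


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic dataset.

    Defaults emulate multi-run surface acquisitions at 1 Hz: two
    hemispheres of 20 x 25 = 500 source vertices at 1 mm spacing, four
    runs of 300 s, 200 targets, mid-level noise giving target within-set
    r^2 near 0.3.
    """

    mesh_rows: int = 20
    mesh_cols: int = 25
    vertex_spacing: float = 1.0  # mm
    n_runs: int = 4
    n_timepoints_per_run: int = 300
    sampling_rate: float = 1.0  # Hz
    noise_sd: float = 1.5  # z-units
    global_coupling: float = 0.3  # weight of mean-source signal in targets
    spatial_corr_length: float = 2.0  # mm, resting-state latent field
    seed: int = 0
    # target planting
    n_targets: int = 200
    null_fraction: float = 0.0  # fraction of pure-null (mean-driven) targets
    cf_sigma_choices: tuple = (2.0, 3.0, 5.0, 7.0)  # mm, planted CF sizes
    cf_amplitude: float = 1.0
    # retinotopy
    ecc_range: tuple = (0.25, 7.0)  # degrees
    angle_range: tuple = (-80.0, 80.0)  # degrees around the horizontal meridian
    field_radius: float = 8.0  # degrees
    prf_sigma_intercept: float = 0.15  # degrees
    prf_sigma_slope: float = 0.15  # degrees per degree eccentricity

    def __post_init__(self):
        for name in ("mesh_rows", "mesh_cols", "n_runs", "n_timepoints_per_run",
                     "n_targets"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.vertex_spacing <= 0:
            raise ValueError("vertex_spacing must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    def rng(self, *names) -> np.random.Generator:
        """Named random stream derived from the root seed.

        Stream keys are hashed with crc32 (stable across processes, unlike
        built-in ``hash``), so identical configs regenerate bit-identical
        data.
        """
        digest = [self.seed] + [zlib.crc32(str(n).encode()) for n in names]
        return np.random.default_rng(np.random.SeedSequence(digest))


@dataclass
class GroundTruth:
    """Planted parameters, for recovery tests only (never used in fitting).

    ``prf`` maps hemisphere -> dict of per-source-vertex arrays
    (x0, y0, sigma in degrees). ``targets`` is a table with one row per
    target: hemisphere, v0 (source vertex id), sigma_cf (mm), is_null,
    global_coupling.
    """

    prf: dict = field(default_factory=dict)
    targets: pd.DataFrame | None = None

    def validate(self, meshes: dict):
        for h, p in self.prf.items():
            if np.any(p["sigma"] <= 0):
                raise ValueError("planted pRF sigma must be positive")
        if self.targets is not None:
            if np.any(self.targets["sigma_cf"] <= 0):
                raise ValueError("planted CF sigma must be positive")
            for h, grp in self.targets.groupby("hemisphere"):
                n = meshes[h].n_vertices
                if grp["v0"].min() < 0 or grp["v0"].max() >= n:
                    raise ValueError("target v0 indexes outside the source mesh")


def make_mesh(rows: int, cols: int, spacing: float = 1.0, hemisphere: str = "L") -> TriangleMesh:
    """Planar regular triangulated grid of rows x cols vertices.

    Quads are split along alternating diagonals (checkerboard), which keeps
    the triangulation isotropic. The whole sheet is labeled "V1".
    """
    if rows < 2 or cols < 2:
        raise InvalidGeometryError("mesh needs rows >= 2 and cols >= 2")
    if spacing <= 0:
        raise InvalidGeometryError("spacing must be positive")
    xs, ys = np.meshgrid(np.arange(cols), np.arange(rows))
    verts = np.c_[xs.ravel() * spacing, ys.ravel() * spacing, np.zeros(rows * cols)]
    faces = []
    for r in range(rows - 1):
        for c in range(cols - 1):
            a = r * cols + c
            b = a + 1
            cc = a + cols
            d = cc + 1
            if (r + c) % 2 == 0:
                faces += [[a, b, d], [a, d, cc]]
            else:
                faces += [[a, b, cc], [b, d, cc]]
    mesh = TriangleMesh(verts, np.array(faces, dtype=np.int64), hemisphere)
    mesh.region_labels["V1"] = np.arange(rows * cols, dtype=np.int64)
    return mesh


def make_retinotopic_map(
    mesh: TriangleMesh,
    ecc_range: tuple = (0.25, 7.0),
    angle_range: tuple = (-80.0, 80.0),
    sigma_intercept: float = 0.15,
    sigma_slope: float = 0.15,
) -> dict:
    """Plant a smooth retinotopic map on a grid mesh.

    Eccentricity increases linearly along the x (column) axis, polar angle
    along the y (row) axis; pRF size grows linearly with eccentricity. The
    left hemisphere maps the right visual hemifield (x0 >= 0) and vice
    versa, implemented by measuring the planted angle from the horizontal
    meridian of the appropriate hemifield.
    """
    if mesh.n_vertices == 0:
        raise InvalidGeometryError("empty mesh")
    x = mesh.vertices[:, 0]
    y = mesh.vertices[:, 1]

    def unit(v):
        span = v.max() - v.min()
        return (v - v.min()) / span if span > 0 else np.zeros_like(v)

    ecc = ecc_range[0] + unit(x) * (ecc_range[1] - ecc_range[0])
    ang = angle_range[0] + unit(y) * (angle_range[1] - angle_range[0])
    theta = np.radians(ang)
    if mesh.hemisphere == "R":
        theta = np.pi - theta  # left hemifield
    x0 = ecc * np.cos(theta)
    y0 = ecc * np.sin(theta)
    sigma = sigma_intercept + sigma_slope * ecc
    return {"x0": x0, "y0": y0, "sigma": sigma}


def _bar_frames(n_frames, radius, res):
    """Bar sweeps in 4 directions (R, U, L, D), width radius/4."""
    c = np.linspace(-radius, radius, res)
    X, Y = np.meshgrid(c, c)
    disk = X**2 + Y**2 <= radius**2
    width = radius / 4.0
    frames = np.zeros((n_frames, res, res))
    n_dir = max(n_frames // 4, 1)
    axes = [X, Y, -X, -Y]
    for f in range(n_frames):
        d = min(f // n_dir, 3)
        step = f - d * n_dir
        frac = (step + 0.5) / n_dir
        center = -radius - width / 2 + frac * (2 * radius + width)
        along = axes[d]
        frames[f] = ((np.abs(along - center) <= width / 2) & disk).astype(float)
    return frames


def _wedge_frames(n_frames, radius, res):
    """A 90-degree wedge rotating one full cycle."""
    c = np.linspace(-radius, radius, res)
    X, Y = np.meshgrid(c, c)
    disk = X**2 + Y**2 <= radius**2
    ang = np.arctan2(Y, X)
    half = np.pi / 4
    frames = np.zeros((n_frames, res, res))
    for f in range(n_frames):
        center = 2 * np.pi * f / n_frames
        delta = np.angle(np.exp(1j * (ang - center)))
        frames[f] = ((np.abs(delta) <= half) & disk).astype(float)
    return frames


def _noise_frames(n_frames, radius, res, rng, blob_deg, fill):
    """Random smoothed binary patterns (naturalistic / multifocal drive)."""
    c = np.linspace(-radius, radius, res)
    X, Y = np.meshgrid(c, c)
    disk = X**2 + Y**2 <= radius**2
    px_sigma = blob_deg / (2.0 * radius / (res - 1))
    smooth = gaussian_filter(
        rng.standard_normal((n_frames, res, res)), sigma=(0, px_sigma, px_sigma)
    )
    thr = np.quantile(smooth, 1.0 - fill)
    return ((smooth > thr) & disk).astype(float)


def make_aperture(
    kind: str,
    field_radius: float = 8.0,
    n_frames: int = 150,
    grid_res: int = 101,
    frame_rate: float = 1.0,
    pad: int = 0,
    rng: np.random.Generator | None = None,
    blob_deg: float = 1.0,
    fill: float = 0.3,
) -> StimulusAperture:
    """Binary stimulus aperture movie: bar sweep, rotating wedge, or noise.

    The ``noise`` kind draws random smoothed binary patterns (a stand-in
    for rich naturalistic stimulation such as movie clips; ``blob_deg``
    sets the pattern scale and ``fill`` the stimulated fraction) and
    requires ``rng``. ``pad`` adds that many all-zero frames at the start
    and end (mean luminance / blank periods).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if kind == "bar":
        frames = _bar_frames(n_frames, field_radius, grid_res)
    elif kind == "wedge":
        frames = _wedge_frames(n_frames, field_radius, grid_res)
    elif kind == "noise":
        if rng is None:
            raise ValueError("the 'noise' aperture kind requires an rng")
        frames = _noise_frames(n_frames, field_radius, grid_res, rng, blob_deg, fill)
    else:
        raise ValueError(
            f"unknown aperture kind {kind!r}; use 'bar', 'wedge' or 'noise'"
        )
    if pad:
        z = np.zeros((pad, grid_res, grid_res))
        frames = np.concatenate([z, frames, z])
    return StimulusAperture(frames=frames, field_radius=field_radius, frame_rate=frame_rate)


def _planar_dists(mesh: TriangleMesh) -> np.ndarray:
    p = mesh.vertices
    return np.linalg.norm(p[:, None, :] - p[None, :, :], axis=2)


def simulate_source(
    mesh: TriangleMesh,
    ground_truth: GroundTruth,
    config: SyntheticConfig,
    aperture: StimulusAperture | None = None,
    resting: bool = False,
    condition: str | None = None,
) -> list[TimecourseMatrix]:
    """Source-sheet time courses, one :class:`TimecourseMatrix` per run.

    Stimulated mode: each vertex's clean signal is its pRF-aperture overlap
    series (z-scored), plus white noise; ``aperture`` may be a single
    :class:`StimulusAperture` shown in every run or a list with one
    aperture per run (distinct clips per run). Resting mode: a latent
    field of white noise smoothed over the sheet with a Gaussian kernel of
    the configured correlation length (plus mild temporal smoothing), plus
    white noise. Runs are independent given the seed stream.
    """
    hemi = mesh.hemisphere
    if hemi not in ground_truth.prf:
        raise ValueError(f"ground truth has no pRF map for hemisphere {hemi}")
    p = ground_truth.prf[hemi]
    if len(p["x0"]) != mesh.n_vertices:
        raise ValueError("ground truth does not cover all mesh vertices")
    condition = condition or ("rest" if resting else "retinotopy")
    T = config.n_timepoints_per_run
    runs = []
    if not resting:
        if aperture is None:
            raise ValueError("stimulated mode requires a stimulus aperture")
        apertures = (
            list(aperture) if isinstance(aperture, (list, tuple)) else
            [aperture] * config.n_runs
        )
        if len(apertures) != config.n_runs:
            raise ValueError(
                f"{len(apertures)} apertures supplied for {config.n_runs} runs"
            )
        clean_runs = []
        clean_cache: dict[int, np.ndarray] = {}
        for ap in apertures:
            if id(ap) in clean_cache:
                clean_runs.append(clean_cache[id(ap)])
                continue
            X, Y = ap.coords()
            Xf, Yf = X.ravel(), Y.ravel()
            A = ap.flat()
            G = np.exp(
                -((Xf[None, :] - p["x0"][:, None]) ** 2
                  + (Yf[None, :] - p["y0"][:, None]) ** 2)
                / (2.0 * p["sigma"][:, None] ** 2)
            )
            clean = zscore(G @ A.T)  # (V, n_frames)
            if clean.shape[1] != T:
                raise ValueError(
                    f"aperture has {clean.shape[1]} frames but runs have {T} timepoints"
                )
            clean_cache[id(ap)] = clean
            clean_runs.append(clean)
    else:
        d = _planar_dists(mesh)
        K = np.exp(-(d**2) / (2.0 * config.spatial_corr_length**2))

    for r in range(config.n_runs):
        rng = config.rng("source", condition, hemi, r)
        if resting:
            w = rng.standard_normal((mesh.n_vertices, T))
            latent = K @ w
            latent = gaussian_filter1d(latent, sigma=2.0, axis=-1, mode="reflect")
            sig = zscore(latent)
        else:
            sig = clean_runs[r]
        noise = config.noise_sd * rng.standard_normal((mesh.n_vertices, T))
        runs.append(
            TimecourseMatrix(
                data=sig + noise,
                vertex_ids=np.arange(mesh.n_vertices),
                sampling_rate=config.sampling_rate,
                run_id=f"run-{r + 1}",
                condition=condition,
                hemisphere=hemi,
            )
        )
    return runs


def expected_resting_correlation(mesh: TriangleMesh, config: SyntheticConfig) -> np.ndarray:
    """Analytic spatial correlation matrix of the noise-free latent field.

    With latent = K w (w white in space), cov = K K^T; the temporal filter
    is shared across vertices and leaves spatial correlations unchanged.
    """
    d = _planar_dists(mesh)
    K = np.exp(-(d**2) / (2.0 * config.spatial_corr_length**2))
    C = K @ K.T
    s = np.sqrt(np.diag(C))
    return C / np.outer(s, s)


def plant_targets(meshes: dict, config: SyntheticConfig) -> pd.DataFrame:
    """Draw planted target CFs: hemisphere, center vertex, size, null flag.

    Centers are drawn away from the sheet border (one planted-sigma margin
    where possible) so planted kernels are mostly contained in the source
    region. The first ``null_fraction`` of targets are pure-null
    (mean-signal-driven only).
    """
    rng = config.rng("targets")
    n = config.n_targets
    hemis = [HEMIS[i % 2] for i in range(n)]
    rows = []
    n_null = int(round(config.null_fraction * n))
    for t in range(n):
        hemi = hemis[t]
        mesh = meshes[hemi]
        sigma = float(rng.choice(config.cf_sigma_choices))
        margin = min(sigma, (min(config.mesh_rows, config.mesh_cols) - 1)
                     * config.vertex_spacing / 2.5)
        x = mesh.vertices[:, 0]
        y = mesh.vertices[:, 1]
        inner = (
            (x >= x.min() + margin) & (x <= x.max() - margin)
            & (y >= y.min() + margin) & (y <= y.max() - margin)
        )
        pool = np.flatnonzero(inner)
        if pool.size == 0:
            pool = np.arange(mesh.n_vertices)
        v0 = int(rng.choice(pool))
        rows.append(
            dict(
                target_id=t,
                hemisphere=hemi,
                v0=v0,
                sigma_cf=sigma,
                is_null=t < n_null,
                global_coupling=config.global_coupling,
            )
        )
    return pd.DataFrame(rows)


def simulate_targets(
    source_tcs: dict,
    ground_truth: GroundTruth,
    config: SyntheticConfig,
    meshes: dict | None = None,
    condition: str = "rest",
) -> tuple[list[TimecourseMatrix], GroundTruth]:
    """Target time courses coupled to the source sheet via planted CFs.

    ``source_tcs`` maps hemisphere -> list of per-run source
    :class:`TimecourseMatrix`. Each non-null target is the z-scored
    CF-weighted sum of its hemisphere's source signals, plus
    ``global_coupling`` times the z-scored mean source signal (across both
    hemispheres), plus white noise. Pure-null targets receive only the
    mean-signal drive (unit weight) plus noise.
    """
    if ground_truth.targets is None:
        if meshes is None:
            raise ValueError("meshes required to plant targets")
        ground_truth.targets = plant_targets(meshes, config)
        if meshes is not None:
            ground_truth.validate(meshes)
    tg = ground_truth.targets
    hemis = sorted(source_tcs.keys())
    n_runs = len(source_tcs[hemis[0]])

    # CF weights from exact planar distances, per hemisphere
    weights = {}
    for hemi in hemis:
        if meshes is not None:
            d = _planar_dists(meshes[hemi])
        else:
            raise ValueError("meshes required to build coupling kernels")
        sel = tg["hemisphere"] == hemi
        w = np.exp(
            -(d[tg.loc[sel, "v0"].to_numpy()] ** 2)
            / (2.0 * tg.loc[sel, "sigma_cf"].to_numpy()[:, None] ** 2)
        )
        weights[hemi] = (np.flatnonzero(sel.to_numpy()), w)

    out_runs = []
    for r in range(n_runs):
        rng = config.rng("target-noise", condition, r)
        T = source_tcs[hemis[0]][r].n_timepoints
        y = np.zeros((len(tg), T))
        all_src = np.vstack([source_tcs[h][r].data for h in hemis])
        zmean = zscore(all_src.mean(axis=0))
        for hemi in hemis:
            rows, w = weights[hemi]
            if len(rows) == 0:
                continue
            pred = zscore(w @ source_tcs[hemi][r].data)
            y[rows] = config.cf_amplitude * pred
        is_null = tg["is_null"].to_numpy()
        y[is_null] = 0.0
        coupling = np.where(is_null, 1.0, tg["global_coupling"].to_numpy())
        y += coupling[:, None] * zmean[None, :]
        y += config.noise_sd * rng.standard_normal(y.shape)
        out_runs.append(
            TimecourseMatrix(
                data=y,
                vertex_ids=tg["target_id"].to_numpy(),
                sampling_rate=config.sampling_rate,
                run_id=f"run-{r + 1}",
                condition=condition,
            )
        )
    return out_runs, ground_truth


@dataclass
class SyntheticDataset:
    """Everything the pipeline needs, generated from one config."""

    config: SyntheticConfig
    meshes: dict
    ground_truth: GroundTruth
    aperture: StimulusAperture
    retinotopy_source: dict  # hemi -> list of runs
    condition_source: dict  # condition -> hemi -> list of runs
    condition_targets: dict  # condition -> list of runs


def simulate_dataset(
    config: SyntheticConfig,
    conditions: tuple = ("rest", "movie"),
    condition_modes: dict | None = None,
) -> SyntheticDataset:
    """Generate meshes, maps, apertures, and all source/target runs.

    The retinotopy condition is stimulus-driven (bar then wedge sweeps in
    a single aperture movie); the listed ``conditions`` default to
    resting-mode acquisitions with independent seed streams, all sharing
    one planted CF ground truth so cross-state stability can be assessed.
    ``condition_modes`` optionally maps a condition name to ``"resting"``
    or ``"stimulated"``; a stimulated condition drives the source sheet
    with per-run random-pattern ("noise") aperture movies — a stand-in for
    naturalistic viewing with distinct clips per run — and couples targets
    to those runs through the same planted CFs.
    """
    condition_modes = condition_modes or {}
    for cond, mode in condition_modes.items():
        if mode not in ("resting", "stimulated"):
            raise ValueError(
                f"condition {cond!r}: mode must be 'resting' or 'stimulated'"
            )
    meshes = {
        h: make_mesh(config.mesh_rows, config.mesh_cols, config.vertex_spacing, h)
        for h in HEMIS
    }
    gt = GroundTruth()
    for h in HEMIS:
        gt.prf[h] = make_retinotopic_map(
            meshes[h],
            config.ecc_range,
            config.angle_range,
            config.prf_sigma_intercept,
            config.prf_sigma_slope,
        )
    T = config.n_timepoints_per_run
    n_bar = int(round(0.6 * T))
    bar = make_aperture("bar", config.field_radius, n_bar, frame_rate=config.sampling_rate)
    wedge = make_aperture("wedge", config.field_radius, T - n_bar,
                          frame_rate=config.sampling_rate)
    aperture = StimulusAperture(
        frames=np.concatenate([bar.frames, wedge.frames]),
        field_radius=config.field_radius,
        frame_rate=config.sampling_rate,
    )
    retino = {
        h: simulate_source(meshes[h], gt, config, aperture=aperture,
                           condition="retinotopy")
        for h in HEMIS
    }
    gt.targets = plant_targets(meshes, config)
    gt.validate(meshes)
    cond_source = {}
    cond_targets = {}
    for cond in conditions:
        stim = condition_modes.get(cond, "resting") == "stimulated"
        if stim:
            movies = [
                make_aperture(
                    "noise", config.field_radius, T,
                    frame_rate=config.sampling_rate,
                    rng=config.rng("aperture", cond, r),
                )
                for r in range(config.n_runs)
            ]
        cond_source[cond] = {
            h: simulate_source(
                meshes[h], gt, config,
                aperture=movies if stim else None,
                resting=not stim,
                condition=cond,
            )
            for h in HEMIS
        }
        cond_targets[cond], _ = simulate_targets(
            cond_source[cond], gt, config, meshes=meshes, condition=cond
        )
    return SyntheticDataset(
        config=config,
        meshes=meshes,
        ground_truth=gt,
        aperture=aperture,
        retinotopy_source=retino,
        condition_source=cond_source,
        condition_targets=cond_targets,
    )
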