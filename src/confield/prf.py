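"""Population receptive field (pRF) estimation.

Each cortical site's visual selectivity is modeled as an isotropic 2D
Gaussian in visual space,

    g(x, y) = exp(-((x - x0)^2 + (y - y0)^2) / (2 sigma^2)),

whose overlap with the stimulus aperture movie, scaled by a signed gain
plus baseline (optionally convolved with a canonical hemodynamic
response), predicts the site's time course. Fitting proceeds in two
stages: an exhaustive grid search, then bounded L-BFGS-B refinement.

The fitted map anchors connective-field centers to visual-field
coordinates and provides the eligibility filter for candidate CF centers
(within-set R^2 > 0.2, peak inside the aperture, positive amplitude).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.optimize import minimize

from .preprocess import TimecourseMatrix


@dataclass
class StimulusAperture:
    """Stimulus aperture movie on a square visual-field grid.

    ``frames`` is (n_frames, res, res), binary or grayscale. Coordinates
    are degrees of visual angle, x right-positive, y up-positive, origin at
    fixation; the grid is square and centered.
    """

    frames: np.ndarray
    field_radius: float
    frame_rate: float = 1.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != self.frames.shape[2]:
            raise ValueError("frames must be (n_frames, res, res)")
        if self.field_radius <= 0:
            raise ValueError("field_radius must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def grid_res(self) -> int:
        return self.frames.shape[1]

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-center coordinate grids (X, Y) in degrees."""
        c = np.linspace(-self.field_radius, self.field_radius, self.grid_res)
        X, Y = np.meshgrid(c, c)
        return X, Y

    def flat(self) -> np.ndarray:
        return self.frames.reshape(self.n_frames, -1)


@dataclass
class PRFParams:
    """Per-vertex Gaussian pRF parameters (arrays, one entry per vertex)."""

    x0: np.ndarray
    y0: np.ndarray
    sigma: np.ndarray
    amplitude: np.ndarray
    baseline: np.ndarray
    r2: np.ndarray
    vertex_ids: np.ndarray | None = None
    warning: np.ndarray = field(default=None)  # optimizer-failure flags

    def __post_init__(self):
        for name in ("x0", "y0", "sigma", "amplitude", "baseline", "r2"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), float)))
        n = len(self.x0)
        if self.vertex_ids is None:
            self.vertex_ids = np.arange(n, dtype=np.int64)
        self.vertex_ids = np.asarray(self.vertex_ids, dtype=np.int64)
        if self.warning is None:
            self.warning = np.zeros(n, dtype=bool)
        if np.any(self.sigma <= 0):
            raise ValueError("pRF sigma must be positive")
        if np.any(self.r2 > 1 + 1e-12):
            raise ValueError("r2 cannot exceed 1")

    def __len__(self) -> int:
        return len(self.x0)

    @property
    def eccentricity(self) -> np.ndarray:
        return np.hypot(self.x0, self.y0)

    @property
    def polar_angle(self) -> np.ndarray:
        """Polar angle in degrees, 0 = right horizontal meridian, CCW."""
        return np.degrees(np.arctan2(self.y0, self.x0))


def double_gamma_hrf(dt: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, peak-normalized.

    Peak at 6 s, undershoot at 16 s with 1:6 amplitude ratio (the common
    canonical parameterization), sampled at ``dt`` seconds.
    """
    from scipy.stats import gamma as gamma_dist

    t = np.arange(0, duration, dt)
    h = gamma_dist.pdf(t, 6) - gamma_dist.pdf(t, 16) / 6.0
    return h / h.max()


def _gaussian_overlap(x0, y0, sigma, aperture: StimulusAperture) -> np.ndarray:
    X, Y = aperture.coords()
    g = np.exp(-((X - x0) ** 2 + (Y - y0) ** 2) / (2.0 * sigma**2))
    return aperture.flat() @ g.ravel()


def prf_predict(
    x0: float,
    y0: float,
    sigma: float,
    aperture: StimulusAperture,
    amplitude: float = 1.0,
    baseline: float = 0.0,
    hrf: np.ndarray | None = None,
) -> np.ndarray:
    """Predicted time course: aperture-Gaussian overlap per frame.

    With ``hrf`` given, the overlap series is convolved with it (causal,
    truncated to the run length) before scaling.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    overlap = _gaussian_overlap(x0, y0, sigma, aperture)
    if hrf is not None:
        overlap = np.convolve(overlap, hrf)[: len(overlap)]
    return amplitude * overlap + baseline


def _as_data(tc) -> np.ndarray:
    if isinstance(tc, TimecourseMatrix):
        return tc.data
    return np.atleast_2d(np.asarray(tc, dtype=float))


def _grid_combos(x0_grid, y0_grid, sigma_grid) -> np.ndarray:
    return np.array(list(product(x0_grid, y0_grid, sigma_grid)), dtype=float)


def _prediction_matrix(combos, aperture, hrf):
    X, Y = aperture.coords()
    Xf, Yf = X.ravel(), Y.ravel()
    A = aperture.flat()  # (T, P)
    G = np.exp(
        -(
            (Xf[None, :] - combos[:, 0:1]) ** 2
            + (Yf[None, :] - combos[:, 1:2]) ** 2
        )
        / (2.0 * combos[:, 2:3] ** 2)
    )
    P = G @ A.T  # (C, T)
    if hrf is not None:
        full = np.apply_along_axis(lambda r: np.convolve(r, hrf)[: P.shape[1]], 1, P)
        P = full
    return P


def prf_grid_fit(
    tc,
    aperture: StimulusAperture,
    x0_grid,
    y0_grid,
    sigma_grid,
    hrf: np.ndarray | None = None,
) -> PRFParams:
    """Exhaustive grid search over (x0, y0, sigma).

    For each vertex the grid combination maximizing within-set R^2 is
    selected; amplitude and baseline follow by least squares. Exact R^2
    ties resolve to the first combination in (x0, y0, sigma) nested-loop
    order, so results are deterministic.
    """
    x0_grid, y0_grid, sigma_grid = map(np.asarray, (x0_grid, y0_grid, sigma_grid))
    if x0_grid.size == 0 or y0_grid.size == 0 or sigma_grid.size == 0:
        raise ValueError("parameter grids must be nonempty")
    if np.any(sigma_grid <= 0):
        raise ValueError("sigma grid must be positive")
    Y = _as_data(tc)
    vertex_ids = tc.vertex_ids if isinstance(tc, TimecourseMatrix) else None
    combos = _grid_combos(x0_grid, y0_grid, sigma_grid)
    P = _prediction_matrix(combos, aperture, hrf)  # (C, T)

    Pc = P - P.mean(axis=1, keepdims=True)
    pnorm = np.linalg.norm(Pc, axis=1)
    ok = pnorm > 0
    Pn = np.zeros_like(Pc)
    Pn[ok] = Pc[ok] / pnorm[ok, None]

    Yc = Y - Y.mean(axis=1, keepdims=True)
    ynorm = np.linalg.norm(Yc, axis=1)
    yok = ynorm > 0
    Yn = np.zeros_like(Yc)
    Yn[yok] = Yc[yok] / ynorm[yok, None]

    R = Pn @ Yn.T  # (C, V) correlations
    best = np.argmax(R**2, axis=0)  # first occurrence wins ties
    rbest = R[best, np.arange(Y.shape[0])]
    r2 = rbest**2

    amp = np.zeros(Y.shape[0])
    sel_ok = ok[best] & yok
    amp[sel_ok] = (
        rbest[sel_ok] * ynorm[sel_ok] / pnorm[best[sel_ok]]
    )
    baseline = Y.mean(axis=1) - amp * P.mean(axis=1)[best]
    r2 = np.where(sel_ok, r2, 0.0)

    return PRFParams(
        x0=combos[best, 0],
        y0=combos[best, 1],
        sigma=combos[best, 2],
        amplitude=amp,
        baseline=baseline,
        r2=r2,
        vertex_ids=vertex_ids,
    )


def _fit_one_vertex(y, aperture, hrf, init, bounds):
    yc = y - y.mean()
    ss = float(yc @ yc)
    if ss == 0:
        return init + (0.0, 0.0, 0.0), True

    def neg_r2(theta):
        x0, y0, sig = theta
        p = _gaussian_overlap(x0, y0, sig, aperture)
        if hrf is not None:
            p = np.convolve(p, hrf)[: len(p)]
        pc = p - p.mean()
        denom = float(pc @ pc)
        if denom <= 0:
            return 1.0
        return -float((yc @ pc) ** 2 / (denom * ss))

    res = minimize(
        neg_r2,
        x0=np.asarray(init, dtype=float),
        method="L-BFGS-B",
        bounds=bounds,
    )
    x0, y0, sig = res.x
    r2 = -neg_r2(res.x)
    p = _gaussian_overlap(x0, y0, sig, aperture)
    if hrf is not None:
        p = np.convolve(p, hrf)[: len(p)]
    pc = p - p.mean()
    denom = float(pc @ pc)
    a = float(yc @ pc) / denom if denom > 0 else 0.0
    b = float(y.mean() - a * p.mean())
    return (x0, y0, sig, a, b, r2), not res.success


def prf_iterative_fit(
    tc,
    aperture: StimulusAperture,
    init: PRFParams,
    bounds=None,
    hrf: np.ndarray | None = None,
    r2_tolerance: float = 1e-6,
) -> PRFParams:
    """Bounded L-BFGS-B refinement of grid-fit parameters.

    Refinement never worsens within-set R^2 beyond ``r2_tolerance``: if the
    optimizer fails or regresses, the grid-fit parameters are returned for
    that vertex with its warning flag set.
    """
    Y = _as_data(tc)
    if bounds is None:
        r = 1.5 * aperture.field_radius
        bounds = [(-r, r), (-r, r), (1e-3, 2 * aperture.field_radius)]
    out = {k: [] for k in ("x0", "y0", "sigma", "amplitude", "baseline", "r2")}
    warn = []
    for v in range(Y.shape[0]):
        theta0 = (init.x0[v], init.y0[v], init.sigma[v])
        theta0 = tuple(np.clip(t, lo, hi) for t, (lo, hi) in zip(theta0, bounds))
        (x0, y0, sig, a, b, r2), failed = _fit_one_vertex(
            Y[v], aperture, hrf, theta0, bounds
        )
        if failed or r2 < init.r2[v] - r2_tolerance:
            x0, y0, sig = init.x0[v], init.y0[v], init.sigma[v]
            a, b, r2 = init.amplitude[v], init.baseline[v], init.r2[v]
            failed = True
        out["x0"].append(x0)
        out["y0"].append(y0)
        out["sigma"].append(sig)
        out["amplitude"].append(a)
        out["baseline"].append(b)
        out["r2"].append(r2)
        warn.append(failed)
    return PRFParams(
        **{k: np.array(v) for k, v in out.items()},
        vertex_ids=init.vertex_ids,
        warning=np.array(warn, dtype=bool),
    )


def select_cf_centers(
    prfs: PRFParams,
    aperture: StimulusAperture | float,
    r2_threshold: float = 0.2,
) -> np.ndarray:
    """Eligible CF-center vertices: well-fit, in-aperture, positive gain.

    Keeps vertices with within-set R^2 > ``r2_threshold``, peak pRF
    position inside the stimulus aperture (eccentricity <= field radius)
    and positive pRF amplitude; input order is preserved. Raises if no
    vertex qualifies.
    """
    radius = aperture.field_radius if isinstance(aperture, StimulusAperture) else float(aperture)
    keep = (
        (prfs.r2 > r2_threshold)
        & (prfs.eccentricity <= radius)
        & (prfs.amplitude > 0)
    )
    idx = prfs.vertex_ids[keep]
    if idx.size == 0:
        raise ValueError(
            "no vertices pass the CF-center eligibility criteria; review the "
            f"r2 threshold ({r2_threshold}) and fit quality"
        )
    return idx
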