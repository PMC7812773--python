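"""Connective-field (CF) model fitting.

A connective field explains a target vertex's time course as a
Gaussian-weighted sum of source-region (V1) signals on the cortical
surface:

    CF(v0, v, sigma) = exp(-|v - v0|^2 / (2 sigma^2)),

with |v - v0| the geodesic distance in mm between source vertices and v0
the CF center. Candidate models (eligible centers x a fixed sigma grid,
both hemispheres pooled) are scored by squared Pearson correlation between
the z-scored model time course and the target, without hemodynamic
convolution. Selection is cross-validated leave-one-run-out, and
out-of-set performance is referenced against a nontopographic null model
— the average source time course — to isolate topographically specific
connectivity.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import GeodesicDistanceMatrix
from .preprocess import TimecourseMatrix, zscore

#: Candidate CF sizes in mm, from near-single-vertex to spanning the sheet.
DEFAULT_SIGMA_GRID_MM = (
    0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 7.0, 10.0, 15.0, 20.0, 30.0, 40.0, 80.0
)


def cf_profile(v0: int, sigma: float, dists: GeodesicDistanceMatrix) -> np.ndarray:
    """Gaussian CF weights over one hemisphere's source vertices.

    Weight 1 at the center, decaying with geodesic distance; only vertices
    of the center's hemisphere carry weight (each hemisphere is a separate
    surface).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    i = dists.index_of(v0)
    return np.exp(-(dists.dists[i] ** 2) / (2.0 * sigma**2))


def cf_predict(profile: np.ndarray, source_tc) -> np.ndarray:
    """Z-scored CF model time course: profile-weighted sum of source signals.

    All source-region vertices participate regardless of pRF eligibility;
    vertices outside the source region are never included (the profile is
    defined over the source set only).
    """
    data = source_tc.data if isinstance(source_tc, TimecourseMatrix) else np.asarray(source_tc)
    profile = np.asarray(profile, dtype=float)
    if len(profile) != data.shape[0]:
        raise ValueError(
            f"profile has {len(profile)} weights for {data.shape[0]} source vertices"
        )
    return zscore(profile @ data)


class CandidateSet:
    """All candidate CF models: eligible centers x sigma grid, per hemisphere.

    Candidates are enumerated sigma-major (ascending), then hemisphere in
    the order given, then center in eligible-list order; exact score ties
    therefore resolve to the smallest sigma, then the lowest center index.
    """

    def __init__(
        self,
        centers: dict,
        dists: dict,
        sigmas=DEFAULT_SIGMA_GRID_MM,
    ):
        self.sigmas = np.asarray(sorted(sigmas), dtype=float)
        if np.any(self.sigmas <= 0):
            raise ValueError("sigma grid must be strictly positive")
        if len(np.unique(self.sigmas)) != len(self.sigmas):
            raise ValueError("sigma grid contains duplicates")
        self.hemis = list(centers.keys())
        self.dists = dists
        self.center_vertex_ids = {}
        self.center_pos = {}
        for h in self.hemis:
            ids = np.asarray(centers[h], dtype=np.int64)
            self.center_vertex_ids[h] = ids
            self.center_pos[h] = np.array(
                [dists[h].index_of(v) for v in ids], dtype=np.int64
            )
        # global candidate metadata in enumeration order
        sig_list, hemi_list, vert_list = [], [], []
        for s in self.sigmas:
            for h in self.hemis:
                ids = self.center_vertex_ids[h]
                sig_list.append(np.full(len(ids), s))
                hemi_list.append(np.array([h] * len(ids), dtype=object))
                vert_list.append(ids)
        self.cand_sigma = np.concatenate(sig_list)
        self.cand_hemi = np.concatenate(hemi_list)
        self.cand_vertex = np.concatenate(vert_list)
        self._profiles = {}

    @property
    def n_candidates(self) -> int:
        return len(self.cand_sigma)

    def profiles(self, hemi: str) -> np.ndarray:
        """(n_sigma * n_centers, n_source) profile matrix, sigma-major."""
        if hemi not in self._profiles:
            D = self.dists[hemi].dists[self.center_pos[hemi]]  # (C, V)
            blocks = [
                np.exp(-(D**2) / (2.0 * s**2)) for s in self.sigmas
            ]
            self._profiles[hemi] = np.vstack(blocks)
        return self._profiles[hemi]

    def raw_predictions(self, source_by_hemi: dict) -> np.ndarray:
        """(n_candidates, T) raw (un-normalized) model time courses.

        ``source_by_hemi`` maps hemisphere -> (n_source, T) array or
        :class:`TimecourseMatrix`. Raw predictions are linear in the source
        data, so per-run predictions may be concatenated across runs before
        z-scoring.
        """
        per_hemi = {}
        for h in self.hemis:
            s = source_by_hemi[h]
            data = s.data if isinstance(s, TimecourseMatrix) else np.asarray(s)
            per_hemi[h] = self.profiles(h) @ data
        n_per = {h: len(self.center_vertex_ids[h]) for h in self.hemis}
        blocks = []
        for i, _ in enumerate(self.sigmas):
            for h in self.hemis:
                blocks.append(per_hemi[h][i * n_per[h] : (i + 1) * n_per[h]])
        return np.vstack(blocks)


def _unit_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Demeaned unit-norm rows plus a validity mask (nonzero variance)."""
    xc = x - x.mean(axis=1, keepdims=True)
    nrm = np.linalg.norm(xc, axis=1)
    ok = nrm > 0
    out = np.zeros_like(xc)
    out[ok] = xc[ok] / nrm[ok, None]
    return out, ok


@dataclass
class CFGridFit:
    """Within-set best candidate per target."""

    cand_idx: np.ndarray
    v0: np.ndarray
    hemisphere: np.ndarray
    sigma: np.ndarray
    r: np.ndarray
    valid: np.ndarray


def cf_grid_fit(target_tc, candidates: CandidateSet, source_tcs: dict) -> CFGridFit:
    """Select, per target, the candidate maximizing squared correlation.

    Candidates of both hemispheres compete; the winning hemisphere is the
    laterality proxy. Zero-variance targets are flagged invalid and carry
    r = 0.
    """
    Y = target_tc.data if isinstance(target_tc, TimecourseMatrix) else np.atleast_2d(np.asarray(target_tc, float))
    P = candidates.raw_predictions(source_tcs)
    Pn, _ = _unit_rows(P)
    Yn, yok = _unit_rows(Y)
    R = Pn @ Yn.T  # (C, V) Pearson correlations
    best = np.argmax(R**2, axis=0)  # first max: smallest sigma, lowest center
    r = R[best, np.arange(Y.shape[0])]
    return CFGridFit(
        cand_idx=best,
        v0=candidates.cand_vertex[best],
        hemisphere=candidates.cand_hemi[best],
        sigma=candidates.cand_sigma[best],
        r=np.where(yok, r, 0.0),
        valid=yok,
    )


def null_model_correction(cv_r, null_r, method: str = "difference"):
    """Reference CF out-of-set correlation against the null model's.

    The default (and only built-in) operator is subtraction: corrected
    values are no longer interpretable as correlations but conservatively
    index topographic connectivity above the nontopographic mean-signal
    baseline. Isolated here so an alternative referencing scheme can be
    swapped in one place.
    """
    if method != "difference":
        raise ValueError(f"unknown correction method {method!r}")
    return np.asarray(cv_r, dtype=float) - np.asarray(null_r, dtype=float)


@dataclass
class CFResults:
    """Cross-validated CF fits for a set of targets (arrays per target)."""

    target_ids: np.ndarray
    v0: np.ndarray
    hemisphere: np.ndarray
    sigma_cf: np.ndarray  # modal across folds; always on the sigma grid
    sigma_cf_mean: np.ndarray  # arithmetic mean across folds
    cv_r: np.ndarray
    null_r: np.ndarray
    corrected: np.ndarray
    within_r: np.ndarray  # (n_targets, n_folds)
    cv_r_folds: np.ndarray
    null_r_folds: np.ndarray
    valid: np.ndarray
    condition: str = ""

    @property
    def n_folds(self) -> int:
        return self.within_r.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "target_id": self.target_ids,
                "condition": self.condition,
                "v0": self.v0,
                "hemisphere": self.hemisphere,
                "sigma_cf_mm": self.sigma_cf,
                "sigma_cf_mean_mm": self.sigma_cf_mean,
                "cv_r": self.cv_r,
                "null_r": self.null_r,
                "corrected": self.corrected,
                "valid": self.valid,
            }
        )
        for k in range(self.n_folds):
            df[f"within_r_fold{k + 1}"] = self.within_r[:, k]
            df[f"cv_r_fold{k + 1}"] = self.cv_r_folds[:, k]
            df[f"null_r_fold{k + 1}"] = self.null_r_folds[:, k]
        return df


def _rowwise_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    an, aok = _unit_rows(a)
    bn, bok = _unit_rows(b)
    return np.einsum("ij,ij->i", an, bn), aok & bok


def crossvalidate(
    target_runs: list,
    source_runs: dict,
    candidates: CandidateSet,
    n_folds: int | None = None,
    condition: str = "",
) -> CFResults:
    """Leave-one-run-out cross-validated CF fitting.

    Each fold trains on the concatenation of all runs but one (each run
    preprocessed separately beforehand), selects the best candidate per
    target, then scores that fixed candidate's prediction on the left-out
    run. The nontopographic null model — the z-scored average of all
    source-region time courses — is scored on the same left-out runs.
    Correlations and parameters are averaged across folds: the reported
    center is the geodesic (Frechet) mean of the fold-selected centers
    within the modal hemisphere — the source vertex minimizing the sum of
    squared geodesic distances to the fold winners — and sigma is reported
    both as the modal fold value (on-grid) and as the cross-fold mean.
    """
    n_runs = len(target_runs)
    if n_runs < 2:
        raise ValueError(
            "cross-validation needs >= 2 runs; for a single run use "
            "cf_grid_fit (within-set mode) explicitly"
        )
    if n_folds is None:
        n_folds = n_runs
    if n_folds != n_runs:
        raise ValueError(
            f"leave-one-run-out scheme requires n_folds == n_runs "
            f"({n_folds} != {n_runs})"
        )
    hemis = candidates.hemis
    t_data = [
        t.data if isinstance(t, TimecourseMatrix) else np.atleast_2d(np.asarray(t, float))
        for t in target_runs
    ]
    target_ids = (
        target_runs[0].vertex_ids
        if isinstance(target_runs[0], TimecourseMatrix)
        else np.arange(t_data[0].shape[0])
    )
    s_data = {
        h: [
            s.data if isinstance(s, TimecourseMatrix) else np.asarray(s, float)
            for s in source_runs[h]
        ]
        for h in hemis
    }
    if any(len(s_data[h]) != n_runs for h in hemis):
        raise ValueError("source and target run counts differ")

    # raw candidate predictions and null predictions per run
    raw_preds = [
        candidates.raw_predictions({h: s_data[h][r] for h in hemis})
        for r in range(n_runs)
    ]
    null_pred = [
        zscore(np.vstack([s_data[h][r] for h in hemis]).mean(axis=0))
        for r in range(n_runs)
    ]

    n_targets = t_data[0].shape[0]
    within_r = np.zeros((n_targets, n_runs))
    cv_r_folds = np.zeros((n_targets, n_runs))
    null_r_folds = np.zeros((n_targets, n_runs))
    sel_idx = np.zeros((n_targets, n_runs), dtype=np.int64)
    valid = np.ones(n_targets, dtype=bool)

    for k in range(n_runs):
        train = [r for r in range(n_runs) if r != k]
        P_tr = np.concatenate([raw_preds[r] for r in train], axis=1)
        Y_tr = np.concatenate([t_data[r] for r in train], axis=1)
        Pn, _ = _unit_rows(P_tr)
        Yn, yok = _unit_rows(Y_tr)
        R = Pn @ Yn.T
        best = np.argmax(R**2, axis=0)
        sel_idx[:, k] = best
        within_r[:, k] = np.where(yok, R[best, np.arange(n_targets)], 0.0)

        P_te = raw_preds[k][best]
        r_te, ok_te = _rowwise_corr(P_te, t_data[k])
        cv_r_folds[:, k] = np.where(ok_te, r_te, 0.0)
        n_te, ok_n = _rowwise_corr(
            np.broadcast_to(null_pred[k], t_data[k].shape), t_data[k]
        )
        null_r_folds[:, k] = np.where(ok_n, n_te, 0.0)
        valid &= yok & ok_te

    # aggregate parameters across folds
    v0 = np.zeros(n_targets, dtype=np.int64)
    hemi_out = np.empty(n_targets, dtype=object)
    sigma_modal = np.zeros(n_targets)
    for t in range(n_targets):
        fold_hemis = [candidates.cand_hemi[c] for c in sel_idx[t]]
        hcounts = Counter(fold_hemis)
        top = max(hcounts.values())
        # hemisphere ties resolve in configured hemisphere order
        hmod = sorted(
            [h for h, c in hcounts.items() if c == top], key=hemis.index
        )[0]
        hemi_out[t] = hmod
        # Frechet mean of the fold-selected centers on the surface: the
        # source vertex minimizing the summed squared geodesic distance to
        # the winners (argmin takes the lowest vertex id on exact ties)
        D = candidates.dists[hmod]
        sel_pos = [
            D.index_of(int(candidates.cand_vertex[c]))
            for c in sel_idx[t]
            if candidates.cand_hemi[c] == hmod
        ]
        cost = (D.dists[sel_pos] ** 2).sum(axis=0)
        v0[t] = int(D.vertex_ids[int(np.argmin(cost))])
        sig = candidates.cand_sigma[sel_idx[t]]
        scounts = Counter(sig)
        stop = max(scounts.values())
        sigma_modal[t] = min(s for s, c in scounts.items() if c == stop)

    cv_r = cv_r_folds.mean(axis=1)
    null_r = null_r_folds.mean(axis=1)
    return CFResults(
        target_ids=np.asarray(target_ids),
        v0=v0,
        hemisphere=hemi_out,
        sigma_cf=sigma_modal,
        sigma_cf_mean=candidates.cand_sigma[sel_idx].mean(axis=1),
        cv_r=cv_r,
        null_r=null_r,
        corrected=null_model_correction(cv_r, null_r),
        within_r=within_r,
        cv_r_folds=cv_r_folds,
        null_r_folds=null_r_folds,
        valid=valid,
        condition=condition,
    )


def significance(values, popmean: float = 0.0) -> tuple[float, int, float]:
    """Two-sided one-sample t test of corrected values against ``popmean``.

    Returns (t, df, p). Degenerate zero-variance samples centered on the
    population mean give t = 0, p = 1 rather than NaN.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 2:
        raise ValueError("significance test needs at least 2 values")
    sd = v.std(ddof=1)
    df = n - 1
    if sd == 0:
        if np.isclose(v.mean(), popmean):
            return 0.0, df, 1.0
        return np.inf * np.sign(v.mean() - popmean), df, 0.0
    t, p = stats.ttest_1samp(v, popmean)
    return float(t), df, float(p)
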