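"""Visual-field translation of CF fits and cross-state comparisons.

The source sheet's retinotopic map turns surface CF parameters into
visual-field coordinates: a target's represented location is the pRF
position of its CF center vertex, and the winning hemisphere is a proxy
for the represented (contralateral) hemifield. Connectivity strength is
compared across cognitive states with the normalized preference ratio
rho_RS / (rho_RS + rho_MW) of null-model-corrected CV correlations, and
with correlation/t statistics weighted by those corrected values
(degrees of freedom adjusted via the Kish effective sample size).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.weightstats import DescrStatsW

from .prf import PRFParams

_CONTRA = {"L": "R", "R": "L"}


@dataclass
class VisualFieldRepr:
    """Per-target visual-field representation derived from CF fits."""

    eccentricity: np.ndarray  # degrees
    polar_angle: np.ndarray  # degrees, 0 = right horizontal meridian, CCW
    hemifield: np.ndarray  # {L, R}, contralateral to the CF hemisphere
    condition: str = ""

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "eccentricity_deg": self.eccentricity,
                "polar_angle_deg": self.polar_angle,
                "hemifield": self.hemifield,
                "condition": self.condition,
            }
        )


def cf_to_visual_field(cf, prfs_by_hemi: dict) -> VisualFieldRepr:
    """Visual-field location of each target: the pRF of its CF center.

    ``cf`` is a :class:`~confield.cf.CFResults` (or any object with ``v0``,
    ``hemisphere`` and ``condition`` attributes); ``prfs_by_hemi`` maps
    hemisphere to the source sheet's :class:`~confield.prf.PRFParams`. The
    hemifield label is the hemisphere's contralateral visual hemifield.
    """
    ecc = np.zeros(len(cf.v0))
    ang = np.zeros(len(cf.v0))
    hemifield = np.empty(len(cf.v0), dtype=object)
    lookup = {}
    for h, p in prfs_by_hemi.items():
        lookup[h] = {int(v): i for i, v in enumerate(p.vertex_ids)}
    for t, (v0, h) in enumerate(zip(cf.v0, cf.hemisphere)):
        if h not in lookup or int(v0) not in lookup[h]:
            raise KeyError(f"no pRF available for CF center vertex {v0} ({h})")
        i = lookup[h][int(v0)]
        p = prfs_by_hemi[h]
        ecc[t] = np.hypot(p.x0[i], p.y0[i])
        ang[t] = np.degrees(np.arctan2(p.y0[i], p.x0[i]))
        hemifield[t] = _CONTRA[h]
    return VisualFieldRepr(
        eccentricity=ecc,
        polar_angle=ang,
        hemifield=hemifield,
        condition=getattr(cf, "condition", ""),
    )


def rc_preference_ratio(rho_rs, rho_mw, floor: float = 0.01):
    """Normalized resting-state preference: rho_RS / (rho_RS + rho_MW).

    Inputs are null-model-corrected CV correlations for the resting-state
    and movie-watching conditions. Negative constituents are clamped to 0
    (the ratio is only meaningful for nonnegative connectivity), and
    entries whose clamped denominator falls below ``floor`` are undefined
    (NaN). 0.5 means equal retinotopic connectivity in both states.

    Scalars in, scalar out; arrays in, array out.
    """
    scalar = np.isscalar(rho_rs) and np.isscalar(rho_mw)
    r1 = np.clip(np.asarray(rho_rs, dtype=float), 0.0, None)
    r2 = np.clip(np.asarray(rho_mw, dtype=float), 0.0, None)
    denom = r1 + r2
    ratio = np.full(np.broadcast(r1, r2).shape, np.nan)
    defined = denom >= floor
    ratio = np.where(defined, np.divide(r1, denom, out=np.zeros_like(denom),
                                        where=denom > 0), np.nan)
    return float(ratio) if scalar else ratio


@dataclass
class StatePreference:
    """Per-target state preference with its constituent corrected values."""

    ratio: np.ndarray
    rho_rs: np.ndarray
    rho_mw: np.ndarray
    mask: np.ndarray  # True where the ratio is defined

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ratio": self.ratio,
                "rho_rs": self.rho_rs,
                "rho_mw": self.rho_mw,
                "defined": self.mask,
            }
        )


def state_preference(rho_rs, rho_mw, floor: float = 0.01) -> StatePreference:
    """Build the per-target preference table from two corrected-value sets."""
    rho_rs = np.asarray(rho_rs, dtype=float)
    rho_mw = np.asarray(rho_mw, dtype=float)
    ratio = rc_preference_ratio(rho_rs, rho_mw, floor=floor)
    return StatePreference(
        ratio=ratio, rho_rs=rho_rs, rho_mw=rho_mw, mask=~np.isnan(ratio)
    )


def _kish_neff(w: np.ndarray) -> float:
    return float(w.sum() ** 2 / (w**2).sum())


def _check_weights(w, n) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if len(w) != n:
        raise ValueError("weights length mismatch")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if not np.any(w > 0):
        raise ValueError("weights must not be all zero")
    return w


def weighted_correlation(x, y, w) -> tuple[float, float]:
    """Weighted Pearson correlation with Kish-adjusted degrees of freedom.

    With uniform weights this reduces exactly to the ordinary Pearson
    correlation and its two-sided p value. The p value uses a t statistic
    on n_eff - 2 degrees of freedom, n_eff = (sum w)^2 / sum w^2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y length mismatch")
    w = _check_weights(w, len(x))
    d = DescrStatsW(np.column_stack([x, y]), weights=w)
    rho = float(d.corrcoef[0, 1])
    neff = _kish_neff(w)
    df = neff - 2
    if df <= 0:
        return rho, np.nan
    rho_c = min(max(rho, -1.0), 1.0)
    if abs(rho_c) == 1.0:
        return rho_c, 0.0
    t = rho_c * np.sqrt(df / (1.0 - rho_c**2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return rho, float(p)


def weighted_ttest_diff(a, b, w) -> tuple[float, float, float]:
    """Weighted paired t test of a - b with Kish-adjusted df.

    Weights are rescaled to sum to the Kish effective sample size, so the
    statsmodels weighted one-sample test returns mean, variance and
    degrees of freedom consistent with effective-n weighting; uniform
    weights recover the classical paired t test exactly. Returns
    (t, df, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired samples must have equal length")
    w = _check_weights(w, len(a))
    neff = _kish_neff(w)
    if neff < 2:
        raise ValueError("fewer than 2 effective observations")
    d = a - b
    w_scaled = w * (neff / w.sum())
    ds = DescrStatsW(d, weights=w_scaled, ddof=1)
    if ds.std == 0:
        m = ds.mean
        return (0.0, neff - 1, 1.0) if np.isclose(m, 0) else (np.inf * np.sign(m), neff - 1, 0.0)
    t, p, df = ds.ttest_mean(0.0)
    return float(t), float(df), float(p)


def contralaterality_index(hemifield, cf_hemisphere) -> float:
    """Signed contralaterality of one unit's targets.

    (n_contra - n_ipsi) / (n_contra + n_ipsi), where a target counts as
    contralateral when its represented hemifield is opposite its CF
    hemisphere. +1 = fully contralateral, -1 = fully ipsilateral.
    """
    hemifield = np.asarray(hemifield, dtype=object)
    cf_hemisphere = np.asarray(cf_hemisphere, dtype=object)
    contra = np.array([_CONTRA[h] for h in cf_hemisphere], dtype=object)
    n_c = int(np.sum(hemifield == contra))
    n_i = len(hemifield) - n_c
    if n_c + n_i == 0:
        raise ValueError("no targets")
    return (n_c - n_i) / (n_c + n_i)


def laterality_test(values) -> tuple[float, float, float]:
    """Two-sided one-sample t test of signed laterality values against 0.

    ``values`` holds one signed contralaterality index per unit (subject or
    simulated replicate); see :func:`contralaterality_index`. Returns
    (t, df, p).
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("laterality test needs at least 2 units")
    sd = v.std(ddof=1)
    df = len(v) - 1
    if sd == 0:
        if np.isclose(v.mean(), 0):
            return 0.0, df, 1.0
        return np.inf * np.sign(v.mean()), df, 0.0
    t, p = stats.ttest_1samp(v, 0.0)
    return float(t), df, float(p)
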