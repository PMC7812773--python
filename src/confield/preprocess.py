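"""Time-course containers and preprocessing.

All experiment types (retinotopy, movie, rest) are preprocessed identically:
a Savitzky–Golay high-pass (subtract the third-order smoothed trend over a
210-s window) followed by z-scoring each vertex over time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_filter

CONDITIONS = ("retinotopy", "movie", "rest")


@dataclass
class TimecourseMatrix:
    """Vertices x timepoints BOLD data for one run.

    Attributes
    ----------
    data : (n_vertices, n_timepoints) float array
        Signal values; z-units after preprocessing.
    vertex_ids : (n_vertices,) int array
        Mesh vertex index of each row (or target ids for non-surface data).
    sampling_rate : float
        Samples per second (Hz).
    run_id : str
        Identifier of the acquisition run.
    condition : str
        One of ``retinotopy``, ``movie``, ``rest``.
    hemisphere : str or None
        Hemisphere tag for surface data, None for target collections.
    """

    data: np.ndarray
    vertex_ids: np.ndarray
    sampling_rate: float = 1.0
    run_id: str = "run-1"
    condition: str = "rest"
    hemisphere: str | None = None

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.vertex_ids = np.asarray(self.vertex_ids, dtype=np.int64)
        if self.data.shape[0] != len(self.vertex_ids):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but {len(self.vertex_ids)} "
                "vertex ids"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_vertices(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


def zscore(x, axis: int = -1):
    """Z-score over time (population SD); constant rows map to all zeros.

    Accepts a plain array or a :class:`TimecourseMatrix` and returns the
    same kind. The constant-row convention avoids division errors and makes
    flat (dead) vertices drop out of all correlations.
    """
    if isinstance(x, TimecourseMatrix):
        return replace(x, data=zscore(x.data, axis=-1))
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, keepdims=True)
    out = np.zeros_like(x)
    np.divide(x - mu, sd, out=out, where=sd > 0)
    return out


def highpass_savgol(
    tc: TimecourseMatrix,
    window_period: float = 210.0,
    polyorder: int = 3,
) -> TimecourseMatrix:
    """High-pass filter by subtracting a Savitzky–Golay smoothed trend.

    ``window_period`` is the smoothing window length in seconds, converted
    to an odd number of samples at the run's sampling rate. Slow drifts
    (periods well beyond the window) are removed; faster fluctuations pass
    essentially unchanged.
    """
    n = tc.n_timepoints
    win = int(round(window_period * tc.sampling_rate))
    if win % 2 == 0:
        win += 1
    if win <= polyorder:
        raise ValueError(
            f"window of {win} samples must exceed polyorder {polyorder}"
        )
    if win > n:
        raise ValueError(
            f"run of {n} samples is shorter than the {win}-sample filter "
            "window; pass a shorter window_period explicitly"
        )
    trend = savgol_filter(tc.data, window_length=win, polyorder=polyorder, axis=-1)
    return replace(tc, data=tc.data - trend)


def preprocess_run(
    tc: TimecourseMatrix,
    window_period: float = 210.0,
    polyorder: int = 3,
) -> TimecourseMatrix:
    """Standard per-run preprocessing: high-pass then z-score.

    Applied identically to every condition; never across run boundaries.
    """
    return zscore(highpass_savgol(tc, window_period, polyorder))
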