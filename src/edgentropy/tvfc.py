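"""Time-varying functional connectivity from parcellated BOLD timeseries.

The stage turns frames x parcels signal matrices into windows x edges
matrices of Fisher-z-transformed sliding-window Pearson correlations:

1. zero-phase 4th-order Butterworth bandpass (default 0.017-0.1 Hz),
2. regression of the cross-parcel mean signal from every parcel (a version
   of global-signal regression; OLS with intercept, residuals kept),
3. trimming of the first and last ``trim`` frames (boundary effects),
4. rectangular sliding window (default width 60 s, step one TR), Pearson
   correlation of all parcel pairs per window, then atanh.

Correlations are clipped to +/-(1 - 1e-12) before the Fisher transform so
degenerate (perfectly correlated) synthetic inputs stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, sosfiltfilt
from sklearn.base import BaseEstimator, TransformerMixin

from .edges import edge_index

R_CLIP = 1.0 - 1e-12


@dataclass
class ParcelTimeseries:
    """One subject's frames x parcels matrix with acquisition metadata."""

    data: np.ndarray
    tr: float
    subject_id: str = "sub-0"
    group: str = "control"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] < 2:
            raise ValueError("timeseries must be frames x parcels with >= 2 parcels")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"{self.subject_id}: non-finite frames in timeseries")
        if self.tr <= 0:
            raise ValueError("tr must be positive (seconds)")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.data.shape[1]


@dataclass
class EdgeDynamics:
    """Windows x edges matrix of Fisher-z sliding-window correlations."""

    data: np.ndarray
    edge_idx: np.ndarray  # (E, 2) canonical i<j pairs
    window_frames: int
    step_frames: int
    tr: float
    subject_id: str = "sub-0"
    group: str = "control"

    @property
    def n_windows(self) -> int:
        return self.data.shape[0]

    @property
    def n_edges(self) -> int:
        return self.data.shape[1]

    @property
    def edge_ids(self) -> list[str]:
        return [f"{i}_{j}" for i, j in self.edge_idx]


class TimeseriesPreprocessor(TransformerMixin, BaseEstimator):
    """Bandpass + cross-parcel mean regression + end trimming.

    Parameters
    ----------
    band : tuple of float
        Passband in Hz; must lie strictly inside (0, Nyquist).
    trim : int
        Frames removed from each end after filtering and regression.
    order : int
        Butterworth order (applied forward-backward, so the effective
        attenuation is doubled and the phase response is zero).
    """

    def __init__(self, band: tuple[float, float] = (0.017, 0.1), trim: int = 10,
                 order: int = 4):
        self.band = band
        self.trim = trim
        self.order = order

    def fit(self, X, y=None):
        return self

    def transform(self, X: np.ndarray, tr: float) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        n_frames = X.shape[0]
        nyquist = 0.5 / tr
        lo, hi = self.band
        if not (0 < lo < hi < nyquist):
            raise ValueError(
                f"band {self.band} Hz must lie inside (0, {nyquist:g}) Hz "
                f"(Nyquist for TR={tr} s)"
            )
        if 2 * self.trim >= n_frames:
            raise ValueError("trimming would remove every frame")
        sos = butter(self.order, self.band, btype="bandpass", fs=1.0 / tr,
                     output="sos")
        Xf = sosfiltfilt(sos, X, axis=0)
        # regress the cross-parcel mean from each parcel; keep residuals
        g = Xf.mean(axis=1)
        G = np.column_stack([np.ones(n_frames), g])
        beta, *_ = np.linalg.lstsq(G, Xf, rcond=None)
        Xr = Xf - G @ beta
        if self.trim:
            Xr = Xr[self.trim:-self.trim]
        return Xr


class SlidingWindowCorrelation(TransformerMixin, BaseEstimator):
    """Rectangular sliding-window Pearson correlation with Fisher transform.

    Window width is specified in seconds and converted to frames as
    ``round(window_seconds / tr)``; with the study geometry (60 s, TR 0.8 s)
    that is 75 frames. The window slides in steps of ``step_frames``.
    """

    def __init__(self, window_seconds: float = 60.0, step_frames: int = 1):
        self.window_seconds = window_seconds
        self.step_frames = step_frames

    def fit(self, X, y=None):
        return self

    def window_frames(self, tr: float) -> int:
        wf = int(round(self.window_seconds / tr))
        if wf < 3:
            raise ValueError(
                f"window of {self.window_seconds} s is {wf} frames at "
                f"TR={tr} s; need >= 3"
            )
        return wf

    def transform(self, X: np.ndarray, tr: float,
                  subject_id: str = "sub-0") -> np.ndarray:
        X = np.asarray(X, dtype=float)
        n_frames, n_parcels = X.shape
        wf = self.window_frames(tr)
        step = int(self.step_frames)
        if step < 1:
            raise ValueError("step_frames must be >= 1")
        if n_frames < wf:
            raise ValueError(
                f"{subject_id}: {n_frames} frames < window of {wf} frames"
            )
        starts = range(0, n_frames - wf + 1, step)
        iu = np.triu_indices(n_parcels, k=1)
        Z = np.empty((len(starts), len(iu[0])))
        for w, s in enumerate(starts):
            seg = X[s:s + wf]
            sd = seg.std(axis=0)
            if np.any(sd == 0):
                bad = int(np.flatnonzero(sd == 0)[0])
                raise ValueError(
                    f"{subject_id}: zero-variance parcel {bad} in window {w}"
                )
            C = np.corrcoef(seg.T)
            Z[w] = np.arctanh(np.clip(C[iu], -R_CLIP, R_CLIP))
        return Z


def preprocess_timeseries(ts: ParcelTimeseries,
                          band: tuple[float, float] = (0.017, 0.1),
                          trim: int = 10) -> ParcelTimeseries:
    """Functional wrapper over :class:`TimeseriesPreprocessor`."""
    pre = TimeseriesPreprocessor(band=band, trim=trim)
    return replace(ts, data=pre.transform(ts.data, tr=ts.tr))


def sliding_window_correlation(ts: ParcelTimeseries,
                               window_seconds: float = 60.0,
                               step_frames: int = 1) -> EdgeDynamics:
    """Functional wrapper over :class:`SlidingWindowCorrelation`."""
    swc = SlidingWindowCorrelation(window_seconds=window_seconds,
                                   step_frames=step_frames)
    Z = swc.transform(ts.data, tr=ts.tr, subject_id=ts.subject_id)
    return EdgeDynamics(
        data=Z,
        edge_idx=edge_index(ts.n_parcels),
        window_frames=swc.window_frames(ts.tr),
        step_frames=step_frames,
        tr=ts.tr,
        subject_id=ts.subject_id,
        group=ts.group,
    )
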