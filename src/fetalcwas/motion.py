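"""Volume censoring ("scrubbing") and scan-inclusion rules.

Operates on ROI-level time series plus frame-to-frame motion traces. A
volume is censored when its frame-to-frame translation exceeds 1 mm or its
rotation exceeds 1.5 degrees, together with the immediately preceding
volume; a second, signal-based rule removes volumes in which more than 10%
of ROI signals deviate from their own time-series median by more than a
multiple of the median absolute deviation. Scans keep at least 4 minutes of
retained data or are excluded. Nuisance regression and band-pass filtering
act on the retained volumes only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from fetalcwas.exceptions import DesignError, InputError

TRANS_THRESH_MM = 1.0
ROT_THRESH_DEG = 1.5
MIN_MINUTES = 4.0


@dataclass
class SubjectScan:
    """One scan: ROI time series, motion trace and the evolving keep mask."""

    scan_id: str
    timeseries: np.ndarray  # (n_rois, n_volumes), arbitrary BOLD units
    translation_delta: np.ndarray  # per-volume frame-to-frame shift, mm
    rotation_delta: np.ndarray  # per-volume frame-to-frame rotation, degrees
    tr_seconds: float = 3.0
    keep_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.timeseries = np.asarray(self.timeseries, dtype=float)
        self.translation_delta = np.asarray(self.translation_delta, dtype=float)
        self.rotation_delta = np.asarray(self.rotation_delta, dtype=float)
        n_vol = self.timeseries.shape[1]
        if self.translation_delta.shape != (n_vol,) or self.rotation_delta.shape != (
            n_vol,
        ):
            raise InputError(
                "motion trace length does not match the number of volumes"
            )
        if self.keep_mask is None:
            self.keep_mask = np.ones(n_vol, dtype=bool)
        else:
            self.keep_mask = np.asarray(self.keep_mask, dtype=bool)
            if self.keep_mask.shape != (n_vol,):
                raise InputError("keep_mask length does not match volumes")

    @property
    def n_volumes(self) -> int:
        return self.timeseries.shape[1]

    @property
    def retained_volumes(self) -> int:
        return int(self.keep_mask.sum())

    @property
    def retained_minutes(self) -> float:
        return self.retained_volumes * self.tr_seconds / 60.0


def censor_motion(
    scan: SubjectScan,
    trans_thresh_mm: float = TRANS_THRESH_MM,
    rot_thresh_deg: float = ROT_THRESH_DEG,
) -> np.ndarray:
    """Mask out high-motion volumes and their immediately preceding frames.

    A volume whose frame-to-frame translation exceeds ``trans_thresh_mm`` OR
    whose rotation exceeds ``rot_thresh_deg`` is removed, together with the
    frame just before it (motion corrupts both frames of the pair). The
    first volume has no predecessor. The scan's keep_mask is updated in
    place (AND-ed with the new mask) and returned.
    """
    if trans_thresh_mm <= 0 or rot_thresh_deg <= 0:
        raise InputError("censoring thresholds must be positive")
    spikes = (np.abs(scan.translation_delta) > trans_thresh_mm) | (
        np.abs(scan.rotation_delta) > rot_thresh_deg
    )
    bad = spikes.copy()
    bad[:-1] |= spikes[1:]  # preceding-frame removal
    scan.keep_mask &= ~bad
    return scan.keep_mask


def censor_mad(
    scan: SubjectScan, voxel_frac: float = 0.10, mad_k: float = 3.0
) -> np.ndarray:
    """Remove volumes where too many ROI signals are MAD outliers.

    A signal "deviates" at volume t when |x[t] - median(x)| > mad_k * MAD(x),
    both computed per ROI over the currently retained volumes. A volume is
    removed when strictly more than ``voxel_frac`` of ROI signals deviate.
    Constant series (MAD 0) never deviate.
    """
    if not 0 < voxel_frac < 1:
        raise InputError("voxel_frac must lie in (0, 1)")
    ts = scan.timeseries
    kept = scan.keep_mask
    if not kept.any():
        return scan.keep_mask
    med = np.median(ts[:, kept], axis=1, keepdims=True)
    mad = np.median(np.abs(ts[:, kept] - med), axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        deviates = np.abs(ts - med) > mad_k * mad
    deviates[(mad == 0).ravel(), :] = False
    frac = deviates.mean(axis=0)
    scan.keep_mask &= ~(frac > voxel_frac)
    return scan.keep_mask


def nuisance_regress(scan: SubjectScan, regressors: np.ndarray) -> np.ndarray:
    """Per-ROI OLS residuals against the regressors, on retained volumes.

    ``regressors`` is a (n_volumes, k) matrix that must include an intercept
    (a constant column, or one in its column space); only the retained
    volumes enter the fit. Returns the (n_rois, n_retained) residual matrix.
    """
    x = np.asarray(regressors, dtype=float)
    if x.ndim != 2 or x.shape[0] != scan.n_volumes:
        raise InputError("regressors must be a (n_volumes, k) matrix")
    xk = x[scan.keep_mask]
    rank = np.linalg.matrix_rank(xk)
    if rank < xk.shape[1]:
        raise DesignError("regressor matrix is rank deficient on retained volumes")
    ones = np.ones((xk.shape[0], 1))
    if np.linalg.matrix_rank(np.hstack([xk, ones])) > rank:
        raise DesignError("regressors must include an intercept column")
    y = scan.timeseries[:, scan.keep_mask].T  # (n_retained, n_rois)
    beta, *_ = np.linalg.lstsq(xk, y, rcond=None)
    return (y - xk @ beta).T


def bandpass_filter(
    scan: SubjectScan,
    low_hz: float = 0.009,
    high_hz: float = 0.08,
    order: int = 2,
) -> np.ndarray:
    """Butterworth band-pass on the full volume grid, censoring-aware.

    Censored volumes are linearly interpolated before filtering (a gap in
    the grid would otherwise ring through the filter), the zero-phase filter
    is applied, and the censored volumes stay masked afterwards. Returns the
    filtered (n_rois, n_volumes) matrix; the scan's timeseries is replaced.
    """
    fs = 1.0 / scan.tr_seconds
    nyq = fs / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise InputError(f"band ({low_hz}, {high_hz}) Hz invalid for TR {scan.tr_seconds}s")
    ts = scan.timeseries.copy()
    kept = scan.keep_mask
    if kept.sum() < 2:
        raise InputError("need at least 2 retained volumes to interpolate")
    t = np.arange(scan.n_volumes)
    for i in range(ts.shape[0]):
        ts[i, ~kept] = np.interp(t[~kept], t[kept], ts[i, kept])
    b, a = sp_signal.butter(order, [low_hz / nyq, high_hz / nyq], btype="band")
    scan.timeseries = sp_signal.filtfilt(b, a, ts, axis=1)
    return scan.timeseries


def check_inclusion(scan: SubjectScan, min_minutes: float = MIN_MINUTES) -> bool:
    """True when the retained data lasts at least ``min_minutes`` minutes."""
    if scan.tr_seconds <= 0:
        raise InputError("tr_seconds must be positive")
    return scan.retained_volumes * scan.tr_seconds >= min_minutes * 60.0
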