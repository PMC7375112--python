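"""Motion screening and signal conditioning.

The chain applied before any phase analysis is fixed:

1. framewise-displacement screening of subjects (FD > 0.5 mm on more
   than 20% of rest frames excludes the subject),
2. nuisance regression (6 rigid-body motion parameters, mean nuisance
   series such as white-matter/ventricle signals, their backward-
   difference derivatives, and an intercept),
3. zero-phase band-pass filtering to the 0.06-0.125 Hz band,
4. z-scoring each region,
5. (downstream) Hilbert phase extraction, then concatenation of task
   blocks and truncation of rest to the task length.

Filtering is forward-backward (2nd-order Butterworth per pass) because
the downstream analysis is phase-based and cannot tolerate filter phase
distortion. No scrubbing/frame-censoring is performed — removing frames
would break the temporal structure the phase metrics rely on.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal

from .containers import PhaseArray, RegionTimeSeries

__all__ = [
    "framewise_displacement",
    "screen_subject",
    "build_confound_design",
    "regress_nuisance",
    "bandpass_filter",
    "global_signal_regression",
    "zscore",
    "select_task_frames",
    "match_length",
]


def framewise_displacement(motion: np.ndarray, radius_mm: float = 50.0) -> np.ndarray:
    """Per-frame head-motion magnitude (mm).

    FD_t = sum |d translation| + radius_mm * sum |d rotation|, i.e. the
    rotational displacement is converted to arc length on a sphere of
    ``radius_mm`` (50 mm by convention). The first frame has FD = 0.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be frames x 6 (3 translations, 3 rotations)")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    if not np.all(np.isfinite(motion)):
        raise ValueError("motion parameters must be finite")
    d = np.abs(np.diff(motion, axis=0))
    fd = d[:, :3].sum(axis=1) + radius_mm * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def screen_subject(fd: np.ndarray, thr_mm: float = 0.5, max_frac: float = 0.2) -> bool:
    """True if the subject is kept.

    Excluded only when *more than* ``max_frac`` of frames exceed
    ``thr_mm`` — both inequalities strict, so a subject with exactly 20%
    of frames above threshold is kept.
    """
    fd = np.asarray(fd, dtype=float)
    if fd.size == 0:
        raise ValueError("empty FD series")
    frac = np.mean(fd > thr_mm)
    return not (frac > max_frac)


def build_confound_design(
    motion: np.ndarray,
    nuisance: np.ndarray | pd.DataFrame | None = None,
    include_derivatives: bool = True,
) -> pd.DataFrame:
    """Nuisance design matrix: motion (6), mean nuisance series, and
    their backward-difference derivatives (first row zero-padded)."""
    motion = np.asarray(motion, dtype=float)
    cols = {f"motion_{i}": motion[:, i] for i in range(motion.shape[1])}
    if nuisance is not None:
        if isinstance(nuisance, pd.DataFrame):
            for name in nuisance.columns:
                cols[str(name)] = nuisance[name].to_numpy(dtype=float)
        else:
            nuisance = np.asarray(nuisance, dtype=float)
            for i in range(nuisance.shape[1]):
                cols[f"nuisance_{i}"] = nuisance[:, i]
    if include_derivatives:
        for name in list(cols):
            d = np.diff(cols[name], prepend=cols[name][0])
            cols[f"{name}_deriv"] = d
    return pd.DataFrame(cols)


def _column_names(confounds) -> list[str]:
    if isinstance(confounds, pd.DataFrame):
        return [str(c) for c in confounds.columns]
    return [f"c{i}" for i in range(np.asarray(confounds).shape[1])]


def regress_nuisance(
    ts: RegionTimeSeries, confounds: np.ndarray | pd.DataFrame
) -> RegionTimeSeries:
    """OLS residuals of every region on the confound design (plus an
    intercept); residuals are orthogonal to every design column."""
    names = _column_names(confounds)
    C = np.asarray(confounds, dtype=float)
    if C.ndim != 2 or C.shape[0] != ts.n_frames:
        raise ValueError(
            f"confounds have {C.shape[0] if C.ndim == 2 else '?'} rows, "
            f"series has {ts.n_frames} frames"
        )
    X = np.column_stack([np.ones(ts.n_frames), C])
    names = ["intercept"] + names
    # drop exact duplicates of earlier columns (e.g. a zero derivative
    # duplicating another zero column) before the rank check
    keep: list[int] = []
    for j in range(X.shape[1]):
        dup = any(np.allclose(X[:, j], X[:, k]) for k in keep)
        if not dup:
            keep.append(j)
    Xk = X[:, keep]
    rank = np.linalg.matrix_rank(Xk)
    if rank < Xk.shape[1]:
        # identify offending columns: those whose removal restores rank
        bad = []
        for j in range(1, Xk.shape[1]):
            others = np.delete(Xk, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(names[keep[j]])
        raise ValueError(f"rank-deficient confound design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(Xk, ts.data, rcond=None)
    return ts.with_data(ts.data - Xk @ beta)


def _design_sos(low_hz: float, high_hz: float, tr_s: float, order: int = 2):
    nyq = 0.5 / tr_s
    if not (0.0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must lie inside (0, {nyq:.4f}) Hz"
        )
    return signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=1.0 / tr_s,
                         output="sos")


def bandpass_filter(
    ts: RegionTimeSeries, low_hz: float = 0.06, high_hz: float = 0.125, order: int = 2
) -> RegionTimeSeries:
    """Zero-phase Butterworth band-pass (``order`` per pass, applied
    forward and backward with :func:`scipy.signal.sosfiltfilt`)."""
    sos = _design_sos(low_hz, high_hz, ts.tr_s, order)
    return ts.with_data(signal.sosfiltfilt(sos, ts.data, axis=0))


def bandpass_gain(freq_hz: float, low_hz: float, high_hz: float, tr_s: float,
                  order: int = 2) -> float:
    """Squared magnitude response of the forward-backward filter at one
    frequency (the effective gain applied to a pure tone)."""
    sos = _design_sos(low_hz, high_hz, tr_s, order)
    _, h = signal.sosfreqz(sos, worN=[freq_hz], fs=1.0 / tr_s)
    return float(np.abs(h[0]) ** 2)


def global_signal_regression(ts: RegionTimeSeries) -> RegionTimeSeries:
    """Residual of each region on the across-region mean series.

    Off by default in the pipeline (the global signal may carry neural
    information); provided for sensitivity analyses.
    """
    if ts.n_regions < 2:
        raise ValueError("need at least 2 regions")
    g = ts.data.mean(axis=1)
    X = np.column_stack([np.ones(ts.n_frames), g])
    beta, *_ = np.linalg.lstsq(X, ts.data, rcond=None)
    return ts.with_data(ts.data - X @ beta)


def zscore(ts: RegionTimeSeries) -> RegionTimeSeries:
    """Demean and scale every region to unit population SD."""
    mu = ts.data.mean(axis=0)
    sd = ts.data.std(axis=0)  # population convention (ddof=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        bad = [ts.region_ids[i] for i in zero[:5]]
        raise ValueError(f"zero-variance region(s): {bad}")
    return ts.with_data((ts.data - mu) / sd)


def _frames_in_blocks(events: pd.DataFrame, n_frames: int, tr_s: float,
                      keep: set[str]) -> np.ndarray:
    mid = (np.arange(n_frames) + 0.5) * tr_s
    sel = np.zeros(n_frames, dtype=bool)
    for _, row in events.iterrows():
        if row["trial_type"] in keep:
            sel |= (mid >= row["onset"]) & (mid < row["onset"] + row["duration"])
    return sel


def select_task_frames(
    data: RegionTimeSeries | PhaseArray | np.ndarray,
    events: pd.DataFrame,
    keep: set[str] | None = None,
    tr_s: float | None = None,
):
    """Concatenate the frames whose midpoint falls inside a kept block.

    Returns ``(selected, boundaries)`` where ``boundaries`` are the
    start offsets of each contiguous run inside the concatenated output
    (for seam auditing). Membership uses the frame-midpoint rule, which
    is unambiguous when block durations are not TR multiples.
    """
    keep = keep or {"task"}
    if isinstance(data, (RegionTimeSeries, PhaseArray)):
        arr, tr = data.data, data.tr_s
    else:
        arr = np.asarray(data)
        if tr_s is None:
            raise ValueError("tr_s required for a bare array")
        tr = tr_s
    sel = _frames_in_blocks(events, arr.shape[0], tr, keep)
    idx = np.flatnonzero(sel)
    if idx.size == 0:
        raise ValueError(f"no frames retained for trial types {sorted(keep)}")
    starts = np.flatnonzero(np.diff(idx, prepend=idx[0] - 2) > 1)
    out = arr[idx]
    if isinstance(data, RegionTimeSeries):
        return data.with_data(out), starts
    if isinstance(data, PhaseArray):
        return PhaseArray(out, tr_s=tr, region_ids=data.region_ids), starts
    return out, starts


def match_length(rest: RegionTimeSeries | PhaseArray | np.ndarray, n_frames_task: int):
    """Truncate the rest series to the first ``n_frames_task`` frames so
    rest and task metrics are estimated on equal-length data."""
    arr = rest.data if isinstance(rest, (RegionTimeSeries, PhaseArray)) else np.asarray(rest)
    if arr.shape[0] < n_frames_task:
        raise ValueError(
            f"rest has {arr.shape[0]} frames, fewer than requested {n_frames_task}"
        )
    out = arr[:n_frames_task]
    if isinstance(rest, RegionTimeSeries):
        return rest.with_data(out)
    if isinstance(rest, PhaseArray):
        return PhaseArray(out, tr_s=rest.tr_s, region_ids=rest.region_ids)
    return out
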