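"""Kuramoto order parameter, metastability and synchrony.

Instantaneous phases come from the analytic signal x_a = x + i H[x]
(H the Hilbert transform) of the narrowband series; theta = arg(x_a).
For a set of N regions the order parameter at frame t is

    R(t) = | (1/N) * sum_k exp(i * theta_k(t)) |,

the modulus of the mean unit phasor: 0 for uniformly scattered phases,
1 for full phase locking. Metastability of the set is the population
standard deviation of R(t) over time (bounded by 0.5); synchrony is its
time mean (bounded by 1). The network "interaction matrix" evaluates
these metrics within each labelled network (diagonal) and over the
union of the regions of every network pair (off-diagonal).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.signal import hilbert

from .containers import (
    InteractionMatrix,
    NetworkAssignment,
    PhaseArray,
    RegionTimeSeries,
    wrap_phase,
)

__all__ = [
    "analytic_phase",
    "order_parameter",
    "metastability",
    "synchrony",
    "interaction_matrix",
    "global_metastability",
]


def analytic_phase(ts: RegionTimeSeries, trim: int = 10) -> PhaseArray:
    """Instantaneous phases via the discrete Hilbert transform.

    The first and last ``trim`` frames are dropped to suppress the
    transform's border effects. The input must already be narrowband
    (band-pass filtered) for the phase to be meaningful.
    """
    if ts.n_frames <= 2 * trim + 2:
        raise ValueError(
            f"{ts.n_frames} frames too few for trim={trim} (need > {2 * trim + 2})"
        )
    sd = ts.data.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(
            f"zero-variance region(s): {[ts.region_ids[i] for i in zero[:5]]}"
        )
    xa = hilbert(ts.data, axis=0)
    theta = np.angle(xa)
    if trim > 0:
        theta = theta[trim:-trim]
    return PhaseArray(wrap_phase(theta), tr_s=ts.tr_s, region_ids=list(ts.region_ids))


def _columns(phases: PhaseArray | np.ndarray, region_set=None) -> np.ndarray:
    if isinstance(phases, PhaseArray):
        theta = phases.data
        if region_set is None:
            return theta
        ids = list(region_set)
        if ids and isinstance(ids[0], str):
            lookup = {r: i for i, r in enumerate(phases.region_ids)}
            unknown = [r for r in ids if r not in lookup]
            if unknown:
                raise KeyError(f"unknown region id(s): {unknown[:5]}")
            cols = [lookup[r] for r in ids]
        else:
            cols = [int(i) for i in ids]
        return theta[:, cols]
    theta = np.asarray(phases, dtype=float)
    return theta if region_set is None else theta[:, list(region_set)]


def order_parameter(
    phases: PhaseArray | np.ndarray, region_set: Sequence | None = None
) -> np.ndarray:
    """Kuramoto order parameter R(t) over a region set (default: all).

    Returns one value per frame, each in [0, 1].
    """
    theta = _columns(phases, region_set)
    if theta.shape[1] == 0:
        raise ValueError("empty region set")
    return np.abs(np.exp(1j * theta).mean(axis=1))


def metastability(R: np.ndarray) -> float:
    """Population SD (ddof=0) of the order-parameter series.

    Zero for any constant R; the bound R(t) in [0, 1] caps the value at
    0.5.
    """
    R = np.asarray(R, dtype=float)
    if R.size < 2:
        raise ValueError("metastability needs at least 2 frames")
    return float(np.std(R))


def synchrony(R: np.ndarray) -> float:
    """Time mean of the order-parameter series, in [0, 1]."""
    R = np.asarray(R, dtype=float)
    if R.size < 1:
        raise ValueError("synchrony needs at least 1 frame")
    return float(np.mean(R))


def interaction_matrix(
    phases: PhaseArray, assignment: NetworkAssignment, kind: str = "metastability"
) -> InteractionMatrix:
    """Network x network interaction matrix.

    Entry (i, i) is the metric over network i's regions; entry (i, j)
    is the metric over the union of the regions of networks i and j —
    symmetric by construction. A single-region network has synchrony 1
    and metastability 0 on its diagonal (one phasor always has unit
    modulus).
    """
    if kind not in ("metastability", "synchrony"):
        raise ValueError(f"unknown kind: {kind!r}")
    idx = assignment.column_indices(phases.region_ids)
    labels = assignment.labels
    empty = [l for l, ix in idx.items() if ix.size == 0]
    if empty:
        raise ValueError(f"network(s) with no regions in the data: {empty}")
    z = np.exp(1j * phases.data)  # (frames, regions)
    # phasor sums and counts per network: union metrics reduce to sums
    sums = np.stack([z[:, idx[l]].sum(axis=1) for l in labels], axis=1)  # (frames, L)
    counts = np.array([idx[l].size for l in labels], dtype=float)
    L = len(labels)
    out = np.empty((L, L))
    for i in range(L):
        for j in range(i, L):
            if i == j:
                R = np.abs(sums[:, i]) / counts[i]
            else:
                R = np.abs(sums[:, i] + sums[:, j]) / (counts[i] + counts[j])
            out[i, j] = out[j, i] = np.std(R) if kind == "metastability" else np.mean(R)
    return InteractionMatrix(out, kind=kind, labels=list(labels))


def global_metastability(phases: PhaseArray | np.ndarray) -> float:
    """Metastability of R(t) computed over all regions at once."""
    theta = _columns(phases)
    if theta.shape[1] < 2:
        raise ValueError("need at least 2 regions")
    return metastability(order_parameter(theta))
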