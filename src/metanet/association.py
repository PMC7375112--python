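"""Update efficiency and brain-behaviour association.

Update efficiency quantifies how "pre-configured" a subject's resting
network architecture is toward the task-general arrangement: the
Pearson correlation between the vectorized (upper triangle plus
diagonal) rest and task-general interaction matrices, Fisher
z-transformed so it can enter ordinary linear models.

Connection-wise association regresses a behaviour score on each of the
105 unique network connections' metastability and controls the false
discovery rate with Benjamini-Hochberg. The efficiency-performance
regression relates scores to update efficiency while controlling for
global metastability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .task_general import devectorize_matrix, vectorize_matrix

__all__ = [
    "update_efficiency",
    "UpdateEfficiency",
    "connection_behavior_association",
    "AssociationResult",
    "efficiency_performance_regression",
    "EfficiencyRegression",
    "bh_fdr",
]

_R_CLAMP = 1.0 - 1e-12


@dataclass
class UpdateEfficiency:
    r: float  # Pearson correlation of vectorized rest vs task-general
    z: float  # Fisher z (atanh of clamped r), always finite


def update_efficiency(rest_M: np.ndarray, taskgen_M: np.ndarray) -> UpdateEfficiency:
    """Similarity of rest and task-general architectures.

    r is clamped to +/-(1 - 1e-12) before atanh so a perfect match maps
    to a large but finite z.
    """
    a = vectorize_matrix(getattr(rest_M, "values", rest_M))
    b = vectorize_matrix(getattr(taskgen_M, "values", taskgen_M))
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in a vectorized matrix")
    r = float(np.corrcoef(a, b)[0, 1])
    z = float(np.arctanh(np.clip(r, -_R_CLAMP, _R_CLAMP)))
    return UpdateEfficiency(r=r, z=z)


def bh_fdr(pvals: np.ndarray, q: float = 0.01) -> np.ndarray:
    """Benjamini-Hochberg step-up selection mask at level ``q``."""
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p values must lie in [0, 1]")
    mask, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    return mask


@dataclass
class AssociationResult:
    """Connection-wise regression of a score on connection values.

    Vectors are over the d(d+1)/2 unique connections (upper triangle
    plus diagonal, row-major) — symmetric duplicates are not re-tested,
    which would distort the FDR.
    """

    slopes: np.ndarray
    r: np.ndarray  # standardized effect (Pearson)
    pvals: np.ndarray  # two-sided
    mask: np.ndarray  # BH-FDR survivors at q
    q: float
    n_subjects: int

    def mask_matrix(self) -> np.ndarray:
        return devectorize_matrix(self.mask.astype(float)) > 0

    def r_matrix(self) -> np.ndarray:
        return devectorize_matrix(self.r)


def connection_behavior_association(
    stacks: np.ndarray, scores: np.ndarray, q: float = 0.01
) -> AssociationResult:
    """OLS of score on each connection's value, BH-FDR corrected.

    ``stacks``: (subjects, d, d) symmetric interaction matrices
    (typically metastability at rest or during a task).
    """
    stacks = np.asarray(stacks, dtype=float)
    scores = np.asarray(scores, dtype=float)
    n = stacks.shape[0]
    if n < 10:
        raise ValueError("need at least 10 subjects")
    if scores.shape != (n,):
        raise ValueError("scores must align with the subject axis")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if scores.std() == 0:
        raise ValueError("constant scores")
    d = stacks.shape[1]
    iu = np.triu_indices(d)
    X = stacks[:, iu[0], iu[1]]  # (subjects, connections)
    xc = X - X.mean(axis=0)
    yc = scores - scores.mean()
    sx = xc.std(axis=0)
    sy = yc.std()
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc * yc[:, None]).mean(axis=0) / (sx * sy)
        slopes = (xc * yc[:, None]).mean(axis=0) / (sx**2)
    r = np.where(sx == 0, 0.0, np.clip(r, -1.0, 1.0))
    slopes = np.where(sx == 0, 0.0, slopes)
    # two-sided p from the t distribution of the correlation
    dof = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(dof / np.maximum(1.0 - r**2, 1e-300))
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    pvals = np.where(sx == 0, 1.0, np.clip(pvals, 0.0, 1.0))
    mask = bh_fdr(pvals, q=q)
    return AssociationResult(
        slopes=slopes, r=r, pvals=pvals, mask=mask, q=q, n_subjects=n
    )


@dataclass
class EfficiencyRegression:
    slope: float  # coefficient on efficiency, controlling for the covariate
    p_value: float  # two-sided p of that coefficient
    partial_r: float  # partial correlation of score and efficiency given control


def efficiency_performance_regression(
    efficiencies: np.ndarray,
    scores: np.ndarray,
    control: np.ndarray | None = None,
) -> EfficiencyRegression:
    """Score ~ efficiency (+ control covariate, typically the subject's
    global metastability)."""
    e = np.asarray(efficiencies, dtype=float)
    y = np.asarray(scores, dtype=float)
    if e.shape != y.shape:
        raise ValueError("efficiencies and scores must align")
    if control is None:
        control = np.zeros_like(e)
    c = np.asarray(control, dtype=float)
    if c.shape != e.shape:
        raise ValueError("control must align with efficiencies")
    if c.std() > 0 and e.std() > 0:
        rc = abs(float(np.corrcoef(e, c)[0, 1]))
        if rc > 0.999:
            warnings.warn(f"efficiency and control nearly collinear (|r|={rc:.4f})")
    X = sm.add_constant(np.column_stack([e, c]) if c.std() > 0 else e)
    fit = sm.OLS(y, X).fit()
    slope = float(fit.params[1])
    p = float(fit.pvalues[1])
    # partial correlation via double residualisation on the control
    if c.std() > 0:
        Zc = sm.add_constant(c)
        ry = y - Zc @ np.linalg.lstsq(Zc, y, rcond=None)[0]
        re = e - Zc @ np.linalg.lstsq(Zc, e, rcond=None)[0]
    else:
        ry, re = y - y.mean(), e - e.mean()
    denom = np.sqrt((ry**2).sum() * (re**2).sum())
    partial_r = float((ry * re).sum() / denom) if denom > 0 else 0.0
    return EfficiencyRegression(slope=slope, p_value=p, partial_r=partial_r)
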