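"""Task-general network architecture via PCA.

A subject's seven task interaction matrices are vectorized (upper
triangle including the diagonal: d(d+1)/2 = 105 entries for 14
networks) and entered into a PCA across tasks. The first principal
component is the subject's task-general architecture — the pattern of
network interactions shared by all tasks; its variance fraction says
how much of the between-task variance one pattern explains. A cohort
exemplar is the element-wise average of the per-subject patterns after
sign alignment. Applying the same PCA to task-minus-rest contrast
matrices splits the architecture into subnetworks whose metastability
is raised (positive pattern entries) or lowered (negative) by tasks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "vectorize_matrix",
    "devectorize_matrix",
    "task_general_pca",
    "exemplar_average",
    "contrast_decomposition",
    "TaskGeneralResult",
    "ContrastDecomposition",
]


def vectorize_matrix(M: np.ndarray, atol: float = 1e-9) -> np.ndarray:
    """Row-major upper triangle including the diagonal of a symmetric
    matrix; length d(d+1)/2."""
    M = np.asarray(M, dtype=float)
    d = M.shape[0]
    if M.shape != (d, d):
        raise ValueError("matrix must be square")
    if not np.allclose(M, M.T, atol=atol):
        raise ValueError("matrix is not symmetric within tolerance")
    iu = np.triu_indices(d)
    return M[iu]


def devectorize_matrix(v: np.ndarray) -> np.ndarray:
    """Inverse of :func:`vectorize_matrix` (exact round trip)."""
    v = np.asarray(v, dtype=float)
    m = v.size
    d = int((np.sqrt(8 * m + 1) - 1) / 2)
    if d * (d + 1) // 2 != m:
        raise ValueError(f"length {m} is not a triangular number")
    out = np.zeros((d, d))
    iu = np.triu_indices(d)
    out[iu] = v
    out = out + out.T - np.diag(np.diag(out))
    return out


@dataclass
class TaskGeneralResult:
    """PC1 of a tasks x connections stack."""

    pattern: np.ndarray  # 105-vector, in data units (sigma_1-scaled)
    pattern_matrix: np.ndarray  # devectorized 14x14 view
    loadings: np.ndarray  # one per task, unit norm
    variance_fraction: float  # PC1 share of total variance
    variance_fractions: np.ndarray  # all components, sums to 1
    mean: np.ndarray  # per-connection mean removed before the SVD


def _stack_pca(X: np.ndarray) -> TaskGeneralResult:
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 observations (tasks)")
    mean = X.mean(axis=0)
    Xc = X - mean
    total = float((Xc**2).sum())
    if total <= 1e-24 * max(float((X**2).sum()), 1e-30):
        raise ValueError("zero total variance: all task matrices identical")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    v1 = Vt[0]
    # Loadings are the unit-normalised projections of the *uncentered*
    # task vectors onto the PC1 axis. (After centering across tasks the
    # left singular vectors are exactly zero-mean, so they cannot carry
    # the expected all-positive structure; the uncentered projections
    # can, and for near-identical tasks they approach the equal-loading
    # value 1/sqrt(n_tasks).)
    proj = X @ v1
    norm = np.linalg.norm(proj)
    loadings = proj / norm if norm > 0 else np.zeros_like(proj)
    # sign convention: mean loading positive; tie-break along the data
    # mean, then by the dominant pattern entry
    m = loadings.mean()
    flip = False
    if abs(m) > 1e-9:
        flip = m < 0
    elif abs(float(v1 @ mean)) > 1e-12:
        flip = float(v1 @ mean) < 0
    else:
        flip = v1[np.argmax(np.abs(v1))] < 0
    if flip:
        v1, loadings = -v1, -loadings
    fractions = s**2 / (s**2).sum()
    pattern = s[0] * v1
    return TaskGeneralResult(
        pattern=pattern,
        pattern_matrix=devectorize_matrix(pattern),
        loadings=loadings,
        variance_fraction=float(fractions[0]),
        variance_fractions=fractions,
        mean=mean,
    )


def task_general_pca(task_matrices) -> TaskGeneralResult:
    """Per-subject PCA over task interaction matrices.

    ``task_matrices``: sequence of symmetric (d, d) arrays or
    :class:`~metanet.containers.InteractionMatrix`, one per task.
    Centering is across tasks only — connections share units, so no
    per-variable scaling is applied.
    """
    rows = [vectorize_matrix(getattr(M, "values", M)) for M in task_matrices]
    return _stack_pca(np.stack(rows))


def pooled_task_general_pca(per_subject_task_matrices) -> TaskGeneralResult:
    """Pooled variant: stack all subjects' task rows into one PCA."""
    rows = []
    for mats in per_subject_task_matrices:
        rows.extend(vectorize_matrix(getattr(M, "values", M)) for M in mats)
    return _stack_pca(np.stack(rows))


def exemplar_average(patterns) -> np.ndarray:
    """Cohort exemplar: element-wise mean of per-subject patterns after
    aligning each pattern's sign to the first subject's orientation (so
    antipodal patterns reinforce instead of cancelling).

    Returns the (d, d) matrix form.
    """
    vecs = [np.asarray(getattr(p, "pattern", p), dtype=float) for p in patterns]
    if not vecs:
        raise ValueError("need at least one pattern")
    ref = vecs[0]
    aligned = [v if float(v @ ref) >= 0 else -v for v in vecs]
    return devectorize_matrix(np.mean(aligned, axis=0))


@dataclass
class ContrastDecomposition:
    result: TaskGeneralResult
    high: np.ndarray  # boolean (d, d): metastability raised by tasks
    low: np.ndarray  # boolean (d, d): metastability lowered by tasks


def contrast_decomposition(task_minus_rest_matrices) -> ContrastDecomposition:
    """Partition connections into high/low subnetworks from the PC1 of
    task-minus-rest contrast matrices.

    Positive PC1 entries form the high-metastability subnetwork,
    negative entries the low; exact zeros stay unassigned.
    """
    res = task_general_pca(task_minus_rest_matrices)
    P = res.pattern_matrix
    return ContrastDecomposition(result=res, high=P > 0, low=P < 0)
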