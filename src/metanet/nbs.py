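"""Network-based statistic (NBS) over subjects' interaction matrices.

Connection-wise paired t statistics on (task - rest) differences are
thresholded; supra-threshold connections form edges of the 14-node
network graph, and the size (edge count) of the largest connected
component is the test statistic. A permutation null is built by
swapping each subject's task/rest labels independently (equivalent to
flipping the sign of that subject's difference matrix), and the
family-wise-error-corrected p value is the smoothed proportion of
permutations whose largest component is at least as large as observed.

Within-network (diagonal) entries are tested connections too: a
supra-threshold diagonal entry attaches to its node's component as a
self-loop and counts one edge, but cannot merge two nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "connectionwise_paired_stat",
    "supra_threshold_components",
    "nbs_permutation",
    "NBSResult",
    "Component",
]


def connectionwise_paired_stat(
    task_stack: np.ndarray, rest_stack: np.ndarray
) -> np.ndarray:
    """Paired t statistic per connection on (task - rest).

    Positive values mean higher in task. Zero-variance differences with
    a nonzero mean yield +/-inf (flagged by being non-finite); zero
    mean with zero variance yields 0.
    """
    task_stack = np.asarray(task_stack, dtype=float)
    rest_stack = np.asarray(rest_stack, dtype=float)
    if task_stack.shape != rest_stack.shape:
        raise ValueError("task and rest stacks must have identical shapes")
    n = task_stack.shape[0]
    if n < 3:
        raise ValueError("paired t needs at least 3 subjects")
    d = task_stack - rest_stack
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where((sd == 0) & (mean == 0), 0.0, t)
    return t


@dataclass
class Component:
    """A connected supra-threshold component: off-diagonal edges,
    attached self-loops, and total size in edges."""

    nodes: list[int]
    edges: list[tuple[int, int]]
    self_loops: list[int] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.edges) + len(self.self_loops)


def supra_threshold_components(
    stat: np.ndarray, thr: float, tail: str = "increase"
) -> list[Component]:
    """Connected components of the supra-threshold graph, largest first.

    ``tail='increase'`` keeps entries with stat > thr, ``'decrease'``
    keeps entries with -stat > thr. ``thr`` must be positive so the two
    one-sided tests are symmetric.
    """
    if thr <= 0:
        raise ValueError("threshold must be positive")
    if tail not in ("increase", "decrease"):
        raise ValueError(f"unknown tail: {tail!r}")
    stat = np.asarray(stat, dtype=float)
    signed = stat if tail == "increase" else -stat
    d = signed.shape[0]
    g = nx.Graph()
    for i in range(d):
        for j in range(i + 1, d):
            if signed[i, j] > thr:
                g.add_edge(i, j)
    loops = [i for i in range(d) if signed[i, i] > thr]
    for i in loops:
        g.add_node(i)
    comps = []
    for nodes in nx.connected_components(g):
        nodes = sorted(nodes)
        edges = [tuple(sorted(e)) for e in g.subgraph(nodes).edges]
        comps.append(
            Component(nodes=nodes, edges=sorted(edges),
                      self_loops=[i for i in loops if i in nodes])
        )
    return sorted(comps, key=lambda c: c.size, reverse=True)


def _max_component_sizes(supra: np.ndarray, iu_i: np.ndarray, iu_j: np.ndarray) -> np.ndarray:
    """Largest component size per row of a boolean (n_perm, n_entries)
    supra-threshold array over upper-triangle entries (incl. diagonal).

    Union-find on the 14-node graph; independent of networkx so the
    observed path has a structurally different implementation to check
    against.
    """
    n_perm = supra.shape[0]
    d = int(iu_i.max()) + 1
    off = iu_i != iu_j
    out = np.empty(n_perm, dtype=int)
    for p in range(n_perm):
        parent = list(range(d))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        active = np.flatnonzero(supra[p])
        for e in active:
            if off[e]:
                ri, rj = find(int(iu_i[e])), find(int(iu_j[e]))
                if ri != rj:
                    parent[rj] = ri
        sizes: dict[int, int] = {}
        for e in active:
            r = find(int(iu_i[e]))
            sizes[r] = sizes.get(r, 0) + 1
        out[p] = max(sizes.values()) if sizes else 0
    return out


@dataclass
class NBSResult:
    threshold: float
    tail: str
    components: list[Component]
    observed_size: int
    null_max_sizes: np.ndarray
    p_value: float
    n_perm: int
    seed: int


def nbs_permutation(
    task_stack: np.ndarray,
    rest_stack: np.ndarray,
    thr: float = 3.0,
    n_perm: int = 5000,
    seed: int = 0,
    tail: str = "increase",
) -> NBSResult:
    """Full NBS: observed components plus a paired-permutation null.

    The p value uses +1 smoothing, p = (1 + #{null >= observed}) /
    (1 + n_perm), so it is never exactly zero.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; p values will be coarse")
    task_stack = np.asarray(task_stack, dtype=float)
    rest_stack = np.asarray(rest_stack, dtype=float)
    stat = connectionwise_paired_stat(task_stack, rest_stack)
    comps = supra_threshold_components(stat, thr, tail)
    observed = comps[0].size if comps else 0

    n, d, _ = task_stack.shape
    iu_i, iu_j = np.triu_indices(d)
    diff = (task_stack - rest_stack)[:, iu_i, iu_j]  # (n, entries)
    sq_sum = (diff**2).sum(axis=0)  # invariant under sign flips
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    mean = signs @ diff / n  # (n_perm, entries)
    var = (sq_sum[None, :] - n * mean**2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_null = mean / np.sqrt(var / n)
    t_null = np.where((var == 0) & (mean == 0), 0.0, t_null)
    signed = t_null if tail == "increase" else -t_null
    null_sizes = _max_component_sizes(signed > thr, iu_i, iu_j)
    p = (1.0 + int(np.sum(null_sizes >= observed))) / (1.0 + n_perm)
    return NBSResult(
        threshold=thr,
        tail=tail,
        components=comps,
        observed_size=observed,
        null_max_sizes=null_sizes,
        p_value=p,
        n_perm=n_perm,
        seed=seed,
    )
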