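"""Weighted modularity, spectral module detection, and null networks.

Modularity of a partition is

    Q = 1/(2m) * sum_ij [ a_ij - k_i * k_j / (2m) ] * delta(c_i, c_j)

with k_i the node strength and m the total weight (the weighted
generalization of degree and edge count). Modules are found by recursive
spectral bisection on the sign of the leading eigenvector of the
generalized modularity matrix, with a Kernighan-Lin-style single-node-move
refinement after each bisection; a subgroup is indivisible when its leading
eigenvalue or the best achievable modularity gain is nonpositive. Null
networks preserve the binary degree sequence exactly (double-edge swaps)
and reuse the original weight multiset in random order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix

from modreorg.connectivity import (
    ConnectivityMatrix,
    WeightedGraph,
    positive_graph,
    threshold_by_edge_count,
)

logger = logging.getLogger("modreorg")

_EIG_TOL = 1e-10
_DQ_TOL = 1e-10
_ZERO_ENTRY_TOL = 1e-12


@dataclass
class ModulePartition:
    """Module label per node (contiguous labels 1..M) plus its modularity."""

    labels: np.ndarray
    Q: float
    source: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(1, present.size + 1)):
            raise ValueError("module labels must be contiguous 1..M")

    @property
    def n_modules(self) -> int:
        return int(self.labels.max())

    def members(self, module: int) -> np.ndarray:
        """0-based node indices of one module."""
        return np.flatnonzero(self.labels == module)


def modularity_q(g: WeightedGraph, assignment: np.ndarray) -> float:
    """Evaluate Q for a given node -> module assignment."""
    w = g.weights
    labels = np.asarray(assignment)
    if labels.shape[0] != g.n_nodes:
        raise ValueError("assignment must cover every node")
    two_m = 2.0 * g.total_weight
    if two_m <= 0:
        raise ValueError("modularity undefined for a graph with no weight "
                         "(m = 0)")
    k = g.strengths
    q = 0.0
    for c in np.unique(labels):
        idx = labels == c
        q += w[np.ix_(idx, idx)].sum() / two_m - (k[idx].sum() / two_m) ** 2
    return float(q)


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Renumber labels 1..M by descending module size (ties: first seen)."""
    uniq, counts = np.unique(labels, return_counts=True)
    order = np.argsort(-counts, kind="stable")
    mapping = {int(uniq[o]): rank + 1 for rank, o in enumerate(order)}
    return np.array([mapping[int(c)] for c in labels], dtype=int)


def _refine_bisection(bsub: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Kernighan-Lin-style refinement of a +-1 split.

    Each pass moves every node exactly once (always the best available
    flip, even if its immediate gain is negative), tracks the best
    intermediate state, and restarts from it while passes keep improving.
    Flipping node i changes s^T B s by 4 * (B_ii - s_i * (B s)_i).
    """
    n = len(s)
    s = s.copy()
    diag = np.diag(bsub)
    best_val = _split_value(bsub, s)
    while True:
        trial = s.copy()
        moved = np.zeros(n, dtype=bool)
        pass_best_val = best_val
        pass_best_s = None
        running = best_val
        for _ in range(n):
            bs = bsub @ trial
            gains = 4.0 * (diag - trial * bs)
            gains[moved] = -np.inf
            pick = int(np.argmax(gains))
            trial[pick] = -trial[pick]
            moved[pick] = True
            running += gains[pick]
            if running > pass_best_val + _DQ_TOL and not (
                    np.all(trial == 1) or np.all(trial == -1)):
                pass_best_val = running
                pass_best_s = trial.copy()
        if pass_best_s is None:
            return s
        s = pass_best_s
        best_val = pass_best_val


def _split_value(bsub: np.ndarray, s: np.ndarray) -> float:
    return float(s @ bsub @ s)


def _best_sweep_cut(bsub: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Best threshold split along the eigenvector ordering.

    Nodes sorted by eigenvector value; every prefix/suffix cut is scored by
    s^T B s, maintained incrementally (flipping node i changes the score by
    4 * (B_ii - s_i (B s)_i)).
    """
    order = np.argsort(-v, kind="stable")
    s = -np.ones(len(v))
    bs = bsub @ s
    val = float(s @ bs)
    best_val, best_k = -np.inf, 0
    for k in range(len(v) - 1):
        i = order[k]
        val += 4.0 * (bsub[i, i] - s[i] * bs[i])
        s[i] = 1.0
        bs += 2.0 * bsub[:, i]
        if val > best_val:
            best_val, best_k = val, k
    s = -np.ones(len(v))
    s[order[:best_k + 1]] = 1.0
    return s


def _bisect(bsub: np.ndarray, refine: bool,
            min_value: float = _DQ_TOL) -> np.ndarray | None:
    """Best +-1 split of the subgroup, or None if none beats ``min_value``.

    Candidates: the sign split of the leading eigenvector and the best
    sweep cut along its ordering, each KL-refined. ``min_value=-inf``
    forces the best split even when it lowers Q (used as a deterministic
    perturbation by `detect_modules`).
    """
    eigval, eigvec = np.linalg.eigh(bsub)
    if eigval[-1] <= _EIG_TOL and min_value >= _DQ_TOL:
        return None
    v = eigvec[:, -1]
    candidates = [np.where(v >= -_ZERO_ENTRY_TOL, 1.0, -1.0),
                  _best_sweep_cut(bsub, v)]
    best_s, best_val = None, min_value
    for s in candidates:
        if refine:
            s = _refine_bisection(bsub, s)
        if np.all(s == s[0]):
            continue
        val = _split_value(bsub, s)
        if val > best_val:
            best_s, best_val = s, val
    return best_s


def _kl_partition_pass(b: np.ndarray, labels: np.ndarray
                       ) -> tuple[np.ndarray, float]:
    """One Kernighan-Lin pass over the whole partition.

    Every node moves exactly once to its best alternative module — an
    existing one or a fresh singleton — even when the immediate gain is
    negative; the best intermediate state is returned with its cumulative
    gain. Moving node i from module a to b changes sum_ij B_ij
    delta(c_i, c_j) by 2 * (S_ib - (S_ia - B_ii)) with S = B @ onehot;
    for a fresh module S_ib = 0.
    """
    n = len(labels)
    diag = np.diag(b)
    trial = labels.copy()
    # dense module columns: existing labels plus one spare empty column
    mods = list(np.unique(trial))
    col = {m: j for j, m in enumerate(mods)}
    cidx = np.array([col[c] for c in trial])
    s = np.zeros((n, len(mods) + 1))
    for m, j in col.items():
        s[:, j] = b[:, trial == m].sum(axis=1)
    col_label: list = mods + [None]
    next_label = max(mods) + 1
    rows = np.arange(n)
    moved = np.zeros(n, dtype=bool)
    running = 0.0
    best_gain, best_state = 0.0, None
    # a long stretch of non-improving moves will not recover: cut the pass
    stale_limit = max(20, n // 4)
    stale = 0
    for _ in range(n):
        own = s[rows, cidx]
        gains = s - (own - diag)[:, None]
        gains[rows, cidx] = -np.inf
        gains[moved] = -np.inf
        flat = int(np.argmax(gains))
        i, j = divmod(flat, s.shape[1])
        if not np.isfinite(gains[i, j]):
            break
        src = cidx[i]
        if j == s.shape[1] - 1:  # fresh singleton module
            label = next_label
            next_label += 1
            col_label[j] = label
            col_label.append(None)
            s = np.column_stack([s, np.zeros(n)])
        else:
            label = col_label[j]
        s[:, src] -= b[:, i]
        s[:, j] += b[:, i]
        trial[i] = label
        cidx[i] = j
        moved[i] = True
        running += 2.0 * gains[i, j]
        if running > best_gain + _DQ_TOL:
            best_gain = running
            best_state = trial.copy()
            stale = 0
        else:
            stale += 1
            if stale > stale_limit:
                break
    if best_state is None:
        return labels, 0.0
    return best_state, best_gain


def _refine_partition(b: np.ndarray, two_m: float,
                      labels: np.ndarray) -> np.ndarray:
    """Partition-level cleanup: KL node-move passes alternated with
    whole-module merges (merging a and b changes 2m*Q by
    2 * sum_{i in a, j in b} B_ij), repeated while Q increases."""
    labels = labels.copy()
    while True:
        changed = False
        while True:
            labels, gain = _kl_partition_pass(b, labels)
            if gain <= _DQ_TOL:
                break
            changed = True
        mods = np.unique(labels)
        if len(mods) > 1:
            onehot = (labels[:, None] == mods[None, :]).astype(float)
            cross = onehot.T @ b @ onehot
            np.fill_diagonal(cross, -np.inf)
            a_i, b_i = np.unravel_index(np.argmax(cross), cross.shape)
            if cross[a_i, b_i] > _DQ_TOL:
                labels[labels == mods[b_i]] = mods[a_i]
                changed = True
        if not changed:
            return labels


def _perturb_and_refine(g: WeightedGraph, b: np.ndarray, two_m: float,
                        labels: np.ndarray) -> np.ndarray:
    """Escape bisection-order local optima.

    Greedy recursive bisection can be unable to reach the best partition
    even when each individual cut is optimal. This loop force-splits one
    module at a time (best internal bisection, accepted even at a loss),
    re-runs the KL/merge refinement, and keeps the perturbed partition
    only when total Q strictly improves. Deterministic; terminates because
    Q increases at every acceptance.
    """
    best_q = modularity_q(g, labels)
    improved = True
    while improved:
        improved = False
        for lab in np.unique(labels):
            idx = np.flatnonzero(labels == lab)
            if idx.size < 2:
                continue
            bsub = b[np.ix_(idx, idx)].copy()
            np.fill_diagonal(bsub, np.diag(bsub) - bsub.sum(axis=1))
            s = _bisect(bsub, refine=True, min_value=-np.inf)
            if s is None:
                continue
            trial = labels.copy()
            trial[idx[s > 0]] = labels.max() + 1
            trial = _refine_partition(b, two_m, trial)
            q = modularity_q(g, trial)
            if q > best_q + _DQ_TOL:
                labels, best_q = trial, q
                improved = True
                break
    return labels


def detect_modules(g: WeightedGraph, refine: bool = True,
                   source: str = "") -> ModulePartition:
    """Recursive spectral bisection with single-node-move refinement.

    Connected components are divided independently (a singleton component
    becomes its own module); within each, bisection recurses on the
    generalized modularity matrix of the subgroup until no division
    increases Q. Labels are renumbered 1..M by descending module size.
    """
    w = g.weights
    n = g.n_nodes
    two_m = 2.0 * g.total_weight
    if two_m <= 0:
        raise ValueError("cannot detect modules on an empty graph (m = 0)")
    k = g.strengths
    b = w - np.outer(k, k) / two_m

    n_comp, comp = connected_components(csr_matrix(w != 0), directed=False)
    labels = np.zeros(n, dtype=int)
    next_label = 1
    stack: list[np.ndarray] = []
    for c in range(n_comp):
        stack.append(np.flatnonzero(comp == c))
    final_groups: list[np.ndarray] = []
    while stack:
        idx = stack.pop()
        if idx.size == 1:
            final_groups.append(idx)
            continue
        bsub = b[np.ix_(idx, idx)].copy()
        # generalized modularity matrix: remove subgroup row sums from the
        # diagonal so dividing the subgroup leaves the rest of Q unchanged
        np.fill_diagonal(bsub, np.diag(bsub) - bsub.sum(axis=1))
        s = _bisect(bsub, refine)
        if s is None:
            final_groups.append(idx)
        else:
            stack.append(idx[s > 0])
            stack.append(idx[s < 0])
    for grp in final_groups:
        labels[grp] = next_label
        next_label += 1
    if refine:
        labels = _refine_partition(b, two_m, labels)
        labels = _perturb_and_refine(g, b, two_m, labels)
    labels = _relabel_by_size(labels)
    return ModulePartition(labels=labels, Q=modularity_q(g, labels),
                           source=source)


def random_equivalent(g: WeightedGraph,
                      seed: int | np.random.Generator = 0) -> WeightedGraph:
    """Degree-preserving null: Maslov-Sneppen double-edge swaps on the
    binarized topology (10x edge count attempted swaps), then the original
    weight multiset reassigned to the rewired edges in random order."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    w = g.weights
    n = w.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    mask = w[iu, ju] > 0
    edges = list(zip(iu[mask].tolist(), ju[mask].tolist()))
    weights = w[iu, ju][mask]
    ne = len(edges)
    if ne < 2:
        raise ValueError("null model needs a graph with at least 2 edges")

    edge_set = set(edges)
    attempts = 10 * ne
    swapped = 0
    pick = rng.integers(0, ne, size=(attempts, 2))
    coin = rng.random(attempts)
    for t in range(attempts):
        e1, e2 = pick[t]
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if coin[t] < 0.5:
            c, d = d, c
        # propose (a, c) and (b, d)
        if a == c or b == d:
            continue
        new1 = (min(a, c), max(a, c))
        new2 = (min(b, d), max(b, d))
        if new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard(edges[e1])
        edge_set.discard(edges[e2])
        edge_set.add(new1)
        edge_set.add(new2)
        edges[e1] = new1
        edges[e2] = new2
        swapped += 1
    if swapped == 0:
        logger.warning("random_equivalent: no legal swap found; returning "
                       "weight-reshuffled original topology")
    out = np.zeros_like(w)
    perm = rng.permutation(ne)
    for (i, j), wt in zip(edges, weights[perm]):
        out[i, j] = wt
        out[j, i] = wt
    return WeightedGraph(out)


@dataclass
class QCurve:
    """Per-subject Q vs edge count with null statistics and a per-ne
    two-sample group comparison (Bonferroni-corrected across the grid)."""

    ne_grid: tuple[int, ...]
    subject_rows: list[dict] = field(default_factory=list)
    group_rows: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"ne_grid": list(self.ne_grid),
                "subjects": self.subject_rows,
                "group_comparison": self.group_rows}


def q_curve(cohorts: dict[str, list[ConnectivityMatrix]],
            ne_grid: tuple[int, ...],
            n_null: int = 100, seed: int = 0,
            refine: bool = True) -> QCurve:
    """For each subject and edge count: sparsify, detect modules, and
    compare Q to ``n_null`` seeded degree-preserving nulls; then test the
    group difference in subject Q at every grid point (Welch two-sample t,
    two-sided), Bonferroni-corrected across the grid."""
    if len(cohorts) != 2:
        raise ValueError("q_curve compares exactly two groups")
    ne_grid = tuple(int(x) for x in ne_grid)
    curve = QCurve(ne_grid=ne_grid)
    q_by_group: dict[str, dict[int, list[float]]] = {
        grp: {ne: [] for ne in ne_grid} for grp in cohorts}
    ss = np.random.SeedSequence(seed)
    for grp, mats in cohorts.items():
        for cm in mats:
            sub_ss = ss.spawn(1)[0]
            for ne in ne_grid:
                sparse = threshold_by_edge_count(positive_graph(cm), ne)
                part = detect_modules(sparse, refine=refine)
                null_q = []
                rng = np.random.default_rng(sub_ss.spawn(1)[0])
                for _ in range(n_null):
                    null_g = random_equivalent(sparse, rng)
                    null_q.append(detect_modules(null_g, refine=refine).Q)
                null_q = np.array(null_q)
                curve.subject_rows.append({
                    "subject_id": cm.subject_id, "group": grp, "ne": ne,
                    "Q": part.Q,
                    "Q_random_mean": float(null_q.mean()),
                    "Q_random_sd": float(null_q.std(ddof=1))
                    if n_null > 1 else 0.0,
                })
                q_by_group[grp][ne].append(part.Q)
    g1, g2 = list(cohorts)
    n_tests = len(ne_grid)
    for ne in ne_grid:
        t, p = stats.ttest_ind(q_by_group[g1][ne], q_by_group[g2][ne],
                               equal_var=False)
        curve.group_rows.append({
            "ne": ne, "t": float(t), "p_raw": float(p),
            "p_corrected": float(min(1.0, p * n_tests)),
        })
    return curve
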