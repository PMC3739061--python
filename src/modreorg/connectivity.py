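"""Per-subject correlation networks and the mean/std group network.

A subject's network is the zero-lag Pearson correlation matrix of its
region time courses (``cc``), with the edge-distance view ``1 - cc``
available on demand. The group network divides the entrywise mean of the
subjects' matrices by their entrywise standard deviation (population form,
1/n inside the root) and keeps only entries with a positive mean —
negative group-mean correlations are masked to zero before any modular
analysis. No Fisher z-transform is applied anywhere: all stages consume
raw correlation values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from modreorg.atlas_io import SubjectTimeSeries

logger = logging.getLogger("modreorg")


@dataclass
class ConnectivityMatrix:
    """One subject's N x N Pearson correlation matrix."""

    subject_id: str
    cc: np.ndarray
    group: str = ""

    def __post_init__(self) -> None:
        self.cc = np.asarray(self.cc, dtype=float)
        n = self.cc.shape[0]
        if self.cc.shape != (n, n):
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(self.cc, self.cc.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if not np.allclose(np.diag(self.cc), 1.0, atol=1e-12):
            raise ValueError("connectivity matrix must have unit diagonal")
        if np.max(np.abs(self.cc)) > 1 + 1e-12:
            raise ValueError("correlation entries must lie in [-1, 1]")

    @property
    def n_regions(self) -> int:
        return self.cc.shape[0]

    @property
    def distance(self) -> np.ndarray:
        """Edge distances d_ij = 1 - cc_ij."""
        return 1.0 - self.cc


@dataclass
class GroupNetwork:
    """Positive-masked mean/std network over a cohort."""

    a: np.ndarray
    mean_cc: np.ndarray
    n_subjects: int

    @property
    def n_regions(self) -> int:
        return self.a.shape[0]


@dataclass
class WeightedGraph:
    """Symmetric nonnegative weight matrix with no self-loops."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weight matrix must be symmetric")
        if np.any(w < 0):
            raise ValueError("weight matrix must be nonnegative "
                             "(positive-masked graphs only)")
        w = w.copy()
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def strengths(self) -> np.ndarray:
        """Node strengths k_i (weighted degree)."""
        return self.weights.sum(axis=1)

    @property
    def total_weight(self) -> float:
        """m = half the sum of all weights."""
        return float(self.weights.sum()) / 2.0

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    def binarized(self) -> "WeightedGraph":
        return WeightedGraph((self.weights > 0).astype(float))


def subject_connectivity(ts: SubjectTimeSeries,
                         region_ids: list[int] | None = None
                         ) -> ConnectivityMatrix:
    """Zero-lag Pearson correlation of every region pair."""
    data = ts.data
    sd = data.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = ([region_ids[i] for i in dead[:5]] if region_ids
                 else list(dead[:5] + 1))
        raise ValueError(
            f"subject {ts.subject_id}: zero-variance time course for "
            f"region(s) {names} — correlation undefined"
        )
    cc = np.corrcoef(data, rowvar=False)
    cc = np.clip((cc + cc.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(cc, 1.0)
    return ConnectivityMatrix(subject_id=ts.subject_id, cc=cc, group=ts.group)


def group_network(mats: list[ConnectivityMatrix],
                  std_mode: str = "population",
                  positive_mask: str = "group") -> GroupNetwork:
    """Entrywise mean over subjects divided by entrywise std.

    ``std_mode="population"`` puts 1/n inside the root (the printed form);
    ``"sample"`` uses 1/(n-1). ``positive_mask="group"`` masks entries whose
    group mean is <= 0 after the ratio; ``"subject"`` additionally clips
    negative per-subject correlations to 0 before the mean/std. Entries with
    zero std and positive mean are capped at the largest finite ratio in the
    matrix (warned) so downstream eigen-decompositions stay finite.
    """
    if len(mats) < 2:
        raise ValueError("group network needs at least 2 subjects "
                         "(standard deviation undefined otherwise)")
    n = mats[0].n_regions
    if any(m.n_regions != n for m in mats):
        raise ValueError("all subjects must share the same region count")
    if std_mode not in ("population", "sample"):
        raise ValueError(f"unknown std_mode {std_mode!r}")
    if positive_mask not in ("group", "subject"):
        raise ValueError(f"unknown positive_mask {positive_mask!r}")

    stack = np.stack([m.cc for m in mats])
    if positive_mask == "subject":
        stack = np.clip(stack, 0.0, None)
    mean = stack.mean(axis=0)
    ddof = 0 if std_mode == "population" else 1
    std = stack.std(axis=0, ddof=ddof)

    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(std > 0, mean / np.where(std > 0, std, 1.0), np.inf)
    a[mean <= 0] = 0.0
    degenerate = np.isinf(a)
    np.fill_diagonal(degenerate, False)
    if degenerate.any():
        finite = a[np.isfinite(a)]
        cap = float(finite.max()) if finite.size else 1.0
        logger.warning(
            "group network: %d edge(s) with zero inter-subject variance "
            "capped at %.4g", int(degenerate.sum()) // 2, cap)
        a[degenerate] = cap
    np.fill_diagonal(a, 0.0)
    a = (a + a.T) / 2.0
    return GroupNetwork(a=a, mean_cc=mean, n_subjects=len(mats))


def _as_weight_matrix(g) -> np.ndarray:
    if isinstance(g, WeightedGraph):
        return g.weights
    if isinstance(g, ConnectivityMatrix):
        w = g.cc.copy()
        np.fill_diagonal(w, 0.0)
        return w
    if isinstance(g, GroupNetwork):
        return g.a
    return np.asarray(g, dtype=float)


def positive_graph(cm) -> WeightedGraph:
    """Positive-masked weighted graph view of a connectivity object."""
    w = _as_weight_matrix(cm)
    return WeightedGraph(np.clip(w, 0.0, None))


def threshold_by_edge_count(g, ne: int) -> WeightedGraph:
    """Keep the ``ne`` largest strictly positive weights (upper triangle).

    Retained weights are unchanged; ties at the cutoff are broken by lower
    (i, j) lexicographic order, so the result is deterministic.
    """
    w = _as_weight_matrix(g)
    n = w.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = w[iu, ju]
    pos = vals > 0
    n_pos = int(pos.sum())
    if not 1 <= ne <= n_pos:
        raise ValueError(f"ne={ne} out of range: graph has {n_pos} "
                         "strictly positive edges")
    # triu_indices is already (i, j)-lexicographic; stable sort on -weight
    # therefore breaks ties toward lower (i, j).
    order = np.argsort(-vals, kind="stable")
    keep = order[pos[order]][:ne]
    out = np.zeros_like(w)
    out[iu[keep], ju[keep]] = vals[keep]
    return WeightedGraph(out + out.T)
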