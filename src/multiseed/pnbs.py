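"""Paired network-based statistic (pNBS).

Detects connectivity modulation between two resting-state sessions in a
paired two-group design (an experimental group with an intervention
between sessions, a control group without).  Because subjects are
paired across sessions, the classical between-group NBS permutation is
not applicable; instead the control group's session-to-session
variability defines the first-level threshold:

1. per-connection paired t-tests of the (post - pre) Fisher-z
   differences, separately per group;
2. the first-level p cutoff is the value with exactly 1% (by default)
   of control connections at or below it — the control group's
   "hypothetical false positives";
3. the same cutoff is applied to the experimental group; every
   supra-threshold connected component whose edge count is <= the
   control group's largest component is eliminated.  The statistic k
   is the total number of surviving edges (possibly spanning several
   components).

Family-wise-error control comes from permuting subjects' difference
matrices between the two groups and recomputing steps 1-3 (threshold
included) each time: p_fwe = #(k' > k) / M.  Designs small enough to
enumerate are enumerated exhaustively.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .types import ConnectivityMatrix

__all__ = [
    "DifferenceMatrix",
    "PnbsResult",
    "difference_matrices",
    "paired_t_pvalues",
    "first_level_threshold",
    "supra_components",
    "pnbs_test",
    "connection_set_from_matrices",
    "connection_set_from_graphs",
]

logger = logging.getLogger(__name__)


@dataclass
class DifferenceMatrix:
    """Per-subject elementwise (post - pre) Fisher-z difference matrix."""

    values: np.ndarray
    subject_id: str
    group: str
    directed: bool
    region_ids: np.ndarray


@dataclass
class PnbsResult:
    threshold_p: float
    surviving_edges: list[tuple[int, int, float]]  # (region i, region j, t statistic)
    k: int
    control_max_component: int
    null_sizes: np.ndarray
    p_fwe: float
    n_permutations: int
    seed: int | None
    exhaustive: bool = False
    connection_set: np.ndarray = field(default=None)  # type: ignore[assignment]


def difference_matrices(
    pairs: dict[str, tuple[ConnectivityMatrix, ConnectivityMatrix]],
    groups: dict[str, str],
) -> list[DifferenceMatrix]:
    """Elementwise post - pre per subject.

    ``pairs`` maps subject id to its (pre, post) Fisher-z matrices;
    ``groups`` maps subject id to its group label.
    """
    out = []
    ref: ConnectivityMatrix | None = None
    for sid, pair in pairs.items():
        if len(pair) != 2 or pair[0] is None or pair[1] is None:
            raise ValueError(f"subject {sid} is missing a session")
        pre, post = pair
        for m in (pre, post):
            if m.scale != "fisher_z":
                raise ValueError("difference matrices require Fisher-z scale inputs")
        if ref is None:
            ref = pre
        if not np.array_equal(pre.region_ids, ref.region_ids) or not np.array_equal(
            post.region_ids, ref.region_ids
        ):
            raise ValueError("all matrices must share one region order")
        if pre.directed != ref.directed or post.directed != ref.directed:
            raise ValueError("directedness must be consistent across subjects")
        out.append(
            DifferenceMatrix(
                values=post.values - pre.values,
                subject_id=sid,
                group=groups[sid],
                directed=pre.directed,
                region_ids=ref.region_ids,
            )
        )
    return out


def _paired_t(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-sample t of differences vs 0 along axis 0; zero-variance -> t=0, p=1."""
    n = x.shape[0]
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    degenerate = sd < 1e-14
    safe_sd = np.where(degenerate, 1.0, sd)
    t = mean / (safe_sd / math.sqrt(n))
    t = np.where(degenerate, 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), n - 1)
    p = np.where(degenerate, 1.0, p)
    return t, p


def paired_t_pvalues(diffs: list[DifferenceMatrix]) -> tuple[np.ndarray, np.ndarray]:
    """Per-connection paired t statistic and two-sided p matrix.

    Connections whose difference is identical across subjects (zero
    variance) get t = 0, p = 1 and a log notice.
    """
    if len(diffs) < 3:
        raise ValueError("paired t-test needs at least 3 subjects")
    arr = np.stack([d.values for d in diffs])
    t, p = _paired_t(arr)
    n_degenerate = int((p == 1.0).sum() - arr.shape[1])  # diagonal is always degenerate
    if n_degenerate > 0:
        logger.info("%d off-diagonal connections had zero variance (p set to 1)", n_degenerate)
    return t, p


def first_level_threshold(control_p: np.ndarray, fraction: float = 0.01) -> float:
    """p cutoff under which exactly floor(fraction * m) control connections fall.

    The cutoff is the floor(fraction*m)-th smallest control p-value, so
    the control group contributes exactly that many supra-threshold
    ("hypothetical false positive") connections.
    """
    p = np.asarray(control_p, dtype=float).ravel()
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    n_supra = int(math.floor(fraction * p.size))
    if n_supra < 1:
        raise ValueError(
            f"{p.size} connections at fraction {fraction} leave no supra-threshold link"
        )
    return float(np.partition(p, n_supra - 1)[n_supra - 1])


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self) -> None:
        self.parent: dict[int, int] = {}

    def find(self, x: int) -> int:
        parent = self.parent
        root = parent.setdefault(x, x)
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _component_edge_counts(edges: np.ndarray) -> tuple[np.ndarray, dict[int, int]]:
    """Root label per edge and edge count per component (weak connectivity)."""
    uf = _UnionFind()
    for i, j in edges:
        uf.union(int(i), int(j))
    roots = np.array([uf.find(int(i)) for i, _ in edges], dtype=int)
    counts: dict[int, int] = {}
    for r in roots:
        counts[r] = counts.get(r, 0) + 1
    return roots, counts


def supra_components(
    exp_p: np.ndarray,
    cutoff: float,
    control_p: np.ndarray,
    connection_set: np.ndarray,
) -> tuple[np.ndarray, int, int]:
    """Apply the component-elimination rule (step 3).

    ``connection_set`` is an (m, 2) array of region-id pairs aligned
    with the flat p-value vectors.  Components are taken on the
    undirected skeleton and sized by edge count.  Returns the indices
    (into the connection set) of surviving experimental edges, k, and
    the control group's largest supra-threshold component size.
    """
    connection_set = np.asarray(connection_set)
    if connection_set.size == 0:
        raise ValueError("empty connection set")
    ctrl_idx = np.nonzero(np.asarray(control_p).ravel() <= cutoff)[0]
    control_max = 0
    if ctrl_idx.size:
        _, counts = _component_edge_counts(connection_set[ctrl_idx])
        control_max = max(counts.values())
    exp_idx = np.nonzero(np.asarray(exp_p).ravel() <= cutoff)[0]
    if exp_idx.size == 0:
        return exp_idx, 0, control_max
    roots, counts = _component_edge_counts(connection_set[exp_idx])
    keep = np.array([counts[r] > control_max for r in roots])
    surviving = exp_idx[keep]
    return surviving, int(surviving.size), control_max


def connection_set_from_matrices(example: ConnectivityMatrix | DifferenceMatrix) -> np.ndarray:
    """All off-diagonal connections (unique pairs when undirected)."""
    ids = np.asarray(example.region_ids)
    n = ids.size
    if example.directed:
        src, dst = np.nonzero(~np.eye(n, dtype=bool))
    else:
        src, dst = np.triu_indices(n, k=1)
    return np.column_stack([ids[src], ids[dst]])


def connection_set_from_graphs(graphs) -> np.ndarray:
    """Union of the edges of several thresholded graphs.

    The typical analyzed set: the union of connections present in the
    four group-average pre/post networks at the chosen average-degree
    threshold.  Directed edges are collapsed onto unique pairs.
    """
    pairs: set[tuple[int, int]] = set()
    for g in graphs:
        for u, v in g.graph.edges():
            pairs.add((min(int(u), int(v)), max(int(u), int(v))))
    if not pairs:
        raise ValueError("the graphs contribute no connections")
    return np.array(sorted(pairs), dtype=int)


def _edge_index(
    connection_set: np.ndarray, region_ids: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    pos = {int(r): i for i, r in enumerate(region_ids)}
    src = np.array([pos[int(i)] for i, _ in connection_set])
    dst = np.array([pos[int(j)] for _, j in connection_set])
    return src, dst


def _pnbs_statistic(
    control: np.ndarray,
    experimental: np.ndarray,
    connection_set: np.ndarray,
    fraction: float,
) -> tuple[int, np.ndarray, float, int, np.ndarray]:
    """Steps 1-3 for one labelling; returns (k, surviving idx, cutoff, control max, exp t)."""
    _, p_ctrl = _paired_t(control)
    cutoff = first_level_threshold(p_ctrl, fraction)
    t_exp, p_exp = _paired_t(experimental)
    surviving, k, control_max = supra_components(p_exp, cutoff, p_ctrl, connection_set)
    return k, surviving, cutoff, control_max, t_exp


def pnbs_test(
    control_diffs: list[DifferenceMatrix],
    exp_diffs: list[DifferenceMatrix],
    connection_set: np.ndarray | None = None,
    fraction: float = 0.01,
    n_permutations: int = 5000,
    seed: int | None = None,
    tie_rule: str = "gt",
) -> PnbsResult:
    """Full paired network-based statistic with permutation FWE control.

    Each permutation reassigns the subjects' difference matrices to
    pseudo-groups of the original sizes and recomputes steps 1-3,
    including re-deriving the first-level threshold.  When the number
    of distinct assignments is <= ``n_permutations`` they are
    enumerated exhaustively (no seed needed); otherwise ``seed`` is
    mandatory.  ``tie_rule='gt'`` counts permutations with k' > k
    (so ties favour significance); ``'ge'`` is the conservative
    variant.
    """
    if len(control_diffs) < 3 or len(exp_diffs) < 3:
        raise ValueError("each group needs at least 3 subjects")
    if tie_rule not in ("gt", "ge"):
        raise ValueError("tie_rule must be 'gt' or 'ge'")
    if n_permutations < 100:
        logger.warning("M = %d permutations is too small for stable p-values", n_permutations)
    example = control_diffs[0]
    if connection_set is None:
        connection_set = connection_set_from_matrices(example)
    connection_set = np.asarray(connection_set)
    src, dst = _edge_index(connection_set, example.region_ids)
    ctrl = np.stack([d.values[src, dst] for d in control_diffs])
    expm = np.stack([d.values[src, dst] for d in exp_diffs])
    n1, n2 = ctrl.shape[0], expm.shape[0]
    k, surviving_idx, cutoff, control_max, t_exp = _pnbs_statistic(
        ctrl, expm, connection_set, fraction
    )
    surviving_edges = [
        (int(connection_set[e, 0]), int(connection_set[e, 1]), float(t_exp[e]))
        for e in surviving_idx
    ]
    pooled = np.concatenate([ctrl, expm], axis=0)
    n_total = n1 + n2
    n_distinct = math.comb(n_total, n1)
    exhaustive = n_distinct <= n_permutations
    if exhaustive:
        assignments = [np.array(c) for c in combinations(range(n_total), n1)]
    else:
        if seed is None:
            raise ValueError("seed is mandatory for random permutation sampling")
        rng = np.random.default_rng(seed)
        assignments = [rng.permutation(n_total)[:n1] for _ in range(n_permutations)]
    null_sizes = np.empty(len(assignments), dtype=int)
    all_idx = np.arange(n_total)
    for a, ctrl_take in enumerate(assignments):
        mask = np.zeros(n_total, dtype=bool)
        mask[ctrl_take] = True
        k_perm, *_ = _pnbs_statistic(
            pooled[mask], pooled[all_idx[~mask]], connection_set, fraction
        )
        null_sizes[a] = k_perm
    if tie_rule == "gt":
        p_fwe = float((null_sizes > k).sum()) / len(assignments)
    else:
        p_fwe = float((null_sizes >= k).sum()) / len(assignments)
    return PnbsResult(
        threshold_p=cutoff,
        surviving_edges=surviving_edges,
        k=int(k),
        control_max_component=int(control_max),
        null_sizes=null_sizes,
        p_fwe=p_fwe,
        n_permutations=len(assignments),
        seed=seed,
        exhaustive=exhaustive,
        connection_set=connection_set,
    )
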