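"""Method-comparison and reproducibility metrics.

Similarity between connectivity matrices is summarized by the overall
Pearson r over corresponding off-diagonal entries; overlap between
region sets (communities vs ICA components) by the Jaccard index.  ICA
component z-maps are folded into a region-by-region co-activation
matrix (sum over components of the product of region-mean z-scores,
raised to a power factor k that emphasizes strong (k>1) or weak (k<1)
co-activation).  Reproducibility across subjects is summarized by
normalized connection-variance matrices with bootstrapped median
confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .connectivity import fisher_z
from .types import ConnectivityMatrix, LabelAtlas

__all__ = [
    "ComponentMaps",
    "CoactivationMatrix",
    "VarianceReport",
    "overall_r",
    "jaccard",
    "binarize_components",
    "coactivation_index",
    "similarity_vs_power",
    "variance_report",
    "kruskal_wallis_medians",
]


@dataclass
class ComponentMaps:
    """Stack of per-component z-score volumes (x, y, z, component)."""

    zmaps: np.ndarray
    component_ids: list[int] | None = None

    def __post_init__(self) -> None:
        self.zmaps = np.asarray(self.zmaps, dtype=float)
        if self.zmaps.ndim != 4:
            raise ValueError("zmaps must be 4D (x, y, z, component)")
        if not np.all(np.isfinite(self.zmaps)):
            raise ValueError("zmaps contain non-finite values")
        if self.component_ids is None:
            self.component_ids = list(range(1, self.zmaps.shape[3] + 1))

    @property
    def n_components(self) -> int:
        return self.zmaps.shape[3]


@dataclass
class CoactivationMatrix:
    values: np.ndarray
    power_k: float
    region_ids: np.ndarray


@dataclass
class VarianceReport:
    """Across-subject connection variances, normalized to [0, 1]."""

    variance_matrix: np.ndarray
    median: float
    median_ci: tuple[float, float]
    mean_subtracted_matrix: np.ndarray
    connection_variances: np.ndarray  # flat, over the analyzed connections
    directed: bool
    max_variance: float = 0.0  # raw (pre-normalization) maximum, z^2 units


def _offdiag_vector(values: np.ndarray, use_full: bool) -> np.ndarray:
    n = values.shape[0]
    if use_full:
        return values[~np.eye(n, dtype=bool)]
    iu = np.triu_indices(n, k=1)
    return values[iu]


def overall_r(
    matA: ConnectivityMatrix | np.ndarray, matB: ConnectivityMatrix | np.ndarray
) -> float:
    """Pearson r over corresponding off-diagonal entries of two matrices.

    If either matrix is directed the full off-diagonal is used;
    for two symmetric matrices the upper triangle suffices.
    """
    a_vals = matA.values if isinstance(matA, ConnectivityMatrix) else np.asarray(matA)
    b_vals = matB.values if isinstance(matB, ConnectivityMatrix) else np.asarray(matB)
    if a_vals.shape != b_vals.shape:
        raise ValueError("matrices must have the same shape")
    a_dir = matA.directed if isinstance(matA, ConnectivityMatrix) else True
    b_dir = matB.directed if isinstance(matB, ConnectivityMatrix) else True
    full = a_dir or b_dir
    a = _offdiag_vector(a_vals, full)
    b = _offdiag_vector(b_vals, full)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("overall r undefined: a matrix has zero off-diagonal variance")
    return float(np.corrcoef(a, b)[0, 1])


def jaccard(setA, setB) -> float:
    """|A intersect B| / |A union B|; 0 (by convention) for two empty sets."""
    a, b = set(setA), set(setB)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def region_mean_z(zmaps: ComponentMaps, atlas: LabelAtlas) -> np.ndarray:
    """Mean z-score per (component, region); shape (n_components, R)."""
    if zmaps.zmaps.shape[:3] != atlas.shape:
        raise ValueError("component maps and atlas are on different grids")
    labels = atlas.labels.ravel()
    flat = zmaps.zmaps.reshape(-1, zmaps.n_components)
    n_regions = atlas.n_regions
    counts = np.bincount(labels, minlength=n_regions + 1)[1:]
    out = np.zeros((zmaps.n_components, n_regions))
    for c in range(zmaps.n_components):
        sums = np.bincount(labels, weights=flat[:, c], minlength=n_regions + 1)[1:]
        out[c] = sums / counts
    return out


def binarize_components(
    zmaps: ComponentMaps, atlas: LabelAtlas, z_cut: float = 0.3
) -> dict[int, set[int]]:
    """Region membership per component: regions whose mean z exceeds ``z_cut``."""
    zbar = region_mean_z(zmaps, atlas)
    ids = atlas.region_ids
    return {
        int(cid): {int(ids[i]) for i in np.nonzero(zbar[c] > z_cut)[0]}
        for c, cid in enumerate(zmaps.component_ids)
    }


def coactivation_index(
    zmaps: ComponentMaps, atlas: LabelAtlas, power_k: float = 1.0, sum_first: bool = False
) -> CoactivationMatrix:
    """Region-by-region co-activation matrix from component z-maps.

    With zbar(c, i) the mean z of component c over region i, clipped at
    0: entry (i, j) = sum_c (zbar(c,i) * zbar(c,j))^k.  ``sum_first``
    switches to the alternative reading (sum_c zbar_i zbar_j)^k.
    """
    if power_k <= 0:
        raise ValueError("power factor k must be positive")
    zbar = np.clip(region_mean_z(zmaps, atlas), 0.0, None)
    products = np.einsum("ci,cj->cij", zbar, zbar)
    if sum_first:
        values = products.sum(axis=0) ** power_k
    else:
        values = (products**power_k).sum(axis=0)
    np.fill_diagonal(values, 0.0)
    return CoactivationMatrix(values=values, power_k=power_k, region_ids=atlas.region_ids)


def similarity_vs_power(
    zmaps: ComponentMaps,
    atlas: LabelAtlas,
    matrices: dict[str, ConnectivityMatrix],
    k_grid: tuple[float, ...] = (0.5, 1.0, 2.0),
):
    """Overall r of each method's matrix vs the co-activation matrix per k."""
    import pandas as pd

    rows = []
    for k in k_grid:
        coact = coactivation_index(zmaps, atlas, power_k=k)
        for method, mat in matrices.items():
            sym = ConnectivityMatrix(
                values=coact.values, directed=False, scale=mat.scale, region_ids=coact.region_ids
            )
            rows.append({"method": method, "power_k": k, "overall_r": overall_r(mat, sym)})
    return pd.DataFrame(rows)


def variance_report(
    per_subject_matrices: list[ConnectivityMatrix],
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> VarianceReport:
    """Reproducibility of a method across subjects.

    Per-connection sample variance of Fisher-z values across subjects,
    normalized by the maximum variance so all entries lie in [0, 1];
    the median over connections summarizes the method, with a 95%
    percentile-bootstrap CI over connections (>= 1000 resamples).
    """
    if len(per_subject_matrices) < 3:
        raise ValueError("variance report needs at least 3 subjects")
    directed = per_subject_matrices[0].directed
    stack = []
    for m in per_subject_matrices:
        vals = m.values if m.scale == "fisher_z" else fisher_z(m.values)
        stack.append(vals)
    arr = np.stack(stack)  # (subjects, R, R)
    var = arr.var(axis=0, ddof=1)
    vmax = float(var.max())
    # identical-subject inputs leave only rounding noise; report exact zeros
    if vmax <= 1e-20 * max(1.0, float(np.abs(arr).max()) ** 2):
        var = np.zeros_like(var)
        vmax = 0.0
    else:
        var = var / vmax
    np.fill_diagonal(var, 0.0)
    flat = _offdiag_vector(var, use_full=directed)
    median = float(np.median(flat))
    rng = np.random.default_rng(seed)
    boot = np.median(
        flat[rng.integers(0, flat.size, size=(n_bootstrap, flat.size))], axis=1
    )
    lo, hi = np.percentile(boot, [2.5, 97.5])
    lo, hi = min(float(lo), median), max(float(hi), median)
    return VarianceReport(
        variance_matrix=var,
        median=median,
        median_ci=(lo, hi),
        mean_subtracted_matrix=var - flat.mean(),
        connection_variances=flat,
        directed=directed,
        max_variance=vmax,
    )


def kruskal_wallis_medians(reports: dict[str, VarianceReport]) -> tuple[float, float]:
    """Kruskal-Wallis H test across methods' connection-variance samples."""
    if len(reports) < 2:
        raise ValueError("need at least 2 methods to compare")
    samples = [rep.connection_variances for rep in reports.values()]
    concatenated = np.concatenate(samples)
    if np.allclose(concatenated, concatenated[0]):
        raise ValueError("all variance samples identical; Kruskal-Wallis is degenerate")
    h, p = stats.kruskal(*samples)
    return float(h), float(p)
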