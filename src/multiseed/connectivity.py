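"""Correlation-matrix builders: MSRA, SRCC, and RCCA.

Three ways to turn one BOLD series plus a parcellation into a
region-by-region connectivity matrix:

* **MSRA** (multi-seed region analysis): each region's seed mean
  time-course is correlated with every brain voxel; significance is
  decided by FDR over the whole-brain map; significant *positive*
  correlations are averaged per target region.  Because the seed is
  fixed but target voxels are data-driven, the matrix is asymmetric
  ("pseudo-directed" — no causal claim is implied).
* **SRCC** (seed region cross-correlation): plain pairwise Pearson
  correlation of the seed mean time-courses, FDR applied across the
  matrix's unique off-diagonal entries.
* **RCCA** (regional cross-correlation): like SRCC but each region is
  summarized by the first principal component of its voxel
  time-courses instead of a mean, which de-weights inhomogeneous
  voxels.

Non-significant entries are set to 0 in all three matrices; the FDR
scope (whole brain for MSRA, matrix for SRCC/RCCA) is deliberately
different per method.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

from .seeding import SeedSet, seed_timecourse
from .types import BoldSeries, ConnectivityMatrix, LabelAtlas

__all__ = [
    "RccaDiagnostics",
    "correlation_map",
    "r_to_p",
    "fdr_threshold",
    "msra_matrix",
    "srcc_matrix",
    "rcca_matrix",
    "fisher_z",
]

logger = logging.getLogger(__name__)

_VAR_EPS = 1e-12


@dataclass
class RccaDiagnostics:
    """Per-region fraction of voxel variance carried by the first PC."""

    explained_variance: dict[int, float]

    def mean(self) -> float:
        return float(np.mean(list(self.explained_variance.values())))


def _pearson_rows(rows: np.ndarray, tc: np.ndarray) -> np.ndarray:
    """Pearson r of each row of ``rows`` against ``tc``; zero-variance rows -> 0."""
    tc_c = tc - tc.mean()
    tc_norm = np.linalg.norm(tc_c)
    if tc_norm < _VAR_EPS:
        raise ValueError("reference time-course has zero variance")
    rows_c = rows - rows.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(rows_c, axis=1)
    flat = norms < _VAR_EPS
    norms[flat] = 1.0
    r = (rows_c @ tc_c) / (norms * tc_norm)
    r[flat] = 0.0
    return np.clip(r, -1.0, 1.0)


def correlation_map(series: BoldSeries, seed_tc: np.ndarray) -> np.ndarray:
    """Voxelwise Pearson correlation of every in-mask voxel with ``seed_tc``.

    Returns a 3D volume: r inside the brain mask, NaN outside.
    Zero-variance voxels get r = 0 (and a log notice).
    """
    seed_tc = np.asarray(seed_tc, dtype=float)
    if seed_tc.shape[0] != series.n_volumes:
        raise ValueError("seed time-course length must match the series")
    mask = series.brain_mask
    r = _pearson_rows(series.data[mask], seed_tc)
    out = np.full(series.data.shape[:3], np.nan)
    out[mask] = r
    return out


def r_to_p(r: np.ndarray | float, n_timepoints: int) -> np.ndarray | float:
    """Two-sided p-value of a Pearson correlation via the t transform.

    t = r sqrt((n-2) / (1-r^2)) with n-2 degrees of freedom; |r| = 1
    maps to p = 0.
    """
    if n_timepoints < 4:
        raise ValueError("need at least 4 time points for a correlation p-value")
    r_arr = np.asarray(r, dtype=float)
    df = n_timepoints - 2
    with np.errstate(divide="ignore"):
        t = r_arr * np.sqrt(df / np.maximum(1.0 - r_arr**2, 0.0))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.abs(r_arr) >= 1.0, 0.0, p)
    return float(p) if np.isscalar(r) else p


def fdr_threshold(pvalues: np.ndarray, q: float = 0.05) -> float:
    """Benjamini-Hochberg step-up p-cutoff.

    Returns the largest p_(i) with p_(i) <= (i/m) q, or 0.0 when no
    p-value qualifies (nothing is declared significant).
    """
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty p-value collection")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    p_sorted = np.sort(p)
    m = p.size
    crit = (np.arange(1, m + 1) / m) * q
    passing = np.nonzero(p_sorted <= crit)[0]
    if passing.size == 0:
        return 0.0
    return float(p_sorted[passing[-1]])


def _p_cutoff_to_r(p_cutoff: float, n_timepoints: int) -> float:
    """Correlation magnitude at a given two-sided p cutoff."""
    if p_cutoff <= 0.0:
        return float("nan")
    df = n_timepoints - 2
    t_c = stats.t.isf(p_cutoff / 2.0, df)
    return float(t_c / np.sqrt(t_c**2 + df))


def msra_matrix(
    series: BoldSeries,
    atlas: LabelAtlas,
    seeds: dict[int, SeedSet],
    q: float = 0.05,
    anti: bool = False,
) -> ConnectivityMatrix:
    """Pseudo-directed multi-seed correlation matrix.

    Row s: the seed of region s is correlated with every in-mask voxel,
    FDR (level ``q``) is applied over the whole-brain map, and entry
    (s, t) is the mean of the significant positive correlations among
    voxels labelled t (0 if none).  ``anti=True`` inverts the sign of
    the correlations first, turning the analysis toward anti-correlated
    networks.  The diagonal is forced to 0.
    """
    region_ids = atlas.region_ids
    missing = [int(r) for r in region_ids if int(r) not in seeds]
    if missing:
        raise ValueError(f"seeds missing for regions: {missing}")
    n = len(region_ids)
    idx = {int(r): i for i, r in enumerate(region_ids)}
    mask = series.brain_mask
    voxels = series.data[mask]
    labels_in_mask = atlas.labels[mask]
    values = np.zeros((n, n))
    invalid: list[int] = []
    r_thresholds: list[float] = []
    for r_id in region_ids:
        r_id = int(r_id)
        tc = seed_timecourse(series, seeds[r_id])
        if np.std(tc) < _VAR_EPS:
            logger.warning("seed time-course of region %d is constant; row zeroed", r_id)
            invalid.append(r_id)
            continue
        r_map = _pearson_rows(voxels, tc)
        if anti:
            r_map = -r_map
        p_map = r_to_p(r_map, series.n_volumes)
        cutoff = fdr_threshold(p_map, q)
        if cutoff <= 0.0:
            continue
        r_thresholds.append(_p_cutoff_to_r(cutoff, series.n_volumes))
        sig = (p_map <= cutoff) & (r_map > 0)
        sums = np.bincount(labels_in_mask[sig], weights=r_map[sig], minlength=n + 1)
        counts = np.bincount(labels_in_mask[sig], minlength=n + 1)
        row = np.zeros(n)
        nonzero = counts[1:] > 0
        row[nonzero] = sums[1:][nonzero] / counts[1:][nonzero]
        values[idx[r_id], :] = row
    np.fill_diagonal(values, 0.0)
    return ConnectivityMatrix(
        values=values,
        directed=True,
        scale="pearson_r",
        fdr_q=q,
        fdr_threshold_r=float(np.mean(r_thresholds)) if r_thresholds else None,
        region_ids=region_ids,
        invalid_regions=tuple(invalid),
    )


def _symmetric_fdr_matrix(
    timecourses: np.ndarray,
    region_ids: np.ndarray,
    n_timepoints: int,
    q: float,
    invalid: list[int],
) -> tuple[np.ndarray, float | None]:
    """Pairwise Pearson matrix with BH applied over unique off-diagonal pairs."""
    n = timecourses.shape[0]
    sd = timecourses.std(axis=1)
    ok = sd > _VAR_EPS
    for i in np.nonzero(~ok)[0]:
        invalid.append(int(region_ids[i]))
        logger.warning("region %d has a constant time-course; row zeroed", int(region_ids[i]))
    corr = np.zeros((n, n))
    if ok.sum() >= 2:
        sub = np.corrcoef(timecourses[ok])
        corr[np.ix_(ok, ok)] = np.clip(sub, -1.0, 1.0)
    np.fill_diagonal(corr, 0.0)
    iu = np.triu_indices(n, k=1)
    pair_ok = ok[iu[0]] & ok[iu[1]]
    pvals = r_to_p(corr[iu][pair_ok], n_timepoints)
    cutoff = fdr_threshold(pvals, q) if pvals.size else 0.0
    out = np.zeros((n, n))
    if cutoff > 0.0:
        keep = np.zeros(pair_ok.shape, dtype=bool)
        keep[pair_ok] = pvals <= cutoff
        out[iu[0][keep], iu[1][keep]] = corr[iu][keep]
        out = out + out.T
    return out, (_p_cutoff_to_r(cutoff, n_timepoints) if cutoff > 0.0 else None)


def srcc_matrix(
    series: BoldSeries, seeds: dict[int, SeedSet], q: float = 0.05
) -> ConnectivityMatrix:
    """Symmetric cross-correlation matrix of seed mean time-courses."""
    region_ids = np.asarray(sorted(seeds), dtype=int)
    tcs = np.vstack([seed_timecourse(series, seeds[int(r)]) for r in region_ids])
    invalid: list[int] = []
    values, r_thr = _symmetric_fdr_matrix(tcs, region_ids, series.n_volumes, q, invalid)
    return ConnectivityMatrix(
        values=values,
        directed=False,
        scale="pearson_r",
        fdr_q=q,
        fdr_threshold_r=r_thr,
        region_ids=region_ids,
        invalid_regions=tuple(invalid),
    )


def region_pc1(voxel_data: np.ndarray) -> tuple[np.ndarray, float]:
    """First-principal-component score series of one region.

    ``voxel_data`` is (n_voxels, t): time points are observations,
    voxels are variables.  The score series' sign is fixed so it
    correlates non-negatively with the region-mean time-course.
    Returns (scores, explained-variance fraction).
    """
    x = np.asarray(voxel_data, dtype=float)
    if x.ndim != 2:
        raise ValueError("voxel_data must be (n_voxels, t)")
    if x.shape[0] == 1:
        tc = x[0] - x[0].mean()
        return tc, 1.0
    pca = PCA(n_components=1)
    scores = pca.fit_transform(x.T)[:, 0]
    mean_tc = x.mean(axis=0)
    if np.corrcoef(scores, mean_tc)[0, 1] < 0:
        scores = -scores
    return scores, float(pca.explained_variance_ratio_[0])


def rcca_matrix(
    series: BoldSeries, atlas: LabelAtlas, q: float = 0.05
) -> tuple[ConnectivityMatrix, RccaDiagnostics]:
    """Symmetric cross-correlation matrix of per-region PC1 time-courses."""
    region_ids = atlas.region_ids
    tcs = np.zeros((len(region_ids), series.n_volumes))
    explained: dict[int, float] = {}
    for i, r_id in enumerate(region_ids):
        vox = atlas.region_voxels(int(r_id))
        data = series.data[vox[:, 0], vox[:, 1], vox[:, 2], :]
        if data.std() < _VAR_EPS:
            # degenerate region: leave a constant time-course, zeroed downstream
            explained[int(r_id)] = 1.0
            continue
        scores, ev = region_pc1(data)
        tcs[i] = scores
        explained[int(r_id)] = ev
    invalid: list[int] = []
    values, r_thr = _symmetric_fdr_matrix(tcs, region_ids, series.n_volumes, q, invalid)
    matrix = ConnectivityMatrix(
        values=values,
        directed=False,
        scale="pearson_r",
        fdr_q=q,
        fdr_threshold_r=r_thr,
        region_ids=region_ids,
        invalid_regions=tuple(invalid),
    )
    return matrix, RccaDiagnostics(explained_variance=explained)


def fisher_z(r):
    """Fisher z transform, z = atanh(r); zeros stay zero.

    Accepts a scalar, an array, or a ConnectivityMatrix (returned as a
    new matrix with ``scale='fisher_z'``).  Values with |r| >= 1 are
    clipped to +/-(1 - 1e-7) with a warning.
    """
    if isinstance(r, ConnectivityMatrix):
        if r.scale == "fisher_z":
            raise ValueError("matrix is already on the Fisher-z scale")
        return ConnectivityMatrix(
            values=fisher_z(r.values),
            directed=r.directed,
            scale="fisher_z",
            fdr_q=r.fdr_q,
            fdr_threshold_r=r.fdr_threshold_r,
            region_ids=r.region_ids,
            invalid_regions=r.invalid_regions,
        )
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) >= 1.0):
        warnings.warn("correlations with |r| >= 1 clipped before atanh", stacklevel=2)
        arr = np.clip(arr, -(1.0 - 1e-7), 1.0 - 1e-7)
    z = np.arctanh(arr)
    return float(z) if np.isscalar(r) else z
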