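"""Independent brute-force reimplementations used as test oracles.

Everything here is written the slow, obvious way — explicit loops and
scipy.stats.pearsonr — and stays independent of the code paths it
checks.
"""

from itertools import combinations

import numpy as np
from scipy import stats


def bh_cutoff(pvalues, q):
    """Hand-stepped Benjamini-Hochberg step-up cutoff."""
    p = sorted(pvalues)
    m = len(p)
    cutoff = 0.0
    for i, pi in enumerate(p, start=1):
        if pi <= i / m * q:
            cutoff = pi
    return cutoff


def pearson_p(x, y):
    r, p = stats.pearsonr(x, y)
    return r, p


def msra_bruteforce(series, atlas, seeds, q=0.05):
    """Per-voxel correlation, BH over the mask, masked positive means."""
    region_ids = [int(r) for r in atlas.region_ids]
    n = len(region_ids)
    out = np.zeros((n, n))
    mask_voxels = np.argwhere(series.brain_mask)
    for si, s_id in enumerate(region_ids):
        vox = seeds[s_id].voxels
        tc = np.mean([series.data[tuple(v)] for v in vox], axis=0)
        rs, ps = [], []
        for v in mask_voxels:
            r, p = pearson_p(series.data[tuple(v)], tc)
            rs.append(r)
            ps.append(p)
        cutoff = bh_cutoff(ps, q)
        for ti, t_id in enumerate(region_ids):
            if t_id == s_id:
                continue
            vals = [
                rs[k]
                for k, v in enumerate(mask_voxels)
                if atlas.labels[tuple(v)] == t_id and ps[k] <= cutoff and rs[k] > 0
            ]
            out[si, ti] = np.mean(vals) if vals else 0.0
    return out


def srcc_bruteforce(series, seeds, q=0.05):
    ids = sorted(seeds)
    n = len(ids)
    tcs = []
    for rid in ids:
        vox = seeds[rid].voxels
        tcs.append(np.mean([series.data[tuple(v)] for v in vox], axis=0))
    rs = np.zeros((n, n))
    ps = {}
    for i in range(n):
        for j in range(i + 1, n):
            r, p = pearson_p(tcs[i], tcs[j])
            rs[i, j] = rs[j, i] = r
            ps[(i, j)] = p
    cutoff = bh_cutoff(list(ps.values()), q)
    out = np.zeros((n, n))
    for (i, j), p in ps.items():
        if p <= cutoff:
            out[i, j] = out[j, i] = rs[i, j]
    return out


def rcca_bruteforce(series, atlas, q=0.05):
    """Per-region PC1 via explicit eigen-decomposition of the voxel covariance."""
    ids = [int(r) for r in atlas.region_ids]
    n = len(ids)
    tcs = []
    for rid in ids:
        vox = atlas.region_voxels(rid)
        x = np.array([series.data[tuple(v)] for v in vox]).T  # (t, n_vox)
        xc = x - x.mean(axis=0)
        if x.shape[1] == 1:
            tcs.append(xc[:, 0])
            continue
        cov = xc.T @ xc / (x.shape[0] - 1)
        w, v = np.linalg.eigh(cov)
        pc1 = v[:, -1]
        scores = xc @ pc1
        if np.corrcoef(scores, x.mean(axis=1))[0, 1] < 0:
            scores = -scores
        tcs.append(scores)
    rs = np.zeros((n, n))
    ps = {}
    for i in range(n):
        for j in range(i + 1, n):
            r, p = pearson_p(tcs[i], tcs[j])
            rs[i, j] = rs[j, i] = r
            ps[(i, j)] = p
    cutoff = bh_cutoff(list(ps.values()), q)
    out = np.zeros((n, n))
    for (i, j), p in ps.items():
        if p <= cutoff:
            out[i, j] = out[j, i] = rs[i, j]
    return out


def pnbs_enumerate(control, experimental, connection_set, fraction=0.01):
    """Exhaustive-permutation pNBS p-value via direct re-implementation.

    ``control``/``experimental`` are (n_subjects, m) arrays over the
    connection set; components are found by naive graph traversal.
    """

    def stat(ctrl, exp):
        p_c = _paired_p(ctrl)
        n_supra = int(np.floor(fraction * len(p_c)))
        cutoff = np.sort(p_c)[n_supra - 1]
        p_e = _paired_p(exp)
        ctrl_sizes = _component_sizes(connection_set, p_c <= cutoff)
        cmax = max(ctrl_sizes) if ctrl_sizes else 0
        exp_sizes = _component_sizes(connection_set, p_e <= cutoff)
        return sum(s for s in exp_sizes if s > cmax)

    n1 = control.shape[0]
    pooled = np.vstack([control, experimental])
    k_obs = stat(control, experimental)
    ks = []
    for combo in combinations(range(pooled.shape[0]), n1):
        take = set(combo)
        rest = [i for i in range(pooled.shape[0]) if i not in take]
        ks.append(stat(pooled[sorted(take)], pooled[rest]))
    return k_obs, ks


def _paired_p(x):
    out = []
    for col in x.T:
        if col.std() == 0:
            out.append(1.0)
            continue
        _, p = stats.ttest_1samp(col, 0.0)
        out.append(1.0 if np.isnan(p) else p)
    return np.array(out)


def _component_sizes(connection_set, supra_mask):
    """Edge counts of connected components among supra-threshold edges."""
    edges = [tuple(e) for e, s in zip(np.asarray(connection_set), supra_mask) if s]
    edges = [(int(a), int(b)) for a, b in edges]
    sizes = []
    remaining = list(edges)
    while remaining:
        comp_nodes = set(remaining[0])
        comp_edges = []
        changed = True
        while changed:
            changed = False
            still = []
            for e in remaining:
                if e[0] in comp_nodes or e[1] in comp_nodes:
                    comp_nodes.update(e)
                    comp_edges.append(e)
                    changed = True
                else:
                    still.append(e)
            remaining = still
        sizes.append(len(comp_edges))
    return sizes
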