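"""Synthetic atlases and BOLD studies with known ground truth.

The generator emulates the ingredients the downstream pipeline needs:
a contiguous integer parcellation, community-structured regional
covariance, and paired pre/post sessions for two groups with an optional
planted connectivity modulation in the experimental group's post
session only.

Signal model
------------
Each community ``c`` has a latent standard-normal time-course
``s_c(t)``.  A region ``r`` in community ``c`` has the signal

    u_r(t) = a_r * s_c(t) + sigma * eps_r(t)

and every voxel of the region observes ``u_r(t)`` plus i.i.d. voxel
noise.  Two regions of the same community therefore have region-mean
correlation ``a^2 / (a^2 + sigma^2)`` in the limit of many voxels and
time points, and cross-community correlation 0.  Planted modulations
add one extra shared latent per edge, with loadings solved numerically
so the pairwise correlation shifts by the requested delta-r in
expectation (exact for node-disjoint planted edges).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .types import BoldSeries, LabelAtlas

__all__ = [
    "CommunitySpec",
    "StudySet",
    "SubjectScan",
    "make_toy_atlas",
    "simulate_bold",
    "simulate_paired_study",
]

_FACE_NEIGHBORS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


class CapacityError(ValueError):
    """Requested atlas does not fit into the given volume shape."""


@dataclass
class CommunitySpec:
    """Covariance structure planted by the generator.

    ``assignment`` maps every region id to a community id.
    ``signal_gain`` is the per-region loading on the community latent
    (a scalar applies to all regions); ``noise_sd`` is region-level
    noise, ``region_noise_sd`` voxel-level noise.
    """

    assignment: dict[int, int]
    signal_gain: float | dict[int, float] = 1.0
    noise_sd: float = 1.0
    region_noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.noise_sd <= 0 or self.region_noise_sd <= 0:
            raise ValueError("noise standard deviations must be positive")
        gains = (
            self.signal_gain.values()
            if isinstance(self.signal_gain, dict)
            else [self.signal_gain]
        )
        if any(g < 0 for g in gains):
            raise ValueError("signal gains must be non-negative")

    def gain(self, region_id: int) -> float:
        if isinstance(self.signal_gain, dict):
            return float(self.signal_gain[region_id])
        return float(self.signal_gain)


@dataclass
class SubjectScan:
    """One acquired series: subject, group (control/experimental), session (pre/post)."""

    subject_id: str
    group: str
    session: str
    series: BoldSeries


@dataclass
class StudySet:
    """A full paired two-group study plus its generating ground truth."""

    subjects: list[SubjectScan]
    atlas: LabelAtlas
    planted_edges: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[str, set[str]] = {}
        for scan in self.subjects:
            seen.setdefault(scan.subject_id, set()).add(scan.session)
        for sid, sessions in seen.items():
            if sessions != {"pre", "post"}:
                raise ValueError(f"subject {sid} must have exactly one pre and one post scan")

    def scans(self, group: str | None = None, session: str | None = None) -> list[SubjectScan]:
        out = self.subjects
        if group is not None:
            out = [s for s in out if s.group == group]
        if session is not None:
            out = [s for s in out if s.session == session]
        return out

    def subject_ids(self, group: str) -> list[str]:
        ids: list[str] = []
        for scan in self.subjects:
            if scan.group == group and scan.subject_id not in ids:
                ids.append(scan.subject_id)
        return ids


def make_toy_atlas(
    n_regions: int,
    shape: tuple[int, int, int] = (24, 24, 12),
    min_region_voxels: int = 8,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    seed: int = 0,
) -> LabelAtlas:
    """Grow ``n_regions`` face-connected regions from random sites.

    Regions are grown voxel by voxel (round robin) from seeded random
    start sites until each reaches a per-region target of at least
    ``min_region_voxels``; unclaimed voxels remain background.  The
    result is deterministic given ``seed``.
    """
    if n_regions < 1 or min_region_voxels < 1:
        raise ValueError("n_regions and min_region_voxels must be positive")
    shape = tuple(int(s) for s in shape)
    total = int(np.prod(shape))
    if n_regions * min_region_voxels > total:
        raise CapacityError(
            f"cannot fit {n_regions} regions of >= {min_region_voxels} voxels "
            f"into a volume of {total} voxels"
        )
    rng = np.random.default_rng(seed)
    for _ in range(8):  # random sites can (rarely) wall a region in; just redraw
        labels = _grow_regions(n_regions, shape, min_region_voxels, rng)
        if labels is not None:
            return LabelAtlas(labels=labels, voxel_size=voxel_size)
    raise CapacityError(
        f"could not grow {n_regions} regions of >= {min_region_voxels} voxels "
        f"in shape {shape}; volume too crowded"
    )


def _grow_regions(n_regions, shape, min_region_voxels, rng):
    total = int(np.prod(shape))
    labels = np.zeros(shape, dtype=np.int32)
    sites = np.unravel_index(rng.choice(total, size=n_regions, replace=False), shape)
    sites = list(zip(*(ax.tolist() for ax in sites)))
    # vary region sizes a little so the parcellation is not uniform
    targets = min_region_voxels + rng.integers(0, min_region_voxels + 1, size=n_regions)
    frontiers: list[list[tuple[int, int, int]]] = []
    sizes = np.zeros(n_regions, dtype=int)
    for rid, site in enumerate(sites, start=1):
        labels[site] = rid
        sizes[rid - 1] = 1
        frontiers.append(_free_neighbors(labels, site))
    active = list(range(n_regions))
    while active:
        still_active = []
        for idx in active:
            if sizes[idx] >= targets[idx]:
                continue
            claimed = _claim_voxel(labels, frontiers[idx], idx + 1, rng)
            if claimed is None:
                if sizes[idx] < min_region_voxels:
                    return None  # walled in below the minimum: redraw sites
                continue
            sizes[idx] += 1
            frontiers[idx].extend(_free_neighbors(labels, claimed))
            if sizes[idx] < targets[idx]:
                still_active.append(idx)
        active = still_active
    return labels


def _free_neighbors(labels, voxel):
    out = []
    shape = labels.shape
    for d in _FACE_NEIGHBORS:
        nb = (voxel[0] + int(d[0]), voxel[1] + int(d[1]), voxel[2] + int(d[2]))
        if all(0 <= nb[i] < shape[i] for i in range(3)) and labels[nb] == 0:
            out.append(nb)
    return out


def _claim_voxel(labels, frontier, region_id, rng):
    while frontier:
        pick = int(rng.integers(0, len(frontier)))
        voxel = frontier.pop(pick)
        if labels[voxel] == 0:
            labels[voxel] = region_id
            return voxel
    return None


def simulate_bold(
    atlas: LabelAtlas,
    spec: CommunitySpec,
    n_volumes: int = 300,
    tr: float = 2.0,
    seed: int = 0,
    shared_components: list[dict[int, float]] | None = None,
) -> BoldSeries:
    """Simulate a 4D BOLD series over the atlas with community covariance.

    ``shared_components`` optionally adds extra standard-normal latents:
    each dict maps region ids to loadings on one shared latent, the
    mechanism behind planted pairwise modulations.
    """
    region_ids = atlas.region_ids
    missing = [int(r) for r in region_ids if int(r) not in spec.assignment]
    if missing:
        raise ValueError(f"regions without community assignment: {missing}")
    rng = np.random.default_rng(seed)
    communities = sorted(set(spec.assignment[int(r)] for r in region_ids))
    latents = rng.standard_normal((len(communities), n_volumes))
    comm_index = {c: i for i, c in enumerate(communities)}
    extra = []
    for comp in shared_components or []:
        extra.append((comp, rng.standard_normal(n_volumes)))
    data = np.zeros(atlas.shape + (n_volumes,), dtype=float)
    for r in region_ids:
        r = int(r)
        signal = spec.gain(r) * latents[comm_index[spec.assignment[r]]]
        signal = signal + spec.noise_sd * rng.standard_normal(n_volumes)
        for comp, g in extra:
            if r in comp:
                signal = signal + comp[r] * g
        vox = atlas.region_voxels(r)
        noise = spec.region_noise_sd * rng.standard_normal((vox.shape[0], n_volumes))
        data[vox[:, 0], vox[:, 1], vox[:, 2], :] = signal[None, :] + noise
    return BoldSeries(
        data=data, tr=tr, voxel_size=atlas.voxel_size, brain_mask=atlas.foreground_mask()
    )


def _region_mean_moments(atlas: LabelAtlas, spec: CommunitySpec, i: int, j: int):
    """Variance of each region-mean time-course and their covariance."""
    ni = atlas.region_voxels(i).shape[0]
    nj = atlas.region_voxels(j).shape[0]
    vi = spec.gain(i) ** 2 + spec.noise_sd**2 + spec.region_noise_sd**2 / ni
    vj = spec.gain(j) ** 2 + spec.noise_sd**2 + spec.region_noise_sd**2 / nj
    same = spec.assignment[i] == spec.assignment[j]
    cov = spec.gain(i) * spec.gain(j) if same else 0.0
    return vi, vj, cov


def _solve_loading(vi: float, vj: float, cov: float, target_r: float) -> tuple[float, float]:
    """Loadings (b_i, b_j) of a shared latent achieving ``target_r``.

    Same-sign loadings raise the correlation, opposite-sign loadings
    lower it; the magnitude is found by root bracketing.
    """
    if abs(target_r) >= 1.0:
        raise ValueError(f"target correlation {target_r} out of range (-1, 1)")
    base_r = cov / np.sqrt(vi * vj)
    if np.isclose(target_r, base_r):
        return 0.0, 0.0
    sign = 1.0 if target_r > base_r else -1.0

    def gap(b: float) -> float:
        return (cov + sign * b * b) / np.sqrt((vi + b * b) * (vj + b * b)) - target_r

    hi = 1.0
    while gap(hi) * gap(0.0) > 0:
        hi *= 2.0
        if hi > 1e6:
            raise ValueError(f"target correlation {target_r} unreachable by a shared latent")
    b = brentq(gap, 0.0, hi, xtol=1e-12)
    return float(b), float(sign * b)


def simulate_paired_study(
    atlas: LabelAtlas,
    base_spec: CommunitySpec,
    planted_edges: list[tuple[int, int]] | list[tuple[int, int, float]] | None = None,
    delta_r: float = 0.0,
    n_control: int = 12,
    n_experimental: int = 13,
    n_volumes: int = 300,
    tr: float = 2.0,
    seed: int = 0,
) -> StudySet:
    """Simulate a paired two-group study with an optional planted modulation.

    Control pre/post and experimental pre are exchangeable draws from
    ``base_spec``; the experimental post session gets one extra shared
    latent per planted edge, calibrated so the edge's region-mean
    correlation shifts by ``delta_r`` (or a per-edge third tuple element)
    in expectation.
    """
    rng = np.random.default_rng(seed)
    edges: list[tuple[int, int, float]] = []
    region_set = set(int(r) for r in atlas.region_ids)
    for e in planted_edges or []:
        i, j = int(e[0]), int(e[1])
        dr = float(e[2]) if len(e) > 2 else float(delta_r)
        if i not in region_set or j not in region_set or i == j:
            raise ValueError(f"planted edge ({i}, {j}) does not reference two distinct regions")
        edges.append((i, j, dr))
    components: list[dict[int, float]] = []
    for i, j, dr in edges:
        vi, vj, cov = _region_mean_moments(atlas, base_spec, i, j)
        bi, bj = _solve_loading(vi, vj, cov, cov / np.sqrt(vi * vj) + dr)
        if bi or bj:
            components.append({i: bi, j: bj})

    def child_seed() -> int:
        return int(rng.integers(0, 2**31 - 1))

    subjects: list[SubjectScan] = []
    groups = [("control", n_control), ("experimental", n_experimental)]
    counter = itertools.count(1)
    for group, n in groups:
        for _ in range(n):
            sid = f"{group[0]}{next(counter):02d}"
            for session in ("pre", "post"):
                planted = components if (group == "experimental" and session == "post") else None
                series = simulate_bold(
                    atlas,
                    base_spec,
                    n_volumes=n_volumes,
                    tr=tr,
                    seed=child_seed(),
                    shared_components=planted,
                )
                subjects.append(SubjectScan(sid, group, session, series))
    kept = edges if components or edges else []
    return StudySet(subjects=subjects, atlas=atlas, planted_edges=kept)
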