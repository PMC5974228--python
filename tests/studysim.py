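"""Desk-scale paired-study simulation shared by the validity tests.

Conditions: a 16-region toy atlas (12x12x6 grid, 4 communities),
12 control vs 13 experimental subjects, seed cross-correlation
connectivity over all unique region pairs, and M = 200 permutations.
Null studies use 100 volumes; powered studies plant a delta-r = 0.4
modulation on a 6-edge path and use 300 volumes.
"""

import multiseed as ms
from multiseed import connectivity, pnbs

N_REGIONS = 16
PLANTED_PATH = [(1, 6), (6, 11), (11, 16), (16, 2), (2, 7), (7, 12)]


def make_conditions(seed=7):
    atlas = ms.make_toy_atlas(N_REGIONS, shape=(12, 12, 6), min_region_voxels=6, seed=seed)
    spec = ms.CommunitySpec(
        assignment={r: (r - 1) % 4 + 1 for r in range(1, N_REGIONS + 1)},
        signal_gain=1.0,
        noise_sd=1.0,
        region_noise_sd=0.5,
    )
    seeds = ms.place_all_seeds(atlas)
    return atlas, spec, seeds


def study_difference_matrices(atlas, spec, seeds, seed, delta_r=0.0, planted=None,
                              n_volumes=100):
    study = ms.simulate_paired_study(
        atlas,
        spec,
        planted_edges=planted or [],
        delta_r=delta_r,
        n_control=12,
        n_experimental=13,
        n_volumes=n_volumes,
        tr=2.0,
        seed=seed,
    )
    pairs: dict = {}
    groups: dict = {}
    for scan in study.subjects:
        mat = connectivity.fisher_z(connectivity.srcc_matrix(scan.series, seeds))
        pairs.setdefault(scan.subject_id, {})[scan.session] = mat
        groups[scan.subject_id] = scan.group
    diffs = pnbs.difference_matrices(
        {sid: (p["pre"], p["post"]) for sid, p in pairs.items()}, groups
    )
    ctrl = [d for d in diffs if d.group == "control"]
    expd = [d for d in diffs if d.group == "experimental"]
    return ctrl, expd


def run_study_pnbs(atlas, spec, seeds, seed, delta_r=0.0, planted=None, n_volumes=100,
                   tie_rule="ge"):
    ctrl, expd = study_difference_matrices(
        atlas, spec, seeds, seed, delta_r=delta_r, planted=planted, n_volumes=n_volumes
    )
    return pnbs.pnbs_test(
        ctrl, expd, fraction=0.01, n_permutations=200, seed=seed + 1, tie_rule=tie_rule
    )
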