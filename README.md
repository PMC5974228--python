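# multiseed

Graph-theoretical resting-state fMRI connectivity analysis for
parcellated 4D BOLD data, built around a pseudo-directed **multi-seed
region analysis (MSRA)** and a **paired network-based statistic
(pNBS)** for detecting short-term connectivity modulation between two
resting-state sessions in paired groups (an experimental group with an
intervention between sessions and a control group without).

## Who this is for

Labs analyzing small-animal (or any parcellated) resting-state fMRI
who want seed-based connectivity matrices, community structure, and a
statistically controlled answer to "did the intervention change the
network between session 1 and session 2?" — without assuming the two
sessions of a subject are independent.

## Methods at a glance

Three connectivity matrix builders operate on a label atlas (1..R
regions) and a preprocessed BOLD series:

* **MSRA** — for every region, a 5-voxel seed is placed automatically
  at the region's center of mass (restricted to the region's central
  z-plane because slices are thick); the seed mean time-course is
  correlated with every brain voxel; FDR (Benjamini–Hochberg,
  q = 0.05) is applied over the whole-brain map; the significant
  *positive* correlations are averaged per target region. Fixed seeds
  vs data-driven target voxels make the R x R matrix asymmetric
  ("pseudo-directed" — not causal).
* **SRCC** — plain cross-correlation of the seed mean time-courses,
  FDR over the matrix's unique off-diagonal entries.
* **RCCA** — like SRCC, but each region is summarized by the first
  principal component of its voxel time-courses.

Non-significant entries are set to 0; surviving Pearson r values are
Fisher z transformed (z = atanh r). Graphs keep the N·d/2 strongest
positive connections (average degree d; e.g. 1,790 directed
connections at d = 20 for a 179-region atlas) and communities come
from Louvain modularity optimization, with a resolution-parameter
bisection when a fixed community count is requested.

The **pNBS** works on per-subject Fisher-z difference matrices
(post − pre):

1. per-connection paired t-tests, separately for control and
   experimental groups;
2. first-level p cutoff = the value with exactly 1% of *control*
   connections at or below it (the control group's "hypothetical false
   positives");
3. in the experimental supra-threshold graph, every connected
   component with edge count ≤ the control group's largest component
   is eliminated; the statistic k = surviving edges.

Family-wise error control: difference matrices are permuted between
groups M times, steps 1–3 are recomputed (threshold included), and
p_fwe = #(k' > k)/M (a conservative `tie_rule="ge"` variant counts
ties; designs small enough are enumerated exhaustively).

A synthetic-data module generates toy atlases (seeded region growing)
and paired two-group BOLD studies with community-structured covariance
and planted, calibrated connectivity modulations, so the whole
pipeline is testable end to end without any external data.

## Worked example

Simulate a paired study (12 control vs 13 experimental subjects, 300
volumes, TR 2 s) with a delta-r = 0.4 modulation planted on the edges
(1,6), (6,11), (11,16) of a 16-region toy atlas, then run the paired
network statistic on SRCC connectivity:

```python
import multiseed as ms
from multiseed import connectivity, pnbs

atlas = ms.make_toy_atlas(16, shape=(12, 12, 6), min_region_voxels=6, seed=7)
spec = ms.CommunitySpec(assignment={r: (r - 1) % 4 + 1 for r in range(1, 17)})
study = ms.simulate_paired_study(
    atlas, spec,
    planted_edges=[(1, 6), (6, 11), (11, 16)], delta_r=0.4,
    n_control=12, n_experimental=13, n_volumes=300, tr=2.0, seed=1,
)

seeds = ms.place_all_seeds(atlas)
pairs, groups = {}, {}
for scan in study.subjects:
    mat = connectivity.fisher_z(connectivity.srcc_matrix(scan.series, seeds))
    pairs.setdefault(scan.subject_id, {})[scan.session] = mat
    groups[scan.subject_id] = scan.group

diffs = pnbs.difference_matrices(
    {sid: (p["pre"], p["post"]) for sid, p in pairs.items()}, groups
)
ctrl = [d for d in diffs if d.group == "control"]
expd = [d for d in diffs if d.group == "experimental"]
result = pnbs.pnbs_test(ctrl, expd, fraction=0.01, n_permutations=500, seed=2)

print(f"first-level p threshold: {result.threshold_p:.5f}")
print(f"surviving edges (k):     {result.k}")
print(f"p_fwe = {result.p_fwe:.4f}  ({result.n_permutations} permutations)")
```

Output:

```
first-level p threshold: 0.07046
surviving edges (k):     15
p_fwe = 0.0000  (500 permutations)
```

The surviving set (`result.surviving_edges`) contains the three
planted edges with strongly positive t statistics (t = 16.9, 19.4,
16.5) plus secondary *negative* modulations such as (1,5) and (11,15):
the extra shared signal that raises the planted correlations
necessarily dilutes the planted regions' correlations with their own
community — a redistribution the component statistic picks up as one
connected alteration. Under a null study (`delta_r=0`) the same
pipeline returns k = 0 or a small k with a large p_fwe.

The same pipeline is available from the shell:

```bash
# one-off artifacts
multiseed simulate --n-regions 16 --n-volumes 300 --delta-r 0.4 \
    --planted-edge 1,6 --seed 1 --outdir study/
multiseed seeds study/atlas.nii.gz seeds.csv
multiseed connect study/c01_pre.nii.gz study/atlas.nii.gz c01_pre.csv --method srcc

# or the whole chain (simulate -> preprocess -> connect -> graph -> pnbs)
multiseed run --outdir run/ --method srcc --seed 1
```

## Scope

Preprocessing covers the post-motion-correction chain only (Gaussian
smoothing, 0.1 Hz low-pass, global signal regression). Slice-time and
motion correction, template registration, GLM activation analysis, and
group ICA are out of scope; ICA component z-maps are accepted as an
*input* to the comparison metrics (overall r, Jaccard, co-activation
index, reproducibility variance).
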