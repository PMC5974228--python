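# Methods

This note documents the models, numerical choices, and known
limitations of `multiseed`, in the spirit of a package reference
manual. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Connectivity matrix construction

All three builders start from a label atlas (contiguous integer
regions 1..R, 0 = background) and a 4D BOLD series with a brain mask,
and end in an R x R matrix in which **zero means "not significant"**.

**Seed placement.** A seed is the anchor voxel plus the next
`seed_size - 1 = 4` nearest in-region voxels (5 total), all on the
region's *central plane*: the occupied z-slice nearest the region's
center of mass. The plane restriction exists because functional voxels
are typically much thicker in z than in-plane, so voxels on other
slices are poorly matched tissue. Numerical choices:

* distances are measured in millimetres (voxel-size scaled), so
  anisotropic grids are handled correctly;
* plane ties break toward the lower slice index, voxel-distance ties
  break by lexicographic coordinate — placement is fully deterministic
  and translation-equivariant;
* regions with fewer than 5 voxels on their central plane keep all of
  them and are flagged (`truncated`), not dropped. No exclusion rule
  is imposed.

**MSRA.** Per seed region: Pearson correlation of the seed mean
time-course with every in-mask voxel; two-sided p-values via the t
transform t = r sqrt((n-2)/(1-r^2)), df = n-2 (the mapping from r to p
is a package choice; only the FDR level is externally fixed);
Benjamini–Hochberg step-up at q = 0.05 **over the whole-brain map**;
entry (s, t) = mean of significant *positive* correlations among
voxels labelled t, 0 if none. The diagonal is excluded
(self-connectivity is undefined in a graph), and the seed's own voxels
stay in its map — their near-1 correlations only touch the excluded
diagonal. Negative significant voxels are excluded by design; an
`anti=True` switch inverts the sign first for anti-correlation
analysis. The matrix records the mean realized r threshold at the FDR
boundary across seeds.

**SRCC / RCCA.** Pairwise Pearson correlation of the R regional
time-courses (seed means for SRCC; first-principal-component score
series for RCCA, sign-fixed to correlate non-negatively with the
region mean), with BH applied **across the R(R-1)/2 unique
off-diagonal p-values**. The different FDR scopes (whole brain vs
matrix) are intentional and kept exactly. Significant negative entries
are retained in these symmetric matrices; they are excluded later at
the graph stage, where edge weights must be positive.

Degenerate inputs: constant seed or regional time-courses zero the
affected row/column and are recorded in `invalid_regions`;
zero-variance voxels get r = 0. Fisher's z = atanh(r) is applied for
averaging and t statistics; |r| >= 1 is clipped to 1 - 1e-7 with a
warning.

## Graphs and communities

`threshold_graph` keeps the N·d/2 strongest positive entries at
average degree d (directed entries or unique undirected pairs — a
connection touches two nodes either way, which is what makes 179 nodes
at d = 20 directed give exactly 1,790 edges and d = 10 undirected give
895), or a fixed top-n, or a plain weight cutoff. Ties at the cut
break by (weight desc, source id, target id), so edge counts are exact
and reproducible. All regions stay in the graph as (possibly isolated)
nodes.

Communities come from Louvain modularity optimization
(`networkx.algorithms.community.louvain_communities`, seeded).
Directed graphs are symmetrized by summing reciprocal weights —
modularity as used here is an undirected quantity. When a fixed
community count is requested (e.g. to match an ICA decomposition), the
resolution parameter is bisected (expanding the bracket by factors of
2 first, then up to 50 bisections); if the exact count is unreachable
— more disconnected components than the target, or no resolution
hitting the count exactly — the closest achievable partition is
returned with `target_reached=False`. The reported modularity Q is
always evaluated at resolution 1. Layout export uses the seeded
spring (Fruchterman–Reingold) algorithm, which is deterministic given
the seed and well-defined on disconnected graphs.

## Comparison metrics

* `overall_r`: Pearson r over corresponding off-diagonal entries (full
  off-diagonal if either matrix is directed, upper triangle if both
  symmetric).
* `jaccard`: |A∩B| / |A∪B|, 0 by convention for two empty sets.
* Co-activation index: with zbar(c, i) the mean z-score of component c
  over region i clipped at 0, entry (i, j) = Σ_c (zbar_i zbar_j)^k.
  The power factor k > 1 emphasizes strong, k < 1 weak co-activation.
  The alternative reading (Σ_c zbar_i zbar_j)^k is available via
  `sum_first=True`; the per-region summary is the mean (not sum) of
  voxel z-scores. These are package choices where the literature
  formulation is ambiguous.
* Reproducibility: per-connection sample variance of Fisher-z values
  across subjects, normalized by the maximum variance so every method
  lives on [0, 1] (the normalization rule is a package choice); the
  median over connections is reported with a 95% percentile-bootstrap
  CI (default 1,000 seeded resamples over connections). Methods are
  compared with the Kruskal–Wallis H test. Inputs whose across-subject
  spread is pure rounding noise are reported as exactly zero variance
  rather than normalized noise.

## Paired network-based statistic (pNBS)

Inputs are per-subject Fisher-z difference matrices (post − pre). The
analyzed connection set defaults to all off-diagonal cells (unique
pairs when symmetric) and can be restricted to the union of edges of
thresholded group-average graphs.

1. Per-connection one-sample t of the differences against 0, two-sided,
   separately per group. Zero-variance connections get t = 0, p = 1.
2. First-level cutoff = the floor(fraction · m)-th smallest *control*
   p-value (default fraction 1%), so exactly that many control
   connections are supra-threshold. If floor(fraction · m) < 1 the
   design is rejected with an error. The cutoff is a *low* quantile of
   the control p-values: it represents the session-to-session
   variability an intervention must exceed.
3. Connected components are taken on the undirected skeleton and sized
   by edge count. Every experimental component with edge count <= the
   control group's largest component is eliminated; k = total
   surviving edges (possibly several components).

Permutation FWE: difference matrices are reassigned to pseudo-groups
of the original sizes; steps 1–3 including the threshold are
re-derived per permutation (reusing the observed threshold would
change the null); p_fwe = #(k' > k)/M. When C(n1+n2, n1) <= M all
assignments are enumerated exhaustively (no seed needed); otherwise a
seed is mandatory.

**Tie handling.** The strict inequality (k' > k) is the default. When
the analyzed connection set is large (hundreds to thousands of
connections) k is large and the tie mass P(k' = k) is negligible, so
the choice hardly matters. At small scale, however, k is a small
integer and the strict rule is measurably anticonservative.
`tie_rule="ge"` (p_fwe = #(k' >= k)/M) is the conservative variant,
and it is the variant whose validity the acceptance tests certify: the
suite simulates 200 null studies at the desk-scale conditions below
and requires the empirical type-I error of the `ge` variant to stay
within 7% at nominal 5%. Validity claims in this package therefore
attach to `tie_rule="ge"`; the strict default is kept for fidelity to
the original formulation.

A note on k = 0: if nothing survives elimination there is no component
to ascribe a p-value to; p_fwe is still reported (the probability a
permutation produces any surviving edge, which is typically large),
but a k = 0 result should simply be read as "no modulation detected".

## Synthetic data: what it emulates and what it does not

`make_toy_atlas` grows face-connected regions from seeded random sites
until each reaches a randomized per-region target >= the minimum; the
result is a contiguous, irregular parcellation, deterministic given
the seed (an infeasibly crowded request raises a capacity error after
a few site redraws).

`simulate_bold` draws one standard-normal latent per community;
region signal = a·s_c(t) + σ·ε(t); voxels add i.i.d. noise. Hence
same-community region means correlate at a²/(a²+σ²) (0.5 at the
defaults a = σ = 1) and cross-community means at 0, with the voxel
noise attenuation 1/(1 + rn²/(N v)) accounted for where it matters.

`simulate_paired_study` draws every subject/session independently;
the experimental post session adds one extra shared latent per planted
edge, with loadings solved numerically (Brent root bracketing on the
exact correlation expression, voxel-noise attenuation included) so the
edge's correlation shifts by delta-r in expectation. Negative shifts
use opposite-sign loadings. The calibration is exact for node-disjoint
planted edges; edges sharing a node interact (each latent inflates the
shared node's variance), so chained planted paths achieve slightly
less than the nominal per-edge shift — and necessarily *dilute* the
planted nodes' other correlations, a redistribution visible as
secondary negative modulations.

Not emulated: hemodynamic response, scanner drift/spikes, motion,
physiological noise, inter-subject anatomical variability (all
subjects share one atlas space). Passing tests therefore certify the
*statistical machinery* — calibration, exactness, error control under
exchangeability — not robustness to real-scanner artifacts.

## Preprocessing

Order: spatial smoothing → temporal low-pass → global signal
regression. Smoothing is an anisotropy-aware Gaussian (sigma per axis
= FWHM / (2 sqrt(2 ln 2)) / voxel size; default FWHM 1.17 mm; reflect
padding at volume borders). The low-pass (default 0.1 Hz cutoff) is a
zero-phase forward-backward Butterworth of order 4 — the filter family
and order are package choices; zero-phase filtering avoids phase lags
that would bias correlations, and the implementation is checked
against its analytic response (passband < 0.5·cutoff preserved within
5%, stopband > 2·cutoff attenuated >= 90%). Global signal = unweighted
mean over the brain mask; every voxel is replaced by its OLS residual
(intercept included), making residuals exactly orthogonal to the
global signal. All steps leave out-of-mask voxels untouched. No
high-pass bound is applied.

## Problem sizes used in the validity tests

The pNBS validity simulations run at a deliberate desk scale chosen
once: a 16-region atlas on a 12 x 12 x 6 grid (4 communities,
a = σ = 1, voxel noise 0.5), 12 control vs 13 experimental subjects,
SRCC connectivity over all 120 unique region pairs, M = 200
permutations; 100 volumes per session for the 200-study null
(type-I) run and 300 volumes for the 50-study power run with
delta-r = 0.4 planted on a 6-edge path. Oracle-equivalence checks run
on a 3-region toy with 50 time points against brute-force
reimplementations at 1e-10.

## Known limitations

* Louvain is a heuristic; the resolution bisection assumes community
  count is (weakly) monotone in resolution, which can fail on
  adversarial graphs — hence the closest-achievable fallback.
* The pseudo-directedness of MSRA reflects seed/target asymmetry, not
  causal direction, and community detection treats it as undirected.
* The first-level threshold depends on the control group's own
  p-distribution; because connectivity matrices are FDR-zeroed before
  differencing, those p-values are not uniform under the null (many
  connections are identically zero in both sessions), which makes the
  realized threshold data-dependent by construction.
* Group ICA is not computed; component z-maps are an input.
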