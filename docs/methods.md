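# Methods

## Cross-subject co-activation networks

The data model is one activity-marker density per (subject, region), with
a group label per subject. Within one group of n subjects, the coupling of
regions i and j is the Pearson correlation r_ij of their densities across
the n subjects. This is a second-order model: all structure the analysis
can see is the group's region×region correlation matrix, which is why the
synthetic generator (below) samples from a multivariate normal — matching
the correlation target is sufficient for every downstream stage.

Significance of a single coefficient uses the exact t-transform
t = r·√((n−2)/(1−r²)) with n−2 degrees of freedom, two-tailed. Networks
keep edges with p ≤ level for levels 0.05, 0.025, 0.01 (non-strict
inequality; uncorrected by design — the thresholds are meant to remove
chance-level coefficients, not to control family-wise error, and the
threshold sweep plus the stable-hub rule is the robustness device).
Thresholded edge sets are nested across levels by construction.

Edge weight is |r| and the distance view is 1 − |r|. Negative coefficients
therefore enter by magnitude; when none survive thresholding (typical for
co-activation data with a high-baseline marker) this coincides with
1 − r. Keeping |r| guarantees distances in [0, 1) for arbitrary inputs.
Missing cells are a hard error: silently dropping subjects pairwise would
vary n across cells and corrupt the p-values.

Groups of unequal region sets (a lesioned group lacks the lesioned
regions) are compared via the matched-control network: the control
expression matrix restricted to the lesioned group's node set, then fully
re-analyzed. Pearson correlations are pairwise, so restriction does not
change the surviving coefficients, only which ones exist.

## Efficiency and the rewired-null ensemble

Global efficiency is the mean of 1/d(i,j) over all unordered pairs, with
shortest paths on the 1 − |r| distances. Unreachable pairs contribute 0
while remaining in the denominator (the standard harmonic-mean
convention); this keeps Geff defined on the fragmented strict-threshold
networks. A numerical floor of 1e−12 on edge distances keeps |r| = 1 edges
traversable. Local efficiency of v is the Geff of the subgraph induced on
v's neighbors (v excluded); nodes with fewer than two neighbors score 0.

The null model preserves exactly: node count, edge count, degree sequence
and the edge-weight multiset. Each null applies ⌊E/2⌋ successful
double-edge swaps — (u,v),(x,y) → (u,x),(v,y) — rejecting self-loops and
duplicate edges; each swapped edge keeps its weight. A bounded retry
budget turns graphs that admit (almost) no legal swap into an error rather
than a silent bias. Per null, the ratios Geff_emp/Geff_null and mean-Leff
ratios are recorded; the 95% interval is the 2.5–97.5 percentile of the
ensemble, taken as order statistics without interpolation because
mean-Leff ratios can be legitimately infinite (a null with no triangles
at all). A network is called small-world when the Leff-ratio interval lies
entirely above 1; group differences are read as non-overlap of two
intervals. Geff ratios near (often slightly below) 1 mean integration is
no better than degree-matched chance, the expected small-world signature.

## Centralities and hubs

Weighted degree is the sum of incident |r| weights. Eigenvector
centrality is the principal eigenvector of the weighted adjacency
(symmetric eigendecomposition; equivalent to the power-iteration fixed
point), reported as magnitudes max-normalized to 1. For a disconnected
graph the leading eigenvector is supported on the spectrally dominant
component and all other nodes score 0 — the convention needed at the
fragmented strictest threshold. Closeness uses the reachable-count
rescaling Clo(v) = (k/Σd)·(k/(N−1)) over the k reachable nodes, 0 for
isolates. Betweenness is Brandes' algorithm on the distance weights
(python-igraph); ties in shortest paths are credited fractionally.

A region is a hub when it sits in the top ⌈q·R⌉ (default q = 0.25) of at
least 3 of the 4 metrics; values tied with the cutoff are all included,
making the call invariant to any strictly monotone per-metric transform
and to row order. A stable hub is a hub at every threshold; the hub score
counts thresholds at which the region was a hub.

## Permutation comparison of centralities

Group labels enter the analysis only through the correlation matrices, so
the permutation test reassigns subjects (without replacement) to
pseudo-groups of the original sizes and recomputes the *full* pipeline —
correlation, threshold at the same level, centralities — per permutation.
The default p-value is two-sided, the fraction of permuted |Diff| ≥
empirical |Diff| per (region, metric); a one-sided variant (Diff >
empirical) and an add-one (b+1)/(m+1) convention are switchable. Inside
the permutation loop the p ≤ level rule is applied as |r| ≥ r_crit(n,
level), which is algebraically identical (the t-transform is monotone)
and avoids recomputing p-values.

## Edge comparison

Each network's coefficients are Fisher-Z transformed (Z = arctanh r).
Distribution-level difference: two-sample KS on the two networks' edge
multisets, asymptotic p. Cell-level difference, over the union of the two
edge sets:

    dC = (Z_A − Z_B) / √(1/(df_A − 3) + 1/(df_B − 3))

with df = the group's subject count, so 1/(n−3) is the textbook sampling
variance of Z (a df = n−2 variant is switchable). |dC| > 2 (≈ α = 0.05
two-sided) flags a change, attributed to the group with the larger Z and
annotated with hub membership of its endpoints. For cells surviving in
only one network, the absent side contributes its unthresholded
coefficient by default; treating a sub-threshold coefficient as exactly 0
(also available) overstates dC by the amount of the discarded
correlation. Reports state which mode was active.

## Behavioral statistics

The bootstrap scheme draws N subjects with replacement from the pooled
sample and assigns them positionally to the original group slots. Pooling
is what makes the resampled statistic a *null* statistic — the
group–outcome link is broken — so p = #(statistic_resampled >
statistic_empirical)/m estimates the null exceedance probability (strict
inequality; magnitudes compared so t is two-sided; add-one correction
switchable). Within-group resampling is used only for percentile CIs of
group means, where the sampling (not null) distribution is wanted. The
base statistics are the classical one-way F and Welch's unequal-variance
t; Cohen's d uses the pooled (n−1)-weighted SD and is reported as a
magnitude. Multiple comparisons: Bonferroni (×k, capped at 1) for planned
pairwise tests, Benjamini–Hochberg across regions for expression
screening.

## Synthetic data generator

The generator emulates the statistical layout of a lesion-study cohort,
not its biology: per-group multivariate-normal densities (truncated at 0)
whose correlation target has block community structure (within/between
community levels), designated hub regions with elevated cross-community
correlation, and per-group edge modifications — pairwise or
whole-neighborhood deltas — for planting group contrasts. Modified
targets are validated (|r| < 1 off-diagonal, else rejected) and repaired
to the nearest PSD correlation matrix by eigenvalue clipping with a
re-normalized unit diagonal. A null twin of any scenario removes all
modifications, giving both groups one correlation structure for
type-I-error suites.

The default study-shaped scenario has 30 regions in 7 anatomical
communities (basolateral amygdala 6, central amygdala 3, dorsal
hippocampus 3, ventral hippocampus 4, parahippocampal 6, prefrontal 5,
retrosplenial 3), a control group of 9 subjects on all 30 regions and a
lesioned group of 10 subjects missing the 3 dorsal-hippocampal regions.
Within-community correlation is 0.6, between 0.25; IL is the planted
control hub (cross-community 0.68); the lesioned group strengthens the
RSC and Per_36 neighborhoods (+0.3), weakens the IL neighborhood (−0.35),
and broadly weakens the vSub/vCA1/BLV neighborhoods (−0.25) to emulate
lesion-induced loss of interactions. Elevations were sized from the
post-repair targets so the planted hub's expected strength clears the
strongest non-hub region by well more than the sampling noise of a summed
correlation row at n = 9 (16.3 vs 9.4 for IL). Density location/scale
default to 1500 ± 300 nuclei/mm² (mean 5 SDs above zero, so truncation
at 0 removes negligible mass). Behavioral defaults: a 300 s test;
group sizes 12/12/8 with means 150/115/40 s (SD 55/55/30) for the
lesion-vs-control-vs-immediate-shock experiment, and 10/9/9/11 with
190/165/150/110 s (SD 55) for the double-lesion experiment — chosen to
produce a medium lesion effect and large shock-control/double-lesion
effects.

What the generator does *not* emulate: measurement error structure of
image quantification, inter-regional mean-density differences, heavy
tails or skew in freezing times, and any within-subject dynamics.
Passing tests therefore demonstrate correctness and calibration of the
*method* under the model's own assumptions, not robustness of the science
to real-data violations of them.

## Simulation sizes and numerical choices

Defaults follow the analysis conventions (10 000 resamples/nulls/
permutations). The test-suite and acceptance-script runs scale these to
keep full runs fast, as the package's own choice of simulation size:
rewired-null ensembles of 150–1000, permutation tests of 300–1000,
bootstrap p-values of 300–1000 resamples; calibration suites use 500
simulated datasets (type-I error of the bootstrap ANOVA and of the
permutation test, both within 0.05 ± 0.02), 200 datasets for
planted-structure recovery (≥ 90% hub recovery at the default scenario;
≥ 80% power for a hub neighborhood weakened by 0.4 at n = 40 per group,
sized by a per-edge power computation). Percentile CIs use
non-interpolating order statistics. Ties at the hub-quantile cutoff are
all included. Degenerate inputs (zero-variance regions, |r| = 1 in the
Fisher transform, zero within-group variance in F, constant pooled
samples in d) raise errors naming the offending quantity rather than
propagating NaNs.

## Known limitations

- Correlation networks at n ≈ 10 subjects are noisy objects; single-draw
  properties (edge density, exact hub sets) vary widely between draws.
  The pipeline's robustness devices (threshold sweep, stable hubs,
  resampling tests) mitigate but do not remove this.
- The eigenvector convention scores only the dominant component; on
  networks whose two largest components have near-equal spectral radius
  the assignment can flip between draws.
- The KS p-value is asymptotic; at very small edge counts it is
  approximate (the statistic D itself is exact).
- The bootstrap-null p for t statistics is two-sided via magnitudes; a
  directional reading requires the one-sided switch.
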