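# Methods

This note documents the statistical models and design choices behind
`mirscreen`: what each stage assumes, which knobs matter, what the
synthetic generator does and does not emulate, and where the design was
genuinely open.

## The data model

A screen is a matrix `X ∈ R^{n×p}` of log2 fold changes, rows indexed by
miRNA mimics, columns by antibody-level readouts (total proteins and
phosphosites, distinguished by a `_p<site>` suffix). Values are relative
to non-targeting controls. The pipeline assumes slide-level RPPA
processing (spot quantification, SuperCurve-style fitting) has already
happened upstream; `normalize` only subtracts the per-protein median of
the control rows and then median-centers each protein across miRNAs to
remove residual plate bias. Both steps are exposed as flags because
different facilities export at different stages of normalization.

Discretization uses a per-protein robust z-score,
`z = (x − median) / (1.4826 · MAD)`, calling ±1 beyond a threshold
(default 1.5, configurable — a perturbation screen has heavy tails, so a
robust scale is essential). When the MAD collapses to zero on a column
that still varies (a single strong responder among many zeros), the
scaled mean absolute deviation (1.2533 · meanAD) is used instead; a
truly constant column produces no calls. Note that a robust z of 1.5 is
a permissive cutoff: on Gaussian noise it calls ~13% of entries, so
analyses that need high-precision calls (e.g., the concordance example)
should raise it.

## Consensus clustering and the number of clusters

For each k in 2…15 the screen is clustered `n_resamples` times
(default 100) by k-means (Lloyd's algorithm, k-means++ seeding, 10
restarts, max 300 iterations, tol 1e-6), each time holding out 10% of
the miRNAs. The consensus matrix M(k) records, for each pair, the
fraction of co-samplings in which the pair co-clustered; pairs never
co-sampled are tracked as undefined rather than silently zero (at the
default settings this is vanishingly rare). Final labels come from
average-linkage hierarchical clustering of 1 − M(k*), cut into k*
groups, so membership reflects co-clustering frequency rather than any
single k-means run.

Cluster-number selection uses the consensus-value CDF. A(k) is the area
under the empirical CDF of the upper-triangle consensus values,
Δ(k) = (A(k) − A(k−1))/A(k−1) (Δ at the smallest k is A itself), and a
candidate k must have Δ(k) ≥ `delta_min` (default 0.025). The Δ rule
alone is insufficient: a large unstructured group (here, the null
cluster of miRNAs with only minor effects) is split almost
deterministically by k-means along its leading noise direction, so A(k)
keeps growing past the true k on stable but arbitrary splits. The
selection therefore also requires the clustering to be *unambiguous*:
the proportion of consensus values strictly between 0.1 and 0.9 (the
ambiguity of the partition) must be at most `pac_max` (default 0.05).
The largest k satisfying both wins; if none does, the smallest k in the
range is returned. On the default design the ambiguity is exactly 0 for
k ≤ 5 and jumps above 0.15 at k = 6, giving a clean selection of five
clusters.

Marker discovery fits, per cluster, a one-vs-rest ensemble of 500
bootstrapped decision trees (`max_features = sqrt(p)`), scoring each
protein by the mean decrease in out-of-bag accuracy over 10 column
permutations (per tree; trees that never split on the protein contribute
zero). Permutation importance was preferred over impurity importance
because signature proteins are correlated by construction. Negative
means are clipped to zero in the report.

## Proliferation

The generator couples cell-number change linearly to the screen:
`rel_change = β · (mean over activators − mean over repressors) + ε`,
with activators {CCNB1, CDK1, S6_pS235} and repressors {P21, P27, PTEN}
embedded in the planted signatures, β = 0.12 and ε ~ N(0, 0.02). These
defaults make the cell-cycle-down cluster strongly anti-proliferative
and the mTOR-like cluster pro-proliferative, producing a low group drawn
from the decile rule (~88 of 879) and a high group of roughly 150–190
miRNAs — a two-group design of the same shape as a real mimic screen,
though not tuned to reproduce any particular published count.

Binning: high ⇔ rel_change > 0.05; low ⇔ rel_change within the empirical
10th percentile (linear-interpolation quantile, ties at the cutoff
included). The rules are independent; a configuration in which the
decile cutoff exceeds the high threshold is rejected as an error rather
than resolved silently. Activator/repressor calls use plain Pearson
correlation per protein with |r| ≥ 0.3; zero-variance proteins are
flagged and classed "neither". The predictive model is a linear SVM
(C = 1) with per-fold standardization under leave-one-out
cross-validation; linear, because the per-protein weights are then
directly interpretable as activator/repressor scores. The fraction of
miRNAs with |rel_change| below 1% is reported descriptively, never
asserted.

## Concordance

The "transition matrix" between two discretized screens is a static 3×3
cross-tabulation over the intersection of their miRNA and protein ids.
The overlap statistic divides the sign-preserved calls by the number of
nonzero calls *in the reference screen*: "true-positive changes" reads
most naturally as reference-screen calls, and agreement on neutral is
excluded because agreeing on "no change" is not a reproduced change.
Both directions and a per-miRNA breakdown are emitted, since pooled and
per-miRNA averages differ whenever call rates vary across miRNAs. The
published real-data overlap value for this statistic is not a target
here (the real screens are not available); the statistic's behavior is
validated against closed-form expectations under independence
(overlap → q/2 at call rate q) and monotone degradation under flip
noise.

## Gaussian graphical models

The estimator solves
`max_Θ log det Θ − tr(SΘ) − λ Σ_{i≠j} |Θ_ij|`
(diagonal unpenalized, S the correlation matrix of the standardized
phospho block) by the classic block coordinate descent on the working
covariance W: cycling over columns, each column update solves an
l1-regularized quadratic subproblem by coordinate descent, warm-started
across sweeps and across the λ path. The kernel is numba-compiled and
takes a full penalty matrix, which also yields the support-constrained
MLE (zero penalty on the support, effectively infinite elsewhere).
Convergence: mean absolute change of W per sweep below tol × mean
|off-diagonal of S|. Each exact column update increases log det W, and
this surrogate is asserted non-decreasing every sweep; the penalized
log-likelihood trajectory is returned alongside and is monotone in
practice. Exceeding the sweep budget raises an error carrying the last
iterate and its residual. Correctness is checked against the
unpenalized matrix-inverse limit, KKT stationarity, brute-force numeric
maximization at p = 3, and an independent solver.

λ is selected by the extended BIC with γ = 0.5 over 20 log-spaced values
in [0.01, max|S_ij|], scanned sparse-to-dense with warm starts and ties
broken toward the sparser model. EBIC is evaluated on the
support-constrained refit rather than the shrunken path estimate: the
l1 bias otherwise inflates the apparent likelihood gain of extra edges
and systematically over-selects (on the planted designs, refit-scored
EBIC moves median support-recovery F1 from ~0.6–0.8 to ~0.9). The
reported network takes its topology from the penalized fit at the
selected λ and its edge scores (partial correlations) from the refit, so
ρ values are not biased toward zero.

Cross-line comparison intersects edge sets exactly, reporting the count
of edges present in precisely each subset of lines (inclusion–exclusion
consistent by construction) plus the common core and a hive-plot-ready
edge table.

## Regulator and pathway networks

A miRNA → phosphoprotein edge requires the same nonzero call in at least
`min_lines` (default 2) of the cell-line screens; any pair with calls in
*both* directions anywhere is treated as ambiguous evidence and dropped
(logged). This stricter conflict rule — rather than dropping only pairs
where both directions independently reach `min_lines` — is deliberately
conservative and keeps the edge set anti-monotone in `min_lines`, which
the per-network filters are designed to guarantee. miRNAs with fewer
than `min_targets` (default 2) surviving edges are removed from each
signed network separately. Pathway regulation is the fraction of a
pathway's *measured* members a miRNA calls (unmeasured members are
excluded from the denominator); inclusion at fraction ≥ 0.5 exactly.

## The synthetic generator

The generator plants, with one master seed and named substreams:

- **Primary screen** (879 × 127 + 8 control rows): four active clusters
  of 79/153/115/150 miRNAs with fixed signed signatures of 6 proteins at
  |log2FC| = 1.0, a null cluster of 382 noise-only miRNAs, and i.i.d.
  N(0, 0.25) residuals. Signatures follow recognizable biology (a
  Notch/AKT-up cluster, a cell-cycle-down/CDK-inhibitor-up cluster, a
  Tau/EMT-down cluster, a PTEN-down/mTOR-up cluster) so marker discovery
  and pathway scoring have interpretable truth.
- **Cell-line networks**: three sparse precision matrices over the
  20-phosphosite panel with 8 core edges shared by all lines (planted at
  |ρ| = 0.42 — links conserved across backgrounds are the strongest), 9
  edges shared by the two mutant lines and 1 by the two same-tissue
  lines (|ρ| = 0.40), and 2 private edges per line. Matrices have unit
  diagonal and off-diagonal −sign·ρ, which realizes the planted partial
  correlations *exactly*; node degrees are capped at 2 per line and the
  random part of the support is resampled until the smallest eigenvalue
  exceeds 0.15. The cap matters: partial correlations strong enough to
  detect at n = 154 (the EBIC detection threshold is ≈ 0.27 there) are
  only positive-definite on chain-like, hub-free supports — which is
  also the topology of signaling cascades.
- **Secondary screens** (154 miRNAs × 127 proteins, 103 shared):
  cluster-stratified miRNA subset; cluster signature means applied to
  shared *non-phospho* proteins (sign-flipped per entry with
  `flip_prob` to emulate imperfect replication); the phospho block drawn
  from N(0, Σ_line) so its covariance follows the planted graphical
  model — systematic cluster means on the phospho block would confound
  the i.i.d. covariance the GGM stage estimates; six planted regulator
  miRNAs instead carry sparse per-miRNA shifts of 3.5 marginal SDs on 3
  phospho targets each (one direction per regulator), consistent across
  lines, which perturbs the covariance only at order 1/154.

What the generator does **not** emulate: sequence-level targeting,
miRNA family structure in the responses, antibody cross-reactivity,
plate/batch artifacts, heavy-tailed or correlated residuals outside the
phospho block, and real-data cluster overlap (planted clusters are
well-separated by design). Passing tests therefore demonstrate that the
pipeline recovers the structure it assumes when that structure is
present at realistic sizes and noise — not that any particular
biological dataset satisfies those assumptions.

## Problem sizes and numerical choices

Tests run the clustering acceptance check at the full 879 × 127 design
with 25 resamples (the library default is 100; the selection statistics
are already stable at 25), the GGM comparisons at n = 154, p = 20 over
20 seeds, and the end-to-end determinism check on a 300-miRNA
configuration — sizes chosen so the full suite completes in a few
minutes on one core. Ties and degenerate inputs are handled explicitly:
k-selection ties go to the smaller k, EBIC ties to the sparser model,
MAD = 0 columns fall back to meanAD, conflicted regulator evidence is
dropped and logged, zero-variance proteins are flagged out of
correlation and network estimation, and pipeline stages communicate only
via files so any stage can be re-run in isolation. All randomness
descends from a single master seed through counter-derived substreams
(`numpy` SeedSequence spawn keys), making every artifact byte-for-byte
reproducible.

## Known limitations

- The exact-magnitude precision construction rejects supports that are
  not positive-definite with margin, so extremely dense supports or
  magnitudes near the PD boundary are unreachable by design.
- EBIC refit scoring assumes n > p on the phospho block; the p ≈ n
  regime would need a different selector.
- The glasso edge path can show machine-scale non-monotonicities
  (edges with |Θ| ~ 1e-3 flickering between adjacent grid points);
  material edges are monotone in practice.
- The overlap statistic is asymmetric by construction; both directions
  are reported, and users comparing screens with very different call
  rates should prefer the per-miRNA table.
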