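# Methods

## Overview

`corepair` implements an integrated network analysis for linking soil
multi-trophic co-occurrence structure to N₂O emission and its temperature
sensitivity: co-occurrence network construction, connectance statistics,
emission/Q10 estimation, a two-step core species-pair criterion, and
within- vs between-group contribution estimates. A synthetic-study
generator provides complete surveys with planted ground truth, so every
stage is validated by recovery rather than by fixtures.

## Co-occurrence networks

Networks are built from Spearman rank correlations (average ranks for
ties) between OTU relative abundances, per field or globally. Candidate
OTUs must be detected (abundance > 0) in at least a prevalence fraction of
the scope's samples (default 0.5; globally this is an absolute count,
ceil(n/2)) and be non-constant — constant vectors have undefined rank
correlations and are excluded from both the edge set and the connectance
denominator. Edges keep pairs with ρ strictly above the threshold
(default 0.8), **positive correlations only** by default; an
`absolute=True` option thresholds |ρ| instead. No p-value gate is applied
by default; an optional Benjamini–Hochberg FDR filter is available. Fewer
than 4 samples in a scope is an error (rank correlation is degenerate).

Connectance is 100 × (strong edges) / (candidate pairs), where the
denominator counts pairs among candidates after the prevalence filter:
n_m × n_n between distinct groups, k(k−1)/2 within a group. Group pairs
with zero possible pairs are flagged absent. The prevalence fraction and
threshold are configurable because published analyses differ in both.

## Emission statistics

Per sample, with rates at 8, 15, 20, 25 and 35 °C:

- **potential** — the rate at 25 °C (denitrification optimum);
- **temperature sensitivity** — sample SD / mean of the five rates;
- **Q10** — default: fit ln(rate) = c + bT by least squares over all
  positive rates and return e^(10b) (uses all five temperatures); a
  `ratio` method averages rate(T+10)/rate(T) over the 10-°C-spaced pairs
  (15→25, 25→35). Both agree exactly on noiseless exponential data.

Field-level values are sample means; the MAT response is fitted at field
resolution with both y = a·e^(bx) (least squares on ln y) and ordinary
linear regression. To make the two AICs commensurable, both are computed
from residual sums of squares **on the original response scale** (the
exponential model's predictions are back-transformed), with k = 3
parameters each; comparing a ln-scale likelihood against a raw-scale one
would be invalid. The exponential r² is reported from the ln-scale fit so
it stays in [0, 1]. Nonpositive responses are dropped from both fits
(same n) with a warning.

Gene signals are normalized per sample by the mean intensity over
detected (positive) probes, so detected intensities average 1 within
every sample.

## Two-step core identification

**Step 1 — functional keystoneness.** The group-pair interaction effect
T_mn is the Pearson correlation between the per-field connectance of
between-group pair (m, n) and the per-field emission metric. Each taxon's
weight is w_s = r_s + r_s · Σ T_mn over the group pairs containing s's
group, where r_s is the Pearson correlation of the taxon's relative
abundance with the per-sample emission metric (constant taxa get w = 0
with a warning). Keystoneness is

F_i = Σ over unordered pairs {k, l} ⊆ M_F, k, l ≠ i of
      w_k · w_l · σ_kl(i)/σ_kl

computed by a Brandes-style accumulation with endpoint weights on the
unweighted thresholded graph; disconnected pairs contribute zero, and
endpoints never count as interior. The functional set M_F defaults to all
network nodes — the equations are well-defined for any subset, and no
restriction is the least arbitrary choice; a subset can be supplied.
Weights are used signed, exactly as defined; negative F is legal and
handled by the affine standardization B′ = (F − F_min)/(F_max − F_min)
(all B′ = 0 with a warning when F is constant). Because the sum runs over
unordered pairs, any ordered-pair convention would only scale F by 2 and
leave B′ unchanged.

**Step 2 — pair reinforcement.** The thresholded network is projected to
its binary adjacency; R_i is node degree, S_ij the shared-neighbor count,
N_I the number of network nodes (isolated candidates included). For every
linked pair, the checkerboard score C = (R_i − S_ij)(R_j − S_ij) counts
"one partner each" neighbor configurations and the togetherness score
T = S_ij(N_I + S_ij − R_i − R_j) counts shared-presence/shared-absence
configurations; the identity C − T = R_i·R_j − N_I·S_ij is asserted for
every pair in integer arithmetic (a violation is an internal error). T is
negative when S_ij > 0 and N_I + S_ij < R_i + R_j. R_i and S_ij are read
from the **network adjacency** (degree and shared network neighbors), not
from raw sample presence/absence: the projection is defined on the
network, and the adjacency reading is the one consistent with the C − T
identity. The reinforcement indices are B′_i·B′_j·C and B′_i·B′_j·T; pairs
are ranked per variant, separately for between-group (top 15) and
within-group (top 10) interactions, with deterministic tie-breaking
(higher raw C or T, then lexicographic OTU ids). The group-pair summary
reports, for both variants, the sum of the index over all linked pairs
and its mean over the selected core pairs; the checker variant is the
default headline column.

## Contributions

Per-field group-pair connectances form the feature matrix (between-group
and within-group sets are disjoint by construction; absent combinations
are zero-imputed and flagged). A random forest (default 1000 trees,
feature subsampling one third of features, fixed seed) regresses the
per-field emission metric on each feature set; the reported percent
variance explained is 100 × the out-of-bag R², which may be negative when
the model predicts worse than the response mean. Out-of-bag PVE is the
defensible convention; a `training` mode reports the in-sample fit for
comparison. The observation unit is the field — the unit at which
connectance exists.

## Association statistics

- **Partial Spearman**: rank-transform all variables, residualize the x
  and y ranks on the control ranks by least squares, Pearson-correlate
  the residuals, parametric t p-value on n − k − 2 degrees of freedom.
  With no controls this reduces exactly to Spearman. Collinear controls
  are an error.
- **ANOVA + Tukey HSD**: one-way F test and pairwise Tukey comparisons at
  α = 0.05, summarized by an insert-and-absorb compact letter display
  (deterministic in sorted group order).
- **Mantel**: Pearson correlation of lower triangles; one-sided add-one
  permutation p over joint row/column permutations (default 999). Core
  dissimilarity uses Bray–Curtis on core-OTU relative abundances and gene
  distance uses Euclidean on normalized intensities — standard choices
  for the respective data kinds.
- No multiple-testing correction on correlation matrices by default (raw
  p < 0.05 flags); an optional BH mode exists.

## Synthetic-study generator

The generator emulates a nested paddy-field survey: 4 climatic zones ×
3 fields × 11 samples (132 samples; all counts configurable), 200 OTUs
over the five main groups, MAT increasing 1.5–23.8 °C across fields, and
soil attributes (pH, DOC, CEC) with mild MAT trends.

**Abundances** come from a latent Gaussian copula: per zone, a latent
correlation matrix is assembled from equicorrelated group blocks
(within-group 0.55, between-group 0.50 at the gradient midpoint) and
planted core-pair modules, repaired to positive definite by eigenvalue
clipping (an error suggests lowering targets if the repair would shift
any entry by more than 0.15); samples are drawn from the zone's Cholesky
factor, pushed through heterogeneous log-normal marginals and closed to
sum 1. Spearman correlations are invariant to the monotone marginals, so
planted latent correlations are recovered up to closure (±0.05
tolerance on recovery tests). Background block correlations scale by a
per-zone multiplier rising 0.6→1.4 from the coldest to the warmest zone,
planting the observed network tightening along the climatic gradient.

**Planted modules.** Each of the 10 function-linked between-group core
pairs is a module built from an explicit factor model (hence exactly
positive semi-definite): the two members load on a shared pair factor
(latent ρ = 0.90), five shared neighbors load on the same factor
(member–neighbor ρ = 0.88, so these edges survive the 0.8 threshold at
n = 132), and three private neighbors per member load on the member's own
factor (ρ = 0.84 to their member, 0.62 to the other member — below the
threshold, so each member keeps a private neighborhood). This makes the
planted pair a genuine hub pair: high degree, five shared neighbors, and
nonzero betweenness. Module OTUs are decoupled from the diffuse
background so the full matrix stays block positive-definite. All module
OTUs carry function loadings (members 1.0, neighbors 0.8) and sit lower
in mean log-abundance (offset −0.8) so their summed mass stays a modest
share of the community — otherwise compositional closure would cancel the
module signal in the emission baseline — and their log-abundance rises
linearly toward warm zones (shift ±0.5), coupling the function-linked
taxa to the climatic gradient as the survey's core taxa are.

**Emissions.** rate(sample, T) = baseline × q10^((T−25)/10) × log-normal
noise (CV 0.10, median 1 so log-scale fits are unbiased), where baseline
is the loading-weighted abundance sum (scale 60 µg N₂O-N kg⁻¹ day⁻¹ per
unit relative abundance) plus a zone effect 2·e^(0.08·MAT). True per-zone
Q10 defaults are 1.67 (midtemperate), 2.14 (warm-temperate), 2.85
(subtropical) and 2.45 (tropical) — the study conditions the default
design emulates. **Gene signals**: nirK/nirS/nosZ probe intensities are
affine in the summed core-member abundances plus noise; the remaining
genes are independent noise.

**What the generator does not emulate:** zero inflation/sparsity (all
OTUs are present in all samples, so prevalence filters pass everything by
default), overdispersed sequencing counts, spatial autocorrelation within
fields, and any mechanistic nitrogen-cycle chemistry — emission is a
statistical construction. Passing recovery tests therefore show the
estimators are correct and calibrated under the planted statistical
structure, not that real surveys carry that structure.

## Numerical choices and degenerate inputs

- All randomness flows from a single integer seed; fixing it fixes every
  generated byte.
- Spearman p-values use the t approximation (as `scipy.stats.spearmanr`).
- Constant OTUs: excluded from network candidates; w = 0 in weighting.
- F constant across a network: all B′ defined 0 with a warning.
- Mean rate 0: CV undefined (error). Missing 25 °C rate: error.
- Nonpositive rates are dropped from log-linear Q10 with a warning; fewer
  than two usable points is an error.
- Tests and simulations use scaled-down problem sizes (12–40 fields,
  100–500 replicates, 99–999 permutations) chosen so that every stochastic
  check has comfortable Monte-Carlo margins at fixed seeds.

## Known limitations

- Correlation-based weights are proxies, not interaction strengths; the
  ranking inherits every caveat of correlation networks on compositional
  data.
- The connectance denominator depends on the prevalence filter; published
  values are comparable only under the same filter.
- Out-of-bag PVE at ~12 fields is noisy and often negative for weak
  feature sets; contribution estimates stabilize at survey scales of
  ~40 fields.
- The per-field networks use 11 samples; rank correlations at that n are
  coarse (the 0.8 threshold sits ~2.4 null SDs from zero), which is why
  group-level connectance, not individual edges, is the per-field signal.
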