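# Methods

`phenosom` implements a data-driven phenotyping pipeline for heterogeneous
cohorts of struggling learners: children described by a small battery of
normed cognitive z-scores are mapped onto a self-organizing map (SOM),
tested for topographic structure by categorical label, carved into
consensus profile groups, and compared on measures inside and outside the
machine learning, optionally including structural-connectome regional
strengths. This note records the models, the parameters that matter, the
numerical choices, and the known limitations.

## Batch self-organizing map

The map is a fixed grid of `R x C` nodes (default 10 x 10, chosen by the
usual rule of thumb of about five times the square root of the number of
observations for cohorts of ~500), each node `i` carrying a weight vector
`m_i` in measure space. Training is the classic batch algorithm:

1. **Initialization.** Node weights are placed on the plane spanned by
   the first two principal components of the data through the data mean.
   Grid rows vary along PC1 and columns along PC2, with spans
   proportional to the square roots of the two leading eigenvalues, so
   the initial map already matches the data's dominant plane. Optional
   Gaussian jitter (`init_jitter_sd`, default 0 for a single map, 0.05
   inside the consensus loop) perturbs this deterministic start.
2. **Batch cycles.** Every child is assigned to its best matching unit
   (BMU) — the node minimizing Euclidean distance, ties broken toward the
   lower node index for reproducibility. Each node then becomes the mean
   of all children whose BMU lies within grid distance `ND` of it (a
   *bubble* neighborhood over a neighborhood set, not a Gaussian kernel,
   matching the buffer-averaging description of the batch algorithm). All
   nodes update concurrently from the pre-cycle weights. A node whose
   neighborhood captures no children keeps its previous weights — the
   alternative (a 0/0 mean) is undefined, and retention is the only
   choice that leaves the fixed point of constant data intact.
3. **Schedule.** The neighborhood shrinks over an ordering phase of `n`
   cycles, `ND(t) = 1 + INS (1 - t/n)` for `t = 1..n` (defaults `INS = 3`,
   `n = 5`, giving 3.4, 2.8, 2.2, 1.6, 1.0), followed by fine-tuning
   cycles at `ND < 1` (default one cycle at `ND = 0`, i.e. each node
   averages only its own BMU hits — exactly a Lloyd/k-means update with
   nodes as centroids, which the tests verify against an independent
   Lloyd implementation).

Grid geometry defaults to a hexagonal lattice with link (hop-count)
distances — the documented defaults of the classic SOM toolboxes — with
rectangular topology and Euclidean/Chebyshev metrics available. The
quantization error (mean child-to-BMU distance) is recorded per cycle; on
every seeded test cohort it is non-increasing through the ordering phase,
though this is an empirical regularity of batch training, not a theorem.

**Weight planes.** Per-measure maps of node weights; the Pearson
correlation between two measures' planes summarizes how similarly those
tasks separate children. Zero-variance planes yield undefined (NaN)
correlations rather than silent zeros.

## Topographic distribution tests

Whether a categorical group (a referral reason, a diagnosis flag) occupies
a distinct map region is tested with the two-sample two-dimensional
Kolmogorov-Smirnov statistic: `D` is the largest absolute difference
between the members' and nonmembers' quadrant fractions, maximized over
candidate origins and all four quadrant orientations
(`{x<=x0, x>x0} x {y<=y0, y>y0}`). Candidate origins are every
combination of an observed x with an observed y coordinate. On a finite
grid this attains exactly the maximum of a scan over every grid node
(any off-sample threshold can be moved to the nearest observed coordinate
without changing quadrant membership); restricting origins to observed
*points* — a common shortcut — can undershoot it, which is why the
product set is used. Children sharing a BMU contribute multiplicity.

Significance uses a label permutation test,
`p = (1 + #{D_perm >= D_obs}) / (1 + n_perm)` (default 9,999
permutations), computed in exact integer arithmetic so ties are handled
deterministically. Permutation inference is exact up to Monte-Carlo error
and valid at small group sizes, at the cost of conservatism from the
discreteness of `D` on a grid: calibration runs show type-I error in the
0.03–0.05 range at nominal 0.05. No correction is applied across
category tests by default; it is configurable.

## Consensus profile groups

Node weights are clustered by k-means (k-means++ seeding, best of 10
restarts; `k = 4` by default, configurable), and each child inherits its
BMU's cluster. Because both the map (through init jitter) and k-means
(through its seed) vary run to run, the whole train-cluster-assign
procedure repeats `n_iterations` times (1,000 by default; the bundled
analyses and validation studies use 200, which already stabilizes modal
assignments). Cluster labels are aligned across repetitions by optimal
assignment (Hungarian matching) of centroids to the first iteration's
centroids — the least arbitrary way to make "the same cluster" meaningful
across retrainings. Each child receives:

- **modal cluster** — the most frequent aligned label;
- **consistency** — the modal share, in `[1/k, 1]` (used as the shading
  of per-child dots in profile figures);
- **clarity** — a per-child Pearson chi-square of the k assignment
  counts against the uniform expectation `n_iterations / k` on `k - 1`
  degrees of freedom; `p < 0.05` marks a clear modal cluster rather than
  a boundary child.

What varies across retrainings is a declared interpretation: the original
procedure's source of run-to-run variation is not documented, so this
implementation injects it explicitly via init jitter plus fresh
clustering seeds, both controlled by one master seed.

## Group statistics

- **Continuous measures** (cognitive, learning, factor scores): classical
  one-way fixed-effects ANOVA, df `(g-1, N-g)`; Tukey HSD post hocs via
  the studentized-range distribution with Tukey-Kramer standard errors
  for unequal group sizes; Bonferroni correction within each data family
  (cognitive, learning, behavior). Degenerate inputs (zero within-group
  variance with equal means) report NaN rather than a coerced statistic.
- **Categorical labels**: a one-way Pearson goodness-of-fit of the
  member counts across clusters against expectations proportional to
  cluster size, `E_c = total * n_c / N`, on `#clusters - 1` df. This is
  the unique test form that reproduces the published worked values from
  their printed counts (e.g. 14.931 for the speech-and-language-therapy
  row, 6.755 for attention referrals), which the tests assert to ±0.01.
- **Gender**: per-cluster 1-df goodness-of-fit of the male/female split
  against the full-sample male proportion, no continuity correction —
  again the unique reading reproducing the published 6.12 and 6.80.
- **Questionnaires**: PCA on the subscale correlation matrix, two
  retained components, varimax rotation, factor scores by the regression
  method standardized to mean 0, sd 1. Exactly low-rank (noise-free) data
  makes the default rotation start a saddle point of the varimax
  criterion, so the rotation restarts from a few seeded random rotations
  and keeps the solution with the best criterion value.

## Connectome comparison

Connection weights are `log10(1 + count)` of the symmetrized streamline
count (counts averaged with their transpose). The `+1` offset keeps the
transform defined at zero streamlines and preserves "no streamlines ⇔
weight 0". Regional strength is the row sum of weights. The group
comparison is two-stage: per region, a Welch two-sample t screens the
deficit group against the within-sample age-appropriate group at
uncorrected `p < 0.05`; screened regions are then tested against an
external typically developing group with Benjamini-Hochberg FDR within
the screened set at `q = 0.05`, and a region is *selected* only if it
passes both. Welch rather than pooled t because the group sizes here are
unequal by design. Lobe-level summaries average each child's strengths
over a lobe's regions (an explicit normalization choice; the raw sums are
~84 times larger than per-connection means) and compare groups with a
two-sided Mann-Whitney U reported as `min(U1, U2)` (exact enumeration
below combined n = 20 and no ties, otherwise normal approximation with
tie correction), FDR-corrected across the five lobes within each
contrast.

**Selection-bias caveat.** The two-stage design reuses the deficit group
in both stages. Conditioning on a chance-extreme screen therefore biases
the same group's stage-2 comparison: in null simulations (no planted
effect, groups 40/40/36) about 1.5 of 30 regions are screened per
replicate and ~0.23 are selected — a conditional false-discovery
proportion near 0.15, three times the nominal `q`. BH control holds for
valid p-values; screened stage-2 p-values are anti-conservative by
construction. This is a property of the published procedure itself, which
the implementation follows exactly; power for real planted deficits is
excellent (a 1.5-sd strength deficit is selected essentially always at
these group sizes), but stage-2 FDR should be read as descriptive, not a
guarantee.

## Synthetic cohort generator

The generator emulates the published study conditions so every stage is
testable without the (undeposited) clinical data:

- **Scores**: four generating clusters of sizes 146/121/132/131; per
  cluster, the 7 cognitive + 3 learning z-scores are multivariate normal
  around the published per-cluster means with covariance
  `diag(sd) @ corr @ diag(sd)`. Within-cluster dispersion and
  inter-measure correlation are not published; the defaults —
  per-measure sd 0.5 and exchangeable correlation 0.3 — are declared
  stand-ins chosen so clusters overlap at their boundaries (some children
  genuinely sit between profiles, as reported) yet remain recoverable.
  Both are configurable and flagged as assumptions in the config.
- **Labels**: gender, referral reason (single-valued multinomial) and
  diagnosis flags drawn independently per child at the published
  count/size rate of its cluster; ages uniform on 65–215 months (the
  published range; age plays no role downstream beyond reporting).
- **Questionnaires**: 8 executive-function and 10 communication subscales
  from a two-factor latent model per instrument (simple-structure
  loadings ~0.75–0.8 with two cross-loading subscales), cluster-mean
  offsets from the published subscale table, scale sds 9 (T-scores) and
  2.5 (scaled scores).
- **Connectomes**: symmetric nonnegative matrices with zero diagonal;
  edges `N(base_weight, noise_sd^2)` truncated at zero (defaults 0.7 and
  0.1, the scale of log10 streamline weights), with all edges incident
  to a group's deficit regions reduced in mean by `deficit_delta`. The
  default region-to-lobe table is the 85-region Desikan-Killiany scheme
  (34 cortical per hemisphere, anterior cingulate with frontal,
  posterior/isthmus cingulate with parietal, insula grouped with
  frontal; 8 subcortical structures per hemisphere plus brainstem).

What the generator does **not** emulate: real measurement error
structure (norm-referenced tests have heavier tails and floor effects),
missingness mechanisms, age effects on any score, spatially structured
connectome covariance (edges are independent given group), and any
coupling between questionnaire factors and the cognitive clusters beyond
mean offsets. Passing tests therefore demonstrate that the machinery
recovers structure of this idealized kind at realistic sizes and noise
levels — not that the published clinical findings would replicate.

## Validation studies and problem sizes

The studies in `phenosom.studies` (run by the test suite and
`scripts/acceptance.py`) use: 200 random instances for the 2D KS
grid-scan oracle; 500 replicates x 200 permutations for type-I
calibration; ten master seeds of the full 530-child cohort with
200-iteration consensus for recovery (best-matched agreement ~85%,
label-permutation p < 0.01, seed-averaged profile table within 3 SE of
the generating means, >95% of children with a clear modal cluster); 50
random instances for the Lloyd identity; and 100/500 replicates for
two-stage sensitivity/null rates. These sizes were chosen as the point
where the Monte-Carlo error is well below each decision margin.

## Known limitations

- Consensus clustering assumes `k` is given; the published stopping rule
  (add clusters until held-out measures stop separating them) is a
  manual procedure, not automated here.
- The 2D KS test is conservative on coarse grids (tied `D` values).
- Stage-2 FDR of the two-stage connectome test is anti-conservative
  under the null (see caveat above).
- Lobe-level medians depend on the declared mean-per-region
  normalization; absolute values are not comparable across different
  normalizations.
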