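# Methods

This note documents the models and procedures `fdnet` implements, the
defaults and why they were chosen, what the synthetic data does and does not
emulate, and the numerical conventions that matter for reproducing results.

## Box-counting fractal dimension

For a 3D binary mask the box-counting dimension is estimated from
*N(r) ∝ r^(−FD)*: cubes of edge *r* (voxel units) tile the mask's bounding
box; *N(r)* counts cubes containing at least one occupied voxel; FD is the
ordinary least-squares slope of log *N(r)* against log(1/*r*) (natural log;
the base cancels in the slope).

Conventions that the power law itself does not fix:

* **Cropping.** The mask is cropped to its occupied bounding box before
  counting, so translation inside a larger empty grid changes nothing
  (tested exactly).
* **Grid anchoring.** The counting grid is anchored at the bounding-box
  minimum corner. No multi-offset minimization is performed; the classical
  definition asks for the *minimal* cover, and offset search could be added
  later, but the anchored grid is deterministic and is what the exactness
  tests assume.
* **Box sizes.** Geometric progressions `base^0 … base^K` with
  `base^K ≤` the maximum bounding-box extent, base 2 by default and base 3
  selectable. Base 2 is standard practice; base 3 makes triadic phantoms
  (Menger sponge, Cantor dust) exactly linear in log–log, recovering
  log 20/log 3 ≈ 2.7268 and 3·log 2/log 3 ≈ 1.8928 to machine precision.
  Fewer than three sizes is an error — a 2-point regression carries no
  goodness-of-fit information.
* **Small regions.** Regions with fewer than `min_voxels = 8` occupied
  voxels yield NaN; below that a log–log regression is meaningless. NaNs
  propagate into pairwise-complete correlations downstream.
* **Degenerate curves.** A flat curve (all counts equal, e.g. a single
  voxel) has slope 0 and is reported with R² = 1: the fit is exact.
* **Anisotropy.** Counting is in voxel units; anisotropic voxel sizes are
  ignored. This is a known limitation — FD values from strongly anisotropic
  acquisitions are comparable within a study but not across voxel
  geometries.

## Covariance network

"Covariance correlation" is implemented as the Pearson product-moment
correlation of regional FD across a group's subjects — the standard
structural-covariance construction. Missing regional values are handled
pairwise-complete (per-entry *n* recorded); undefined entries (constant
column, < 3 complete pairs) are recorded as 0 and counted.

The proportional threshold keeps the ⌈p·E⌉ largest positive values among
the E = n(n−1)/2 unique off-diagonal entries (p = 0.20 default → 456 of
2278 for n = 68), zeroing negatives and the diagonal. Two deliberate
choices: the requested count is taken over *all* unique pairs, not only
positive ones, so the edge budget is deterministic; and entries tied exactly
at the cutoff are all kept (order-independence beats hitting the budget
exactly). The retained network keeps its correlation weights — node degree
is defined as a sum of coefficients, so binarizing would change the model.
Metrics accept a `weighted` flag (default True) because the degree
definitions are stated both as coefficient sums and as edge counts in the
literature this follows; both modes are computed by the CLI.

## Modularity and module detection

Q is the standard weighted Newman modularity with strengths
kᵢ = Σⱼ Aᵢⱼ and m = (Σᵢⱼ Aᵢⱼ)/2. Module detection is a Louvain-style greedy
multilevel maximization implemented in-package so that determinism is a
contract, not an accident: node sweep order is shuffled by a seeded
generator, moves are accepted only for gains above 1e−10, levels aggregate
until no gain, and the best of `n_restarts` (default 100) partitions by Q is
returned, ties keeping the first encountered. Module ids are renumbered by
descending size, then smallest contained node index. On ≤ 8-node graphs the
detected Q matches exhaustive enumeration over all partitions (tested); on
the synthetic cohorts it recovers the planted blocks exactly.

## Node and lobe metrics

* Within-module degree z uses the *population* SD over the module (z is a
  standardization over the module's members, not an inference); modules with
  zero SD (uniform or singleton) give z = 0 for all members.
* Participation coefficient: isolated nodes get P = 0; values are clamped to
  [0, 1] against floating-point residue.
* Hub threshold z ≥ 2.5 — the established convention for within-module
  degree — since no cutoff is inherent in the definition.
* Intra-lobe connectivity aggregates weights over node pairs inside a
  lobe/hemisphere selection; inter-lobe over pairs with exactly one endpoint
  inside. Both a raw **sum** and a density-normalized **mean** (sum divided
  by eligible pair count) are reported. The reference tables this mirrors
  print values ≈ 0.3–0.7, a scale consistent with a normalized quantity
  rather than a raw weight sum over hundreds of pairs, but the exact
  normalization is not derivable from their verbal definition ("sum of
  connectional weights"); emitting both modes keeps every candidate
  inspectable rather than guessing. The E/M ratio rows recompute from the
  printed values regardless of mode, since normalization constants cancel.
* Conservation identity (tested): Σ over lobes of intra sums + half the sum
  of the four lobes' inter sums equals the network's total strength.

## Statistics

**Regional tests.** Per-region two-tailed Welch (unequal-variance) t-tests —
Welch over pooled because group variances are not assumed equal; the flag is
switchable. FDR is Benjamini–Hochberg step-up (the default meaning of "FDR
correction"), via statsmodels, cross-checked against a brute-force
implementation in the tests. Zero-variance regions: equal means → p = 1,
unequal → p = 0, flagged `degenerate`.

**Permutation scheme.** One covariance network exists per group, so network
properties cannot be t-tested directly. Each permutation draws 25 F + 25 M
from each group without replacement, pools the 100 drawn subjects, and
splits them into two randomized 50-subject groups preserving the 25F + 25M
balance — the only split consistent with sex-balanced randomized groups of
50. Both randomized networks are rebuilt from scratch (correlation,
threshold, module detection) and the property difference recorded. Three
aligned outputs are reported, because the source description of the decision
rule mixes a percentile criterion with a one-tailed t-test and cannot be
disambiguated: (1) add-one empirical p = (1 + #{null ≥ observed})/(n+1),
never exactly 0; (2) the one-tailed 95th-percentile criterion
(observed > null's 95th percentile); (3) a Welch t-test comparing the two
randomized groups' permuted property samples. Everything is
seed-deterministic: same seed, bit-identical result.

A scale caveat documented rather than hidden: the observed difference is
computed on the full groups (n = 100) while the null is built from
50-subject randomized groups, so under the null the percentile criterion is
*conservative* (null spread exceeds observed spread). When the cohort has 50
per group the draw uses every subject, the scheme becomes an exact
permutation test, and the calibration tests verify ≈ 5% type-I error in that
regime.

## Synthetic data

Phantoms are deterministic: cube/slab/line/point, Menger sponge (recursive
20-of-27 subdivision), Cantor dust (triple product of middle-thirds Cantor
sets). They validate the FD estimator against closed-form dimensions.

Cohorts emulate a two-group, 100-per-group, sex-balanced (50/50) study of 68
regional FD values per subject:

* **Means** sit on the empirical cortical FD scale: per-lobe baseline means
  (frontal 2.2399, temporal 2.1991, parietal 2.2972, occipital 2.2033) with
  the 16 reference effect regions at their published group-A values.
* **Subject SD** 0.10 for every region, matching the lobe-level ±SD scale of
  the reference summaries.
* **Correlation** is compound-symmetric within 5 planted blocks (sizes
  22/14/13/11/8, the reference middle-aged module memberships) at 0.5, and
  0.1 between blocks — the simplest structure whose modularity optimum is
  the planted partition. PSD is validated at build time and non-PSD configs
  fail loudly with the offending eigenvalue. `within_boost_a` optionally
  raises group A's within-block correlation to plant a network-level effect.
* **Group effects**: group B's means shift by the published elderly−middle
  differences at the 16 lateralized regions (14 decreases, left-dominant
  9/5; bilateral pericalcarine increases +0.0519/+0.0261).
* FD values are drawn Gaussian. Real FD distributions are bounded (a 3D
  mask's FD lies in [0, 3]), but at SD 0.10 around means ≈ 2.2 the normal
  approximation never approaches the bounds.

What passing tests on this generator do **not** show about real data: the
compound-symmetric blocks are far cleaner than empirical covariance (hence
synthetic Q ≈ 0.7 versus ≈ 0.22–0.23 in the reference analysis, and
participation coefficients near 0 because almost no retained edge crosses a
block); there is no scanner noise, no registration error, no age/sex
covariance structure; and regional SDs are homogeneous. Module *recovery*
results therefore bound the pipeline's correctness, not its field
sensitivity.

Two honest negative findings from running the pipeline at these defaults,
kept as-is rather than tuned away:

* The published-scale group mean shifts (0.008–0.05 FD at subject SD 0.10,
  n = 100/group) are marginal effects: mean BH recovery at q < 0.05 is
  ≈ 10%, and a global null shows ≈ 0 false discoveries. Detecting such
  shifts reliably would need per-region SDs several-fold smaller or much
  larger cohorts.
* A *uniform* within-block correlation boost (+0.15 in one group) barely
  moves thresholded-network modularity: asymptotically the retained edge set
  is all-within-block for both groups and Q is invariant to a uniform weight
  scale, so only finite-sample leakage of between-block edges carries
  signal (detection ≈ 20–40% depending on n). Q is sensitive to *topology*
  differences, not to uniform covariance strength.

## Problem sizes used by tests and the acceptance script

Simulation-based checks run at deliberately modest sizes chosen as the
package's own test design: module recovery over 10 seeds (5 in the
acceptance script) at the default n = 100/group; regional-test calibration
over 20 seeds (10 in the script); permutation calibration with 200
permutations over 30 replicates (20 in the script) on n = 50/group cohorts;
permutation power over 15 replicates at n = 100/group. Module detection
inside permutations uses 5 restarts (the planted structure is strong; 100
restarts is the default for one-shot analyses).
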