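# Methods

## Scope and model

The package audits the Independent Evolution (IE) algorithm — an
ancestral-state and per-branch "rate" estimator — by running it on data
whose generating process is fully known, alongside two reference methods
(PIC and PIDC) whose statistical behaviour under that process is
understood.  The generating process throughout is Brownian motion (BM) on
a rooted binary phylogeny: the trait change along a branch of length *b*
is Normal(0, σ²·b), independent across branches.  Traits are *geometrically
normal*: BM runs in log space and values are exponentiated at every node
and tip, so arithmetic-scale data are log-normal with variance increasing
from root to tips.  No selection (OU), rate shifts, or measurement error
are modelled.

## The IE algorithm as implemented

Given strictly positive tip values, the algorithm proceeds exactly as
published:

1. An adaptive peak AP(v) = Σᵢ(xᵢ/dᵢ)/Σᵢ(1/dᵢ) is computed for every
   internal node v from **all** tips i at path distance dᵢ, on the original
   tree, before any traversal.  The weighting is read as inverse-distance
   weighting; this is the only reading consistent with the two-tip
   ancestor formula the step generalizes and with the published algebra of
   the equal-branch cherry case, and it keeps AP inside the range of the
   tip values.
2. Cherries are processed tipward→rootward.  Triangle sides come from the
   proportional metric S = 2|x−y|/(x+y) (side s1 between the two
   descendants; s2 and s3 from descendant 2 and 1 respectively to the
   peak); vertex distances from the Farris formulas
   T = (sum of incident sides − opposite side)/2 (T1 and T2 belong to the
   descendants, T3 to the peak); R-values Rᵢ = Tᵢ·2bᵢ/(b₁+b₂) (taken
   verbatim; no rate interpretation is implied by the scaling, which has
   no stated derivation); and the ancestral state
   A = (x₁/R₁ + x₂/R₂)/(1/R₁ + 1/R₂).
3. The collapsed cherry's parent becomes a leaf carrying A and **its own
   original branch length**.  Adaptive peaks are *not* recomputed as the
   tree shrinks.  Because each cherry's inputs (tip/reconstructed values
   and the precomputed peak) are fixed before any collapse, the processing
   order cannot change the values; cherries are nevertheless processed
   deepest-first with ties broken by node id so that error reporting is
   deterministic.
4. After the full pass, signed R multiplies R by the sign of
   (descendant − reconstructed ancestor), and the standardized directional
   contrast on each branch is (ln descendant − ln ancestor)/√b.

The corrected variant ("log" metric) log-transforms the values at entry
and uses absolute differences of the logged values as side lengths —
equivalently, |ln x − ln y| on the arithmetic values — leaving every other
step unchanged.  Its outputs are in log-trait units.  On an equal-branch
cherry whose peak lies between the two values this variant returns the
adaptive peak as the ancestral state exactly (the side lengths become
collinear, T3 = 0, and the weighted mean telescopes); the test suite
verifies the identity to 1e−10 relative tolerance over 1000 random
cherries.

### Undefined values

Two failure classes exist by construction: a side is undefined when the
two values sum to zero (impossible for positive data), and the ancestral
state is undefined when either R is zero, which happens whenever two
triangle vertices coincide (e.g. equal sister values).  By default these
raise an error naming the node.  In permissive mode (used by the bulk
experiments) the node records NaN, NaN propagates to every enclosing
ancestor, and the run continues; summaries report per-row NaN counts and
experiments report pooled counts.  Negative T (a triangle-inequality
violation of the side metric) cannot occur for valid inputs because both
supported metrics are true metrics on positive reals, but the formulas are
applied verbatim if it ever arises and the result flags it.

## Reference methods

PIC ancestral states are the *local* estimates of one Felsenstein pruning
pass on logged data: each internal node takes the inverse-branch-length
weighted mean of its daughters after the standard branch-length adjustment
b′ = b + b_L·b_R/(b_L+b_R).  These local estimates (rather than re-rooted
global ML values) are used deliberately: PIDC is defined on them, and the
frozen cross-check against an independent R implementation (ape) confirms
the arithmetic.  PIC emits n−1 standardized contrasts; PIDC emits one
directional contrast per branch, (child − parent)/√b, 2n−2 in all.

The corrected triangle geometry uses Apollonius' theorem: the median from
the vertex opposite side a is m = √(2b²+2c²−a²)/2 and the centroid lies
2/3 along it, so T = √(2b²+2c²−a²)/3.  A planar-embedding oracle
(coordinates → centroid → Euclidean distances) verifies the closed form to
1e−10 on 1000 random triangles.

## Synthetic data

`simulate_tree` grows a pure-birth (Yule) tree at rate 1 per lineage per
unit time: exponential waiting times, a uniformly chosen lineage splits,
and all pendant branches extend to the final time, giving an ultrametric
tree with strictly positive branch lengths.  A 100-tip tree (root-to-tip
depth ≈ Σ1/k ≈ 5.2 time units) is the default experimental backbone — a
surrogate with the same order of tip count as the primate consensus trees
these methods are typically run on.  Branch lengths are used in their
native units; nothing is rescaled.

`simulate_bm_trait` draws one Normal(0, σ²·b) increment per branch and
accumulates along root-to-node paths (default σ² = 1, root log value 0),
then exponentiates.  The per-branch construction is distributionally
identical to a multivariate-normal draw over tips but also yields the true
change on every branch, which the branch-level audits require.
`simulate_correlated_pair` draws bivariate increments with per-branch
covariance [[1, β],[β, 1]]·b, so β is simultaneously the increment
correlation and the evolutionary regression coefficient of trait 2 on
trait 1; β is swept linearly over [0, 1] across pairs.

What the generator does *not* emulate: real trees' non-ultrametricity and
topological imbalance beyond Yule, intraspecific variation and measurement
error, rate heterogeneity, and bounded or negative-valued traits.  Passing
tests therefore demonstrate algorithmic properties under the ideal BM
regime, not robustness on empirical data — which is the point of the
audit: a method that fails under its own idealized assumptions cannot be
rescued by realism.

Seeding: replicate i of a batch with master seed s uses
`numpy.random.default_rng([s, i])`, so every replicate is reproducible in
isolation and all experiments are bit-for-bit reproducible under a fixed
seed.

## Experiments and their resolution

**Single-trait bias audit** (default 1000 replicates; the CLI `--fast`
profile uses 200): per replicate, IE consumes the arithmetic values and
PIDC the logged values; IE ancestral states are log-transformed before
comparison so all scoring is in log space.  Summaries are box-plot
statistics (mean, SD, median, quartiles, extremes) of estimate − truth per
node and per branch, ordered by distance from the root, emitted as tables
rather than figures.  The headline effects are unambiguous at 200
replicates: the IE root-state inflation is ≈ +1.7 log units against a
Monte-Carlo standard error of a few hundredths.

The claim that PIDC's per-node mean error lies within ±0.05 *everywhere*
needs more care: the error is exactly zero-mean (estimates and truth are
jointly Gaussian and linear in the same increments), but its per-node SD
reaches ≈ 1.15 on the default tree, so a 200-replicate mean has standard
error ≈ 0.08 — wider than the band being tested.  The band test therefore
runs 6000 replicates (worst-node SE ≈ 0.015).  The per-*branch* version of
the same claim is harder still: contrasts on the shortest branches have
SDs of several units.  There the test exploits the estimator's exact
linearity: the branch-contrast linear map is extracted by pushing unit
increments through the actual PIDC code path, and the Monte-Carlo mean of
n replicates — whose exact sampling distribution is Normal with variance
σ²b/n per increment — is drawn directly at n = 10⁶.  This is a change of
sampling scheme, not of the quantity tested.

**Paired-trait slope-recovery audit** (default 500 pairs; `--fast` 100):
per pair, β̂ is the origin-OLS slope (Σxy/Σx², the form appropriate for
zero-mean contrasts) of trait-2 on trait-1 contrasts — n−1 PIC contrasts,
2n−2 PIDC contrasts, 2n−2 IE standardized contrasts, or 2n−2 IE signed
R-values (signed, because unsigned R carries no direction).  IE consumes
arithmetic values and PIC/PIDC logged values, mirroring the single-trait
protocol.  Each method's β̂ are then meta-regressed through the origin on
the simulated β.  Pairs in which IE produced any undefined value are
excluded from the IE meta-regressions only, with counts recorded; PIC and
PIDC keep all pairs.

On the default 100-tip surrogate tree the IE meta-slopes land around
0.93–0.95 — attenuated below PIC's and below 1, with the characteristic
crossing (overestimation for small β, underestimation for large β) — but
their exact values are tree-dependent; stronger attenuation is expected on
larger, more unbalanced empirical trees.  The PIC/PIDC meta-slopes are
tree-independent (≈ 1).

## Known limitations

- IE's failure modes on non-positive data are reproduced, not repaired;
  negative trait values (e.g. principal-component scores) are rejected.
- NEXUS support covers tree blocks with TRANSLATE tables; only the first
  tree of a file is read.
- The pure-birth surrogate cannot reproduce branch-number-specific values
  tied to any particular empirical tree; supplying that tree as Newick or
  NEXUS reproduces them.
- `rvalue_accuracy` reports per-branch correlations between signed
  R-values and true changes without asserting a fixed threshold; the
  observed medians are well below 1, consistent with R-values being
  dominated by noise, but the exact distribution is tree-specific.
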