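# Methods

This note records the model, the conventions and the design choices behind
`nucfuse`, including the places where the underlying method is genuinely
open to interpretation and what this implementation chose.

## Representations

**Alphabet.** The 20 native amino acids are indexed 1..20 by alphabetical
one-letter code (A, C, D, …, Y). PSI-BLAST ASCII matrices arrive in the
order A, R, N, D, …, V and are permuted into the canonical order on read.
Positions in error messages are 1-based.

**DipC (420D).** Positions 1–20 hold residue frequencies `aa_i/L`;
positions 21–420 hold ordered-dipeptide frequencies `cr_i/(L−1)` with pair
(a, b) at `20 + 20·(index(a)−1) + index(b)`. Both blocks sum to 1. The
row-major pair layout is a fixed, documented bijection; any other fixed
layout would be equivalent. Sequences with L < 2 are rejected.

**PseAAC (20+2λ D).** The amphiphilic formulation: for tiers k = 1..λ
(default λ = 10), the two correlation factors are means over residue pairs
k apart of products of standardized scale values,

    τ_{2k−1} = (1/(L−k)) Σ_i h1(res_i)·h1(res_{i+k}),   τ_{2k} analogous with h2,

interleaved hydrophobicity-first. The final vector is
`[f_1..f_20, w·τ_1..w·τ_{2λ}] / (Σf + w·Στ)` with weight w = 0.05, so all
components share one denominator and sum to 1. The shipped scales are a
Tanford-style hydrophobicity and the Hopp–Woods hydrophilicity, each
standardized to zero mean and unit (population) SD over the 20 residues;
both are configurable. Because the factors are products, not squared
differences, correlation components can in principle be negative for real
sequences; the normalization guarantees the sum, not the sign. Sequences
with L ≤ λ are rejected.

**Compressed PSSM (210D).** `M = PᵀP` for an L×20 score matrix P; the
210-vector is M's lower triangle in row-major order (element (i, j), i ≥ j,
at `i(i−1)/2 + j`, 1-based). M sums over positions, so the descriptor is
invariant to row permutations and independent of L. Scores are used as
read (raw log-odds); no normalization is applied before the product.

## Fusion and balance factors

The fused vector of a protein assigned to location i is
`V_i = [r_i·A, (1−r_i)·B]` with `r_i ∈ (0,1)`. Blocks are fused on their
natural scales by default. Note the scale asymmetry this implies: PᵀP
entries grow with L² while frequency blocks are ≤ 1, so the PSSM block
dominates the cosine geometry except for r very near 1. An optional
per-feature z-scoring of the raw blocks (fitted on training data only) is
available on `BalancedFusionKNN(zscore=True)` and makes the blocks
commensurable; it is off by default.

**Weighting unlabeled queries.** `r_i` is indexed by class, but a test
protein's class is unknown. Two modes are implemented:

* *candidate-class* (default everywhere a prediction is reported): when a
  query is scored against a training neighbour of class c, both vectors
  are fused with `r_c`, so each comparison happens inside that class's
  weighted space. This is label-free and well defined.
* *true-label*: every vector is fused with its own class's factor. This
  is only usable when labels are known and is provided as an
  optimization-time fitness variant (below).

## Balance-factor search

Fitness of a candidate R is `1 − overall success rate` of a stratified
K-fold CV (default K = 3 inside the search) of the fused cosine-KNN;
folds are drawn once per search and frozen, so fitness is a deterministic
function of R. Because only the fusion weights change between candidates,
the fitness closure precomputes the Gram matrices `A·Aᵀ` and `B·Bᵀ`; the
cosine of two vectors fused with factors (r_u, r_v) is the closed form
`(r_u r_v G_A + (1−r_u)(1−r_v) G_B) / (‖·‖‖·‖)`, making one fitness call an
O(N²) re-weighting with no re-encoding. A test verifies the closed form
against literal fuse-then-classify.

The search: (1) draw a random coordinate order; (2) start from r = 0.5
everywhere; (3) scan each coordinate over the grid 0, 0.01, …, 1
(endpoints clamped to (1e−6, 1−1e−6) to respect the open interval),
keeping the fitness-minimizing value (first grid point on ties) before
moving on; (4) repeat for all coordinates; (5) repeat the whole restart 50
times to form the GA's initial population. The GA uses size-2 tournament
selection, arithmetic crossover (rate 0.8), additive Gaussian mutation
(rate 0.1, sd 0.05) with reflection into the open interval, elitism 1, and
stops after 100 generations or 20 stalled ones. All randomness derives
from a single integer seed; identical seed + config + data give
bit-identical results.

### Identifiability of balance factors

Measured on the synthetic generator, per-class balance factors are only
*partially* identifiable, for reasons intrinsic to the method rather than
to the optimizer:

* With two classes, either block alone separates them (a class with no
  PSSM shift is still recognizable in PSSM space by the *absence* of a
  shift), so the CV fitness is nearly flat in R and the optimum is
  arbitrary.
* Under candidate-class weighting the optima are interior (≈ 0.4–0.6):
  raising `r_c` rescales similarities toward class c for *all* queries,
  so each factor balances recall of its own class against attracting
  impostors.
* Under true-label weighting, extreme factors make classes living in
  different blocks mutually near-orthogonal, so optima land near the ends
  of (0,1) — but any assignment giving each class a private subspace
  scores equally well, because the quadratic compression `M = PᵀP` gives
  even a no-signal class a self-coherent direction once it is alone in a
  block. In a four-class design with two composition-twin and two
  PSSM-twin classes, the optimizer reliably ranks composition classes
  above PSSM classes in r (directional recovery, asserted by a test), but
  one twin can "park" in the other block, so exact recovery of every
  factor is not guaranteed.

This also offers a parsimonious explanation for optimized factors
clustering near 0 and 1 in practice: under label-dependent fitness
evaluation, block-orthogonal assignments are strong attractors.

## Discriminant projection

`S_W` and `S_B` follow the standard within/between-class scatter
definitions (class means weighted by class size; their sum equals the
total scatter, asserted by a test). Components solve
`S_B w = λ (S_W + ridge·I) w` via the symmetric-definite eigensolver;
`ridge = 1e−6 · trace(S_W)/d` by default, since `S_W` is necessarily
singular when d (630 for DipPSSM) exceeds the sample count. The ridge
actually used is stored on the model. At most
`min(C−1, rank(S_B))` components are returned, ordered by descending
eigenvalue, each column's largest-magnitude entry made positive so
serialized models are reproducible. `ridge_policy="off"` raises on a
singular `S_W` instead.

## Classification and evaluation

Cosine similarity `cos(u,v) = u·v/(‖u‖‖v‖)` ranks neighbours descending;
no distance conversion is needed. Vote ties break by (1) larger summed
similarity within the tied classes, (2) smaller class code; exact
similarity ties at the k-boundary go to the smaller training index. Zero
vectors are rejected at fit and predict time. The neighbourhood size is
selected by scanning k = 1..10 for the highest mean overall success rate,
as an outer loop in the evaluator.

Stratified K-fold partitions deal each class's shuffled members to the
least-filled folds, so per-class counts differ by at most one across
folds; classes smaller than K warn and stratify best-effort. The default
protocol is 10-fold; `repeats` controls averaging over independent
partitions (5 by default for speed; 50 matches the heavier convention for
final runs). `K = N` coincides with the jackknife, which is implemented
separately, is seed-independent, and is asserted equal to K = N folding.
All trainable stages — optional z-scoring, the discriminant projection,
the KNN store — are fitted on training folds only.

Metrics are one-vs-rest per location: SE = TP/(TP+FN) (identical to the
per-location success rate on pooled predictions), SP = TN/(TN+FP),
ACC = (TP+TN)/total, and MCC with the convention MCC = 0 when its
denominator vanishes. The overall success rate is `Σ TP(i) / N`.

## Synthetic data generator

Each class c draws a residue-frequency profile
`softmax(s_c · γ · z_c)` (z_c standard normal per residue, γ =
`composition_concentration`, s_c = `signal_split[c]`) and a PSSM column
shift `(1−s_c) · δ · d_c` (δ = `pssm_profile_shift`); sequences are i.i.d.
draws from the profile with lengths uniform in `length_range`, and each
PSSM row is shared base profile + class shift + Gaussian noise
(`pssm_noise_sd`), rounded and clipped to [−16, 13] to mimic log-odds
output. Class effects are ANOVA-centered: deviations are centered across
the classes that carry them (skipped when fewer than two do), so the base
profile is the grand mean and "no deviation" is the centroid of the class
cloud rather than a signature. Everything is a deterministic function of
the seed, and `write_fixture` emits exactly the text formats the readers
consume.

Defaults (3 classes × 10 proteins, lengths 30–80, γ = 1.0, δ = 3.0, noise
sd 1.0, s = 0.5 everywhere) produce clearly separated classes — fused CV
success ≥ 0.9 — which is the regime the qualitative pipeline tests assume.
What the generator does *not* emulate: real residue dependencies along the
chain, alignment-derived correlations between a sequence and its own
PSSM (blocks are generated independently given the class), and the heavy
class-size imbalance of curated localization datasets. Tests passing on
this generator therefore validate the machinery and its contracts, not
biological attainable accuracy.

## Problem sizes used in checks

The automated checks run at desk scale on one CPU: datasets of 18–60
proteins, 3–4 classes, searches with 4–50 restarts and 10–40 generations,
and 5 CV repeats. These sizes were chosen so the full suite completes in
well under a minute while still exercising every code path; the
module-level defaults (50 restarts, 100 generations, 10-fold CV) match the
method's standard operating point.

## Known limitations

* The PseAAC scales and weight w follow the classical convention; the
  exact tables behind any given third-party PseAAC service may differ, so
  numerical vectors are comparable only within this package.
* Raw-scale fusion lets the PSSM block dominate cosine geometry (above);
  enable `zscore=True` when the composition block should matter at
  moderate r.
* Balance factors are only partially identifiable (above); treat
  optimized R as a performance device, not as an interpretable measure of
  block importance per class.
* Reading PSI-BLAST output assumes the standard ASCII layout with 40
  integer columns; other profile formats must be converted to the
  tsv-matrix dialect.
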