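# Methods

## Data model

A connectivity graph is simple, undirected and edge-weighted over a fixed,
ordered node set; the collection property that everything rests on is the
fixed-cardinality vertex sequence (FCVS): every graph has the same node
count and a one-to-one node correspondence given by the shared label
ordering. A graph is therefore identified with its symmetric adjacency
matrix (zero diagonal; absent edges are exact 0). On ingestion, matrices
asymmetric beyond 1e-9 are rejected (this guards against truncated files),
matrices within tolerance are exactly symmetrized as (A + Aᵀ)/2, and
nonzero diagonals (correlation matrices carry 1s) are forced to 0.
Structural weights must be nonnegative; functional weights lie in [−1, 1]
before thresholding.

Functional weights must be similarities for the kernel machinery, so
negative correlations are zeroed (threshold 0 by default; configurable up
to 0.5 for sensitivity analyses — the qualitative conclusions are expected
to be threshold-stable, and the transform below depends only on ranks).
Group-average matrices use the arithmetic mean for structural counts and
Fisher z-averaging (atanh → mean → tanh, with |r| clipped at 1 − 1e-7
because atanh diverges at ±1) for correlations.

## Kernel two-sample test

The direct connection embedding unfolds the upper triangle row-major into a
vector of length l(l−1)/2; it is bijective on FCVS graphs, so the Gaussian
kernel on embeddings is a characteristic kernel on the graphs themselves,
and MMD = 0 iff the two group distributions coincide. The unbiased
estimator MMD²ᵤ is used throughout; it can legitimately be negative and is
never truncated at zero.

**Bandwidth.** σ is the median of all pairwise embedded distances of the
dataset at hand (a mean option exists). The heuristic uses no class labels,
so computing it once from the full dataset introduces no leakage into the
permutation test; it is likewise held fixed across permutations, which
keeps the permuted statistics exchangeable with the observed one and avoids
an O(T) recomputation.

**Permutation null.** T label shuffles of the pooled sample, preserving
group sizes, drawn independently per iteration (pure Monte Carlo — the
identity permutation is not forced into the null sample). The p-value is
the fraction of null values ≥ the observed statistic, with zero exceedances
reported as 1/T; comparisons use exact float ≥ with no jitter. Internally
the kernel matrix is computed once and only the group mask moves: for a
permuted mask z the three kernel sums are recovered from zᵀKz and zᵀK1, so
T iterations cost O(T·N²) with no Python loop. Monte-Carlo permutation
p-values under the null satisfy P(p ≤ k/T) = (k+1)/(T+1), i.e., uniform up
to O(1/T) discreteness — the calibration tests bear this out.

## Common representation space and MMD²_SF

Structural and functional MMD values are not comparable on raw weights
because the two weight distributions differ in nature. Each modality is
therefore rank-transformed through its own pooled empirical CDF: all
nonzero upper-triangle weights of all graphs of that modality (both
classes; ~l²·n values, so the ECDF is well resolved even for few subjects)
form the pool Ω, and each present edge's weight ω is replaced by
F̂(ω) = |{v ∈ Ω : v ≤ ω}| / |Ω| (strict ≤ counting; ties get the upper
step, no midranks). Only nonzero weights enter Ω and zeros stay zero, so
graph sparsity is preserved and density differences between modalities do
not leak into the weight distribution. The transform depends on ranks only:
any strictly increasing rescaling of a modality's raw weights leaves its
transformed dataset bit-identical (tested), and on all-distinct weights the
pooled transformed values are exactly {1/N, …, N/N}.

MMD²_S and MMD²_F are the MMD²ᵤ values of the two transformed datasets,
computed with **one shared σ** taken from the pairwise distances of the
pooled transformed embeddings of both modalities. The sharing is a design
choice the construction needs: with per-modality bandwidths the two
statistics would again live on different scales and their difference would
be meaningless (a `per_modality_sigma` flag exists for sensitivity
analysis only).

The differential statistic is MMD²_SF = MMD²_S − MMD²_F, tested one-sided
(structural more affected) by default; the two-sided option doubles the
smaller tail. Its null distribution permutes class labels independently
within each modality — structural and functional graphs may come from
different subjects, so no pairing is assumed or used — preserving all four
group sizes. The ECDFs and σ ignore class labels, so they are
permutation-invariant and built once. For visual comparison of MMD²_S and
MMD²_F against one scale, `shared_null_reference` draws two-group splits
from the pooled transformed graphs of both modalities, with split sizes
alternating between the structural (8+8) and functional (10+10) designs
across iterations; it is explicitly visualization-only and feeds no
p-value.

## Classification baseline

Leave-one-subject-out cross-validation of an SVM on the precomputed graph
kernel (regularization C = 1 by default; not tuned). Within each fold σ is
recomputed from the N−1 training embeddings only, so the held-out subject
never influences the kernel scale. Above-chance accuracy is tested with the
exact binomial tail Pr(i ≤ r | p = 1/2) over the misclassification count r,
computed with exact integer binomial coefficients.

Known limitation: under the null, LOSO with balanced classes is
*anti*-biased — the held-out subject's class is always the training
minority, so a max-margin classifier tends to predict the other class and
null accuracies land near 0, not 0.5. The binomial p-values remain
non-significant (the test is one-sided toward high accuracy), so no false
positives arise, but accuracy itself is a poor effect-size measure near
chance; this is one reason the MMD route, which needs no data splitting, is
the primary method. The same artifact makes the baseline insensitive to
weak effects (at the default mild functional effect the SVM can score below
chance while the KTST still detects the group difference).

## Synthetic study generator

The generator emulates a two-hemisphere mouse connectome study and is the
package's calibration instrument; its defaults are the study design all
shipped calibration and power numbers refer to:

| parameter | default | meaning |
|---|---|---|
| `l` | 50 | brain regions, split into two 25-node hemispheres |
| `n_per_class_structural` | 8 | subjects per class, structural |
| `n_per_class_functional` | 10 | subjects per class, functional |
| `delta_s` | 0.6 | fraction of inter-hemispheric structural weight removed in the condition class |
| `delta_f` | 0.1 | same for inter-hemispheric functional covariance |
| `structural_noise` | 0.3 | log-normal CV of per-edge streamline-count noise (~30% inter-subject variability) |
| `functional_timepoints` | 360 | resting-state samples behind each correlation matrix |

The structural template has rounded log-normal streamline counts: dense
within-hemisphere connections (median ~50), a strong homotopic
inter-hemispheric bundle (median ~200, the "callosal" edges), and a sparse
10% of other inter-hemispheric pairs (median ~20). Subjects are
multiplicative mean-one log-normal perturbations of the template, rounded
to integer counts. The functional latent covariance mirrors the block
structure (within-hemisphere 0.3, homotopic 0.6, other inter-hemispheric
0.1, unit diagonal, diagonal-loaded to positive definiteness); each
subject's graph is the sample Pearson correlation matrix of 360 Gaussian
draws from it, negatives thresholded — finite-sample correlation noise
thereby has realistic correlation-matrix geometry rather than being pasted
on additively. The condition class scales inter-hemispheric structural
weights by 1 − δ_S and inter-hemispheric covariance by 1 − δ_F before
subject noise; δ_S = 1 reproduces full callosal agenesis, δ_S = δ_F = 0 is
an exact null. The effect deliberately targets inter-hemispheric edges so
power simulations stress the same structure the method is aimed at.

What the generator does **not** emulate: tractography error structure
(false-positive streamlines, length biases), BOLD autocorrelation and
physiological confounds, hemispheric asymmetries, inter-site variation, or
subject-level structure–function coupling. Passing calibration here shows
the statistics are correct and well calibrated under a realistic noise
model, not that any particular real dataset will behave identically.

## Numerical choices

- Kernel matrices are computed from squared distances in double precision,
  exactly symmetrized, diagonal set to 1; no approximations.
- Permutation engine: `numpy.random.Generator.permuted` on a tiled mask;
  all randomness flows from one seeded generator per test invocation, and
  the seed is recorded in every result object, so results are reproducible
  bit-for-bit.
- Degenerate inputs fail loudly: all-identical embeddings (median distance
  0) ask the caller for an explicit σ; classes with fewer than two members
  are rejected (the unbiased estimator divides by m(m−1)); an empty weight
  pool rejects ECDF construction.
- Replicated-study seeds are spawned from one root via
  `numpy.random.SeedSequence`, keeping replicates independent and the whole
  report a function of a single integer.

## Problem sizes in the shipped checks

The test suite calibrates type-I error on 500 zero-effect replicates
(T = 1000 permutations per test), checks estimator unbiasedness on 2000
replicates, and measures power/sign recovery on 200 replicates per effect
direction, all at the default 50-node design; the acceptance script uses
200 replicates per run and T = 100 000 for the single-study tests. These
sizes give Monte-Carlo standard errors of about 0.01 on rejection rates
while keeping the default suite fast on a single CPU.
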