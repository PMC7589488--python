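# Methods

## Mutation typing

An SNV at position `p` is typed by fetching the symmetric genomic
window `[p − w, p + w]` with `w = max(n_up, n_down)` from the
reference, verifying that the central base equals the reported
reference allele, and — when that base is a purine — reverse-
complementing the *entire window* together with the alternate allele
before slicing `n_up` bases 5′ and `n_down` bases 3′ of the central
base. Orienting the full window first is the only self-consistent way
to extend the context asymmetrically (for the tetra scheme, `n_up = 2`,
the extra 5′ base of a purine-strand variant comes from the genomic 3′
side). Typing is total rather than throwing: windows that overlap a
chromosome end, contain `N`, or disagree with the file's reference
allele are rejected with a tallied reason, so the invariant
`matrix total + rejections = input variants` holds exactly. The
reference genome is authoritative — a ref-mismatch drops the variant,
never rewrites it.

Labels are canonical tuples `(5′ flank, ref, alt, 3′ flank)` with two
renderers: bracket style `A[C>T]G` (default; the convention of COSMIC
signature files) and pipe style `A|C > T|G`. Dictionaries enumerate the
`4^(n_up+n_down) × 6` labels with substitution classes in the fixed
order C>A, C>G, C>T, T>A, T>C, T>G and contexts lexicographic within
class. Chromosome-name reconciliation (`chr` prefix stripping) is an
explicit opt-in; unmatched chromosomes are an error rather than being
silently coerced. Duplicate variant rows are counted once per
occurrence (tumor-portion tables may legitimately repeat loci).

## Bootstrapped NMF extraction

One extraction = `num_iterations` repetitions of (multinomial bootstrap
→ NMF), followed by clustering of all pooled signature columns.

* **Bootstrap.** Column `j` is redrawn from
  `Multinomial(N_j, V[:, j] / N_j)` with `N_j` the rounded column
  total; totals are preserved exactly and zero columns are fixed points.
* **Brunet updates** minimize the KL divergence `D(V ‖ WH)` with the
  standard multiplicative updates (H then W each sweep), denominators
  floored at machine epsilon. The divergence is non-increasing at every
  sweep.
* **Lin updates** minimize `½‖V − WH‖²_F` with modified multiplicative
  steps: variables at zero whose gradient is negative are lifted to a
  floor `σ = 1e-9` before the step and denominators are shifted by
  `δ = 1e-12`, which removes zero-locking and makes the decrease — and
  convergence to a stationary point — provable. σ and δ are fixed
  numerical guards, not tuning knobs.
* **Stopping.** Both algorithms stop when the relative objective change
  per sweep drops below `inner_tol` (default 1e-9) or after
  `max_inner_updates` (default 10,000) sweeps.
* **Clustering.** All `num_iterations × k` signature columns are pooled
  and partitioned into `k` clusters by k-means-style iteration under
  cosine distance: restart 0 is seeded with the columns of the first
  iteration, nine further restarts with random pooled vectors; each
  restart runs to an assignment fixpoint (cap 500 rounds, empty
  clusters re-seeded with the worst-fit vector) and the restart with
  the smallest within-cluster cosine-distance sum wins. Centroids are
  member means renormalized to column sum 1 and are ordered by
  descending cluster size ("total attribution" is not observable before
  exposures exist; membership count is the deterministic proxy used
  here). Silhouette widths use the classical
  `s(i) = (b−a)/max(a,b)` formula on the pooled cosine-distance matrix,
  with `s = 0` for singleton clusters.
* **Exposures.** The final activities are recomputed by non-negative
  least squares against the *original* (un-normalized, un-bootstrapped)
  counts, so they are in mutation units per sample regardless of the
  normalization used during extraction.
* **Determinism.** Per-iteration RNG substreams are spawned from the
  master seed by iteration index (`numpy` `SeedSequence.spawn`), so the
  result is bitwise-identical at any thread count and any execution
  order. Worker parallelism uses threads (the heavy work is numpy,
  which releases the GIL).

`approach="freq"` divides each sample column by its total and
multiplies by the rounded *median* of the original totals: all samples
then carry equal weight while the matrix stays count-like, which keeps
the multinomial bootstrap meaningful. The median (rather than the mean)
keeps the constant insensitive to the very hyper-mutators the
normalization is meant to defuse. `weak_type_threshold` (default 0 =
off) sorts mutation-type rows ascending by total and sets rows aside
while their cumulative share of the grand total stays below the
threshold; removed rows are re-inserted as zeros in the final
signatures.

## Fast combinatorial NNLS

Exposures against known signatures solve `min ‖V − WH‖_F, H ≥ 0` with
the Van Benthem–Keenan combinatorial active-set strategy: `WᵀW` and
`WᵀV` are formed once; samples sharing a passive set are grouped and
their normal equations solved together; infeasible iterates step back
toward the last feasible point (zeroing one variable per step); and
optimality is declared per sample when every active-set gradient
component is ≤ 1e-10. Exchange rounds are capped at `30·k`, after which
the best feasible iterate is returned with a warning; singular
passive-set subsystems fall back to the pseudo-inverse. The
scipy Lawson–Hanson solver is used in the test suite as an independent
per-column oracle; agreement is at the 1e-14 level on random problems.

## Matching and the Monte-Carlo correlation null

Signatures are compared by cosine distance `1 − cos∠`; a match is
called below 0.2 by default (an explicit threshold where visual heatmap
inspection would otherwise decide). Relative activities (exposures
normalized per sample) live on the simplex, so pairwise correlations
are negatively biased by closure. The null simulates activity matrices
whose per-signature mean and standard deviation track the observed
ones (normal draws truncated at zero by clipping — the
minimal-assumption reading), renormalizes each sample to sum 1,
computes all pairwise Spearman coefficients (mid-rank ties) and keeps
each simulation's minimum; the p-value is the fraction of simulated
minima at or below the observed minimum. Simulated activities are
renormalized per genome because observed relative activities are; this
is flagged in run metadata. With `k = 2` the two relative activities
are deterministic complements (Spearman ≡ −1) and the procedure
degenerates; a warning is emitted.

## Synthetic data: what it emulates and what it does not

The generator plants ground truth at three levels: a uniform-random
multi-chromosome genome (redrawn until every pyrimidine-oriented
context of the requested shape occurs, so any mutation type can be
placed); variant sets drawn per sample from signature mixtures and
placed uniformly among genome positions carrying the drawn context (on
either strand, with alleles complemented when the genome presents the
purine strand); and count matrices `V = round(WH)` or multinomial draws
around `WH`.

Planted signatures are random positive blocks over *disjoint*
mutation-type subsets (pairwise cosine distance 1), so recovery
thresholds are unambiguous. Planted exposures are Dirichlet(0.5)
mixture weights scaled by a uniform 400–600 per-sample burden. The
Dirichlet concentration below 1 matters beyond realism: tumor cohorts
show strong sample-to-sample variation in which process dominates, and
it is exactly this variation that makes the factorization
identifiable. If instead every signature were active at a similar
level in every sample, `V = WH` would admit a continuum of equally
good factor pairs (`W·A`, `A⁻¹H` for mixing matrices `A` near the
identity stays non-negative) and *no* method could single out the
planted factors — we verified empirically that in that regime the KL
optimum sits at cosine distance 0.1–0.3 from the planted signatures
while fitting the data better than they do.

What the generator does **not** emulate: genome-scale context
composition (toy genomes are uniform, real genomes are not),
replication-timing or expression covariates of regional mutation rate,
sequencing artifacts, subclonality, and correlated signature
activities. Passing recovery tests therefore demonstrates correctness
of the algorithms under the stated sampling model, not performance on
any particular tumor cohort.

## Problem sizes

The bundled benchmark scenarios use 96 mutation types, 40 samples,
~500 mutations per sample, k = 3 (plus one 20× hyper-mutator sample
driven by a fourth disjoint signature in the normalization scenario),
and 30 bootstrap iterations; the tetra scenario types the same ~20,000
variants at 384 types. Production analyses should raise
`num_iterations` to several hundred; every reported quantity here is
computed at the sizes above. The Monte-Carlo calibration check uses
100 repetitions of nsim = 500 with 4 signatures × 60 genomes.

## Known limitations

* `k` is user-chosen; no automatic model-order selection is provided.
* Only single-nucleotide substitution types are supported (no indel or
  doublet signatures).
* The VCF reader interprets the five standard body columns only; it
  does not parse genotypes, INFO fields, or structural records, and it
  deliberately tolerates header-less bodies.
* freq normalization assumes every sample has at least one mutation;
  all-zero samples are dropped with a warning before extraction.
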