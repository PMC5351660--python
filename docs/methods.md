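# Methods

## The REO model

Within one sample, rank all genes by expression in ascending order
(rank 1 = lowest; exact ties share the midrank). The relative expression
ordering (REO) of a gene pair (i, j) is the sign of expr_i − expr_j, a
two-outcome event. Because a REO depends only on the within-sample
ordering, it is invariant under any strictly increasing transform of
that sample's values — the property that makes REO-based statistics
immune to scaling, normalisation choices and, to a large degree, batch
effects and partial RNA degradation.

### Consistency score

For a matched FF/FFPE sample pair over an identical gene list, the
consistency score is k/n: among the n evaluable gene pairs, the number k
whose ordering sign agrees (and is nonzero) in both samples. Two
refinements:

- **Tie policy.** Pairs with exactly equal expression in either sample
  are excluded from both k and n and reported separately. The REO is
  defined as a two-outcome event, and zeros/ties are common in RNA-seq;
  forcing an arbitrary direction would inject noise into both the
  numerator and denominator.
- **Closest-pair exclusion.** Pairs with the smallest FF-sample rank
  difference R_ij = |R_i − R_j| are the ones whose ordering is most
  easily flipped by measurement noise. At exclusion fraction f, exactly
  floor(f · C(n,2)) pairs with the smallest R_ij in the FF sample are
  removed before scoring; ties at the cut are broken by lexicographic
  gene-ID pair so the excluded set is deterministic. The exclusion count
  is computed per FF sample (closeness is an FF-side property; the FFPE
  side is the degraded measurement being judged).

### Stable-pair mining

Over an accumulated cohort, a pair is highly stable when one direction
holds in at least a threshold fraction (default 0.99) of samples, ties
counting toward neither direction with the full cohort size as
denominator (the conservative reading). The threshold comparison is ≥
and is a config knob; the reversal-pair comparisons below are strict (>)
— both conventions are surfaced rather than hidden. When cohorts from
several sources are accumulated, gene lists are intersected (union with
missingness would make support fractions incomparable across pairs).

### Reversal-pair signatures and avgRij

A candidate signature pair must show one direction in more than 85% of
class-0 samples and the opposite direction in more than 85% of class-1
samples (strict comparisons, ties to neither side). Candidates are
ranked by

    avgRij = mean[Rij(class0)] * mean[Rij(class1)],

the product of class-wise mean absolute rank differences, computed on
whole-sample ranks over the full shared gene list (not over candidate
genes only — Rij is defined on the whole transcriptome's ranks). The
product is used directly: ranking by the product is identical to ranking
by its geometric mean, and only the ranking matters for selection. The
top k pairs are kept, k odd so the majority vote cannot deadlock; score
ties are broken lexicographically.

Enumerating candidates in both orientations and swapping the class
arguments are equivalent (antisymmetry), so the implementation fixes the
orientation by the class-0 majority without loss.

### Majority-vote classification

Each signature pair votes class 0 if its class-0 ordering holds
strictly, class 1 if the reverse holds strictly, and abstains (tie)
otherwise. The label is class 0 iff class-0 votes exceed k/2; tied votes
therefore fall to class 1 — the literal "otherwise" branch of the rule.
Sensitivity is reported per dataset per class (fraction of known-label
samples assigned that label), not pooled accuracy.

### Rank Product differential expression

For each same-patient pair, genes are ranked by fold change
(FFPE + c)/(FF + c), pseudocount c = 1.0 by default on linear-scale
values to absorb zeros (configurable). RP_up is the geometric mean
across pairs of the descending-order ranks (rank 1 = most up-regulated);
RP_down the ascending analogue. This is the one-sample (paired-design)
Rank Product variant. Significance: gene labels are permuted within each
pair — implemented by permuting each pair's observed rank vector, which
preserves tie structure — for n_perm ≥ 100 permutations. With c_g the
count of pooled null RP values at or below gene g's observed RP:

- p_g = (c_g + 1) / (n_perm · n_genes + 1) (add-one permutation
  convention);
- FDR_g = (c_g / n_perm) / rank(g), the Rank Product literature's
  expected-false-positives estimate, monotonized along the RP ordering
  and clipped to [0, 1]. Benjamini–Hochberg is deliberately not used:
  the permutation-based estimate is the convention that accompanies the
  RP statistic.

Because RP is computed on within-pair fold-change ranks, it is invariant
under transformations that preserve each pair's fold-change ordering
across genes — per-sample scaling (library size) and power transforms.
It is *not* invariant under arbitrary monotone transforms of expression
(an additive shift changes which gene has the larger ratio), which is
the honest scope of its "rank-based" robustness; the invariance tests
assert exactly the scale/power form.

The cross-tissue direction test takes the genes called differentially
expressed in every tissue, counts those with the identical deregulation
direction (sign of mean log2 fold change) in all tissues, and tests that
count against chance with a two-sided exact binomial at p = 0.5.

## Synthetic data generator

The generator produces every input the pipeline needs, emulating the
structure of paired FF/FFPE studies:

- **Expression**: value = exp(mu_g + eps), mu_g ~ Uniform(−4.5, +4.5)
  in natural log, eps ~ N(0, 0.4²). The uniform spread keeps rank
  density constant across the expression range (an implanted log-effect
  maps to the same rank displacement anywhere), and ±4.5 nats ≈ a 4
  orders-of-magnitude dynamic range, typical of expression data.
- **Degradation**: FFPE value = exp(log FF + delta_g + eta),
  delta_g ~ N(0, 0.45²) drawn once per gene universe and shared across
  any cohort built on it — degradation propensity is a property of the
  transcript, not the tissue — plus FFPE measurement noise
  eta ~ N(0, 0.3²). With sd 0.45, ~12% of genes get |delta_g| ≥ ln 2,
  i.e. a ≥ 2-fold systematic shift (the "thousands of genes out of
  20,000" regime), while the expected pair-flip probability leaves mean
  REO consistency near 90% — the two phenomena the model must exhibit
  simultaneously, independently tunable because shift and noise are
  separate terms. Storage time optionally inflates the noise linearly
  (sd × (1 + slope · years)), allowing qualitative storage-time
  experiments.
- **Two-phenotype cohorts**: all genes share class-invariant means
  except the implanted reversal pairs. Pair (a, b) at centre c with
  effect delta gets class-0 means c ± delta/2 (a high) and the mirror
  image in class 1. Default: five pairs, delta = 1.5, centres spaced
  1.2 · delta apart around the middle of the range. The spacing is an
  identifiability argument, not a tuning knob: an implanted gene sweeps
  only [c − delta/2, c + delta/2] between classes, so (i) centres
  further apart than delta make cross-implant reversals impossible, and
  (ii) any incidental reversal against a background gene inside the
  interval splits the span, giving it at most (delta/2)² of rank-diff
  product against the implant's delta² — a 4× avgRij margin under
  constant rank density. The implanted pairs are therefore provably the
  top-scoring reversal pairs up to sampling noise. delta = 1.5 keeps
  each pair's ordering nearly deterministic within a class
  (flip sd per sample ≈ 0.57) yet small relative to the expression
  range.
- **Reproducibility**: all draws flow from one integer seed through
  named PCG64 substreams; identical config ⇒ bit-identical matrices.
  `noise_seed` reseeds only sampling noise, producing fresh "patients"
  on the same gene universe, degradation profile and implanted effects —
  how an independent validation cohort relates to its training cohort.

What the generator does **not** model: count noise (values are
log-normal, not negative binomial), poly-A fragmentation chemistry or
RIN scores, correlated gene modules, class-imbalanced or impure samples,
and platform-specific probe artifacts. Passing tests therefore
demonstrate the correctness and internal robustness of the REO
machinery under its stated assumptions, not clinical performance on
real cohorts.

## Numerical and design choices

- Ranks use scipy's midrank convention; ordering comparisons use value
  signs, not rank differences — they agree except at ties, which are
  excluded anyway.
- The exclusion count is floor(f · C(n,2)) with a 1e-9 guard against
  float artifacts (0.2 × 10 pairs must exclude exactly 2).
- All C(n,2) pair kernels stream in rectangular blocks (default 2048
  genes per side), so auxiliary memory is O(block² · n_samples) rather
  than O(n_genes²) — a 20,000-gene cohort (~2×10⁸ pairs) never
  materializes its pair list. The closest-pair exclusion works from an
  exact histogram of doubled rank differences (at most 2n integer bins),
  so the cut threshold is found without sorting all pairs.
- Probe sets mapping to zero or several genes are dropped; several
  probes on one gene average arithmetically; collapsing precedes
  ranking.
- Input values are taken as given (linear scale, nonnegative, no
  missing values); the all-zero gene filter is defined jointly over a
  paired cohort, with a per-matrix variant for single cohorts.

## Problem sizes

The test suite and the acceptance script run at desk scale, chosen so
every stage's statistical behaviour is visible while a full run stays in
tens of seconds: 2,000 genes; 12 same-patient FF/FFPE pairs; a 60-sample
accumulated normal cohort; 80+80 training and 100+100 validation samples
per class; 100–200 permutations for Rank Product. Oracle-equivalence
checks run at ≤ 50 genes where exhaustive enumeration is exact.

## Known limitations

- Whole-cohort stable-pair sets at the default threshold are large
  (>10⁶ pairs at 2,000 genes); the TSV export is correspondingly large.
- The permutation FDR is the RP convention's expected-FP ratio; it is an
  estimate of the proportion of false positives, not a strict FDR
  control procedure.
- Real archival cohorts violate generator assumptions in ways listed
  above; the optional real-data path (plain TSV in, same commands)
  exists precisely so the pipeline can be checked against downloaded
  cohorts when those are available.
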