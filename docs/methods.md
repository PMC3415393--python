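# Methods

`badgerqc` detects, diagnoses and corrects sample mix-ups between matched
expression and genotyping arrays in large (typically cancer) population
studies, using cis-eQTLs as a many-locus identity fingerprint. This note
records the statistical model, the tunable parameters, the design choices
made where the design was genuinely open, and what the bundled simulator
does and does not emulate.

## The identity model

**Genotype prediction.** For each eQTL pair *i* (an expression probe and a
SNP whose B-allele count drives its intensity), three one-dimensional
expression densities f_AA, f_AB, f_BB are estimated from trusted matched
arrays by Gaussian-kernel density estimation. Given the log2 intensity
e_ij of probe *i* on expression array *j*, the posterior over genotype
classes under equal priors is

    P(g | e_ij) = f_g(e_ij) / Σ_g' f_g'(e_ij),

and the predicted B-allele count is the posterior expectation
p_ij = P(AB|e) + 2·P(BB|e) ∈ [0, 2]. Classes with fewer than
`min_class_count` (default 3) training arrays are unavailable; the
posterior renormalises over the available classes. As the expression
signal fades all class densities approach each other and p tends to 1
(the heterozygote), which under a squared-error score under-penalises
exactly the error mode most likely to be innocent: het/hom genotype
miscalls. This is the reason equal priors are kept rather than
allele-frequency priors (available as future work, deliberately off by
default).

**Scoring.** With observed B-allele counts o_ik on genotype array *k*,
the score between arrays *j* and *k* is

    B_jk = (I / I_jk) · Σ_{i: both observed} (p_ij − o_ik)²,

where I is the size of the eQTL set and I_jk the number of jointly
non-missing terms: a missing-rescaled sum that reduces to the plain sum
of squared differences when nothing is missing. Cells with I_jk = 0 are
missing and excluded from ranking. Matching works from expression arrays
towards genotype arrays (duplicates are far easier to identify and
collapse on the genotype side): within each expression array's row, the
rank matrix BR assigns rank 1 to the smallest score, ties sharing the
minimum rank so that exact replicate genotype arrays are all rank 1. A
correctly mapped array should have its intended partner at rank 1.

**Confidence.** For each expression array the sorted scores
B_(1) ≤ … ≤ B_(m) give a minimum score (is there *any* matching DNA in
the study?) and a gap statistic Δ = B_(g+1) − B_(1), where g (default 1)
is the largest number of replicate genotype arrays expected; the gap is
measured past any legitimate block of replicates.

**Refinement.** eQTLs are selected for association strength, not
predictive power, so the set is pruned by the discrepancy statistic
d_i = mean over well-matched array pairs of (p_ij − o_ij)². Pairs with
d_i above a cutoff T are dropped and scores recomputed over the retained
index (algebraically identical to subtracting the removed terms; the
recomputation is used because it is bitwise-reproducible and equally
cheap vectorised). "Well-matched" means reciprocal rank-1 intended pairs
under the current scores. T is a config parameter; by default it is set
automatically at the midpoint of the largest gap in the sorted d_i, with
two guards chosen a priori: only gaps whose upper edge lies above the
median d_i are candidates (the cutoff separates a poorly performing tail,
never the heart of the set), and the winning gap must be at least 10
times the mean inter-point gap, else no pruning happens. The 10×
prominence keeps the probability of splitting a homogeneous set around
10⁻³, while a genuine null cluster (mean squared residual near
2·maf·(1−maf) + (1−2·maf)² against a near-constant prediction of 1) sits
a ~30× gap above well-behaved pairs.

## eQTL discovery

Cis pairs are scanned over probes with `perfect` annotation against SNPs
on the same chromosome within 1 Mb (point-to-point distance; probes carry
a single anchor coordinate). The association test is the 1-d.f.
linear-trend F-test of log-expression on allele count, evaluated through
the F log-survival function so that −log10 p values far beyond the
retention threshold of 15 do not underflow. The extreme threshold is
intentional: the set serves identification, not biology, and at 10⁻¹⁵ the
expected number of false pairs is negligible at any realistic scan size.
Probes covering SNPs (cis-eQTL artefacts) are first-class signal here:
a hybridisation artefact is more robust across populations than a true
regulatory association.

KDE bandwidths follow Silverman's rule, 0.9·min(sd, IQR/1.34)·n^(−1/5),
floored at 0.05 log2 units so a degenerate (constant) class still yields
a finite density. The estimator is an exact Gaussian mixture over the
training points evaluated in log space (numerically safe in far tails,
exactly serialisable); tests cross-check it against an independent KDE
implementation.

## The iteration loop

`run_badger` repeats: refit densities on the trusted training set
(reinstating the full eQTL set), predict, score, rank, refine, propose
corrections from the evidence, apply those passing the acceptance policy.
Trust starts as the configured pilot (or, without one, every intended
match) and grows each iteration to the pilot plus all samples confirmed
as reciprocal rank-1 matches — densities sharpen as the map is cleaned.
The loop ends with a confirming iteration that accepts nothing and finds
the trusted set unchanged; a recurring correction set stops the loop with
an "unresolved" report (oscillation guard).

**Proposals.** Unresolved arrays go onto a bipartite graph (edge when
BR < `rank_threshold`, default 3; intended edges marked; DOT export
available). The rank-1 evidence induces a partial map ψ on samples whose
cycles are swap/cycle hypotheses (enumerated up to length 8) and whose
maximal chains — anchored by a high-min-score orphan expression array at
one end and an unclaimed genotype array at the other — are
slippage/chain hypotheses. When every chain step shifts exactly one
position of the pre-exclusion extraction sequence, the hypothesis is
emitted as slippage and the alien occupant of the leftover array is named
from the sequence — which is what makes dispensing-slip errors exactly
correctable, space-holders included. Pairs of 2-cycles that jointly reverse a contiguous block
of a stage sequence are merged into one correction so the entire error is
identified, not just its middle. Where plate provenance exists,
systematic transforms are tested wholesale per stage — 180° rotation,
row/column-order reversal (for a 12-well strip the latter is the BeadChip
strip reversal), plate swaps between plates of equal occupancy, ±1
sequence slippage — and reported when they strictly increase the number
of rank-1 intended matches; transforms outrank cycle decompositions of
the same arrays.

**Orphans and aliens.** An array with no counterpart shows two signatures
at once: its best score sits at the level of random non-matching pairs
(operationalised as exceeding both the 99th percentile of matched
min-scores and a quarter of the overall score median), and it lacks
reciprocity (its best match is somebody else's reciprocal partner). Both
are required before an array is treated as orphan/alien. Standalone
orphan/alien findings are report-only: un-pairing an array is
destructive, rests only on absence of evidence, and in practice warrants
human review or lab validation; within a sequence-consistent slippage
chain, however, orphan and alien moves are part of an accepted
correction.

**Acceptance policy.** Unattended runs need an automatic stand-in for the
human assessment a real study would apply between iterations. A
relabeling is accepted only if every re-paired (expression, genotype)
combination is reciprocal rank 1 *and* the expression array's Δ exceeds
the 99th percentile of the matched-pair min scores. The percentile form
(rather than a fixed multiple of the median) makes the gate
scale-adaptive: the margin a correction creates must be larger than any
score a genuinely matched array attains in this cohort, so coincidence is
ruled out on the cohort's own scale; a fixed multiple is too strict when
densities come from a modest pilot and too lax when they are sharp. Plate
transforms are accepted when they gain at least one rank-1 intended match
and every re-paired combination is rank 1. Accepted corrections are
attributed to the platform on which the affected samples were
processing-neighbours at some stage (adjacent sequence positions, or
orthogonally adjacent wells of one plate); neighbours on both or neither
platform yield "undetermined", in which case the relabeling is applied on
a configurable default platform (genotype) while the report keeps the
honest attribution.

## Plate-layout design

An 8×12 plate has 88 horizontal + 84 vertical = 172 orthogonally adjacent
well pairs (diagonals ignored). A switch of same-sex neighbours is
invisible to a sex check, so designs minimise same-sex pairs subject to
avoiding 180° rotational symmetry of the pattern *and* of its sex
inverse. The chequerboard attains the minimum (0) but is rotationally
self-symmetric; the blocked design (row blocks of sizes 1-2-2-2-1 with
alternating phase, adjacent columns complementary) has exactly 36
same-sex pairs, 3 per column, and no self-symmetry — though its inverse
equals its own rotation, so design and inverse should not be used
together. The permuted-columns family draws columns from four basic
patterns (the blocked phase vector, its complement, and a cyclic shift of
each; the phase vector is a palindrome, so plain reversals would
degenerate); the exact permutation is a constructor parameter.

For uniform random balanced (48/48) layouts, the expected number of
same-sex pairs is 172·(2·48·47)/(96·95) ≈ 85.09 (the per-pair probability
that two distinct wells share a sex). Monte-Carlo summaries report this
mean, and, for a batch of plates, the minimum pairwise number of
differing wells: since both layouts are balanced, a d-well difference is
explained by a minimum of d/2 simple switches (each switch fixes at most
two wells; a brute-force search over small plates confirms attainment).
With 100 random plates the central estimate of the closest-pair
difference is 30 wells (≈15 switches), so random layouts are mutually
distinguishable. Default simulation sizes: 10,000 layouts for the
same-sex mean, 200 replicates of 100 plates for the minimum-difference
median; both run in seconds.

## Quality metrics

P95 (and the P05 baseline) is the 95th (5th) percentile of an array's
log-intensities under the linear-interpolation definition (pinned because
scanner conventions differ); it is batch- and scanner-dependent, so only
relative use is advised. The signal-separation statistic is
(mean intensity rank of `perfect`-tier probes − mean rank of intergenic
probes) / number of ranked probes — ascending ranks, mean rank for ties.
Normalising by probe count makes the value platform-comparable and
confines it to (−1, 1); it is invariant under any strictly monotone
intensity transform. On a dead or empty array the residual
cross-hybridisation background inverts the ordering, so the statistic
goes substantially negative rather than to zero — useful for telling
"failed hybridisation" from "no sample". `quality_vs_minscore` reports
the Spearman association between a quality metric and the per-array
minimum score, plus flags for scheduled-empty arrays showing signal and
scheduled-sample arrays showing none.

## The synthetic cohort generator

The simulator produces exactly the statistical structure the method
assumes, with planted ground truth:

- **Genotypes.** Ancestral MAFs uniform on `maf_range` (default
  0.1–0.5); per-group allele frequencies by Balding–Nichols drift
  (Beta(p(1−F)/F, (1−p)(1−F)/F)); Hardy–Weinberg within group; optional
  parent–parent–child trios by Mendelian transmission.
- **Expression.** e = baseline + effect·(B count) + N(0, noise_sd) for
  true-eQTL probes (defaults: effect 1.0 log2 units, noise 0.3, a third
  of 150 probes with a true eQTL at n = 96 samples — an internal-pilot
  sized study with strong cis-artefact-like effects). The effect is
  zeroed in groups flagged `eqtl_active=False`, emulating associations
  that do not replicate across populations. Intergenic probes sit at a
  background baseline; a configurable fraction of eQTL probes is
  annotated as covering SNPs.
- **Tumour.** A heterozygous call collapses to 0 or 2 with probability
  loh_rate × cellularity (defaults 0.3 and Beta(5,2); these are
  placeholders for unreported real-world rates): the purer the tumour
  the more LOH survives into the call, and stromal contamination rescues
  heterozygous calls. Homozygous and missing calls are untouched.
- **Provenance.** Every sample carries extraction (pre-exclusion
  sequence, including excluded space-holders), genotyping-plate and
  expression-chip locations. Expression processing order is a seeded
  shuffle of the extraction order by default, reflecting the extra
  re-arrangement BeadChips undergo; this is what makes platform
  attribution informative.
- **Errors.** Neighbour swaps, k-cycles, block reversals, sequence
  slippage over a window of the pre-exclusion sequence, plate swaps, 180°
  plate rotations, duplicates, aliens, empty arrays — each returning the
  exact truth corrections, so restoration can be checked bit-for-bit.

What the generator does **not** emulate: intensity-level array physics,
probe-specific response curves, copy-number segment structure, batch
effects, sex chromosomes (sex is a layout label), genotype-calling error
beyond LOH collapse, and linkage disequilibrium between SNPs. Passing
tests therefore demonstrate the statistical machinery under the model's
own assumptions — strong eQTLs, independent markers, honest provenance —
not robustness to raw-data artefacts, which on real studies is handled
upstream (normalisation, genotype calling, annotation).

## Numerical choices and degenerate inputs

Missing values are NaN throughout; every operation defines behaviour on
missing explicitly (skipped terms with rescaling in scores, skipped
arrays in prediction, missing cells excluded from ranking). Posterior
evaluation runs in log space with log-sum-exp. Scores are clipped at 0
against negative floating-point residue of the vectorised expansion.
Rank ties take the minimum rank. Entirely missing arrays are reported as
`empty` and excluded. Genotype arrays with ≥99.5% concordance over ≥10
shared calls are collapsed as duplicates before ranking and reported.
All randomness flows from a single integer seed; generation is
bit-reproducible.

## Problem sizes used in the checks

The bundled verification runs use: 96-sample clean cohorts (50 eQTLs) for
rank-diagonal checks; 192-sample cohorts with a 48-sample pilot, 17
neighbour swaps, one windowed slippage and one full-plate rotation for
restoration (20 seeds); 96-sample cohorts with 10%/50% random switches
for the iteration-depth property; 60-sample quartets for the tumour
direction; 10,000 random layouts and 200×100-plate replicates for the
design simulations. These sizes give stable Monte-Carlo estimates while
keeping a full verification run to a few minutes on one core.

## Known limitations

- Attribution is heuristic: errors between samples that were neighbours
  on both platforms (or neither) cannot be attributed, and the applied
  default may relabel the wrong platform even when the resulting array
  pairing is correct.
- Cycle enumeration is bounded (length ≤ 8); longer rearrangements must
  surface as chains or systematic transforms.
- Standalone aliens cannot be named (only sequence-consistent slippage
  names its aliens), so maps corrupted by arbitrary foreign samples are
  flagged rather than fully restored.
- The windowed-slippage search relies on chains; the transform search
  only tests whole-stage ±1 shifts.
- A study whose minority subgroup lacks the majority's eQTL associations
  will show elevated min-scores for that subgroup (the simulator
  reproduces this); such samples should not be discarded as mismatches
  without further evidence.
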