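# Methods

This note documents the models and procedures `oxygc` implements, the
defaults and why, the numerical choices, what the synthetic generators do
and do not emulate, and the known limitations.

## Site-class GC content

`gc_content` counts G+C over unambiguous A/C/G/T only; any other symbol
(N, IUPAC ambiguity codes, gaps) is excluded from numerator and
denominator, and a codon containing any ambiguity contributes no site to
any class. A sequence with zero unambiguous bases has no defined GC
fraction and raises rather than returning NaN.

Codon-position degeneracy is decided by substitution behaviour under the
translation table (default: bacterial/archaeal code 11, configurable): a
position is fourfold iff all four bases there encode the same amino acid,
zerofold iff none does. Stop codons are classified with stop treated as its
own "amino acid" and are flagged by `is_stop`. Under code 11 exactly eight
codon families (Leu-CTN, Val, Ser-TCN, Pro, Thr, Ala, Arg-CGN, Gly), i.e.
32 codons, have a fourfold third position; the test suite asserts this
against an exhaustive enumeration oracle.

**4FDS GC** pools third positions of codons whose third position is
fourfold, across the whole CDS set of a genome. **ZRS GC** is implemented
literally as the second nucleotide of every non-stop codon — not as a
degeneracy-computed zerofold set — because that operational definition is
what the delineation of these sites specifies; a `strict_zerofold=True`
mode restricts to substitution-verified zerofold second positions for
sensitivity analysis. CDSs whose length is not a multiple of 3 or that
contain an internal stop are skipped with a logged warning; annotation
pipelines produce such records and no guidance exists for them, so
exclusion (counted and visible in logs) is the conservative choice.

The orthologue screen `ortholog_ratio_filter` takes the three pairwise
distances among two ingroup orthologue candidates and an outgroup
reference and keeps the pair iff d(in1,in2)/d(in1,out) ≤ 0.8 and
d(in1,in2)/d(in2,out) ≤ 0.8 (boundary keeps). The original
outgroup-ratio method names "ratios 1 and 2" with both thresholds 0.8 but
does not print the formulas; these ratios are this package's documented
stand-in, not a claim about the original tool. Ortholog detection itself
(reciprocal best hits) is out of scope — pairs and distances are inputs.

## Distances, identity, neighbour joining

`p_distance` is the proportion of differing sites among compared columns
with **pairwise deletion**: a column counts for a pair only when both
sequences carry an unambiguous base. `identity_percent` = 100·(1 −
p-distance) is therefore mismatch-only identity: alignment gaps are never
penalised. This matters for fragmentary 16S sequences, whose large
alignment gaps reflect incomplete assemblies rather than indels — identity
is a more robust divergence proxy than gap-counting similarity there.
Complete deletion is not offered; pairwise deletion is the package-wide
convention.

`nj_tree` is the Saitou–Nei agglomeration. Tie-break: among Q-minimal
pairs, join the pair whose sorted (smallest-member-label, other-label)
tuple sorts first — deterministic and seed-free. Negative branch lengths
(possible on non-additive inputs) are clamped to zero with the deficit
moved to the sister branch so the pair's path sum is preserved; each clamp
is logged. On additive matrices NJ is exact and the tests require
reconstruction of input distances to 1e-9. `bootstrap_support` resamples
alignment columns with replacement, rebuilds NJ per replicate, and writes
each internal bipartition's replicate frequency as an integer percent on
the full-data tree (default 1000 replicates); degenerate resamples (a pair
with no comparable columns) are skipped with a warning and the support
denominator adjusted.

## Independent pair extraction

Merged states: aerobes + obligate aerobes → *aerobic*; anaerobes +
obligate anaerobes → *anaerobic*. The taxonomic prefilter walks ranks from
species upward, at each rank keeping groups that contain both merged
states among records not claimed at a lower rank — so a mixed species
claims its strains before its genus is considered.

"Adjacent in the tree" is defined here operationally (the source describes
it only by a worked example): maximal state-uniform clades are collapsed
into groups, and a bottom-up greedy scan emits **one event per mixed
node**, pairing the largest exposed aerobic group with the largest exposed
anaerobic group (ties by smallest member label). Groups left over at a
node where an event fired are discarded — pairing them higher up could
straddle the event's branch and break independence; at single-state nodes
the groups merge and propagate. This rule reproduces the published worked
example (three events; slow pair species7–species6, fast pair
species8–species5) and guarantees tip-disjoint pairs on any labelled tree,
which the suite property-tests on random trees and verifies against an
independent run-scan oracle on caterpillars. At a multifurcation the same
rule applies (one event, two largest opposite-state child groups).

Representatives: *slow* mode picks the group member with the shortest path
from the group's MRCA (least derived), *fast* the longest; ties go to the
genome with more annotated genes, then to the lexicographic smallest id.
Path lengths are rounded to 12 digits before comparison so representative
choice survives Newick round-trips. Both modes are always computable from
the same events, mirroring the duplicated slow/fast analysis design.
Pairs may carry a 16S identity; `filter_pairs_by_identity` keeps pairs at
or above a percent threshold (threshold 0 keeps all; a positive threshold
excludes unannotated pairs with a warning) and a sweep across thresholds
supports relatedness-sensitivity tables.

## PGLS

For a rooted tree with non-negative branch lengths, C[i,j] is the depth of
MRCA(i,j) and C[i,i] the root-to-tip depth. Unrooted trees are rejected —
no silent midpoint rooting. Zero-length terminal branches get 1e-8 added
to their variance (logged) to keep C(λ) positive definite. Pagel's λ
multiplies off-diagonal entries only.

`pgls_fit` regresses y on X = [1, x] by GLS via Cholesky whitening:
β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y with V = C(λ). Inference uses σ̂² = RSS/(n−2) and a
t distribution with n−2 df. λ̂ maximises the full multivariate-normal
log-likelihood over [0,1] by bounded scalar search (tolerance 1e-6), with
explicit boundary evaluation at 0 and 1 since the optimum is often on the
boundary; REML is available behind a flag. A fixed-λ mode is provided
because published tables reporting λ = 1.0 throughout do not say whether λ
was estimated (hitting the boundary) or fixed. A non-positive-definite
V raises with the condition number; a constant predictor raises a
degenerate-design error.

Oxygen coding: each of the seven contrasts assigns 3 to the more
oxygen-preferring group and 2 to the less, dropping organisms outside the
contrast; codes are not centred. GC is log-transformed on the **percent
scale, natural base** (`log_transform_gc`); the percent-vs-proportion and
base choices affect intercept and slope scale only, never sign or p, and
are switchable. The implementation was validated against R's
`nlme::gls` + `ape::corBrownian` on a fixed ultrametric fixture
(agreement to 1e-9, frozen in the test suite).

## Nonparametric tests

Wilcoxon signed-rank: zeros dropped, mid-ranks on |d|, statistic W⁺. For
n ≤ 25 the exact null is computed by convolution over doubled mid-ranks —
algebraically identical to enumerating all 2ⁿ sign vectors (the tests
verify equality against literal enumeration for n ≤ 12) but feasible
across the exact regime. Mann–Whitney U: mid-ranks, exact null by
enumeration of all C(n₁+n₂, n₁) labellings for n₁+n₂ ≤ 20. Beyond the
exact regimes both use normal approximations with continuity and tie
corrections; exact and approximate p agree within 0.01 at the boundary on
tie-free data. Two-tailed p is min(1, 2·min(lower, upper)) in all paths.
The crossover sizes (25, 20) are configurable per call.

## Synthetic data

Generators are pure functions of parameters + a single integer seed;
named substreams (`stream(seed, name)`) let stages be re-simulated
independently. Defaults state the world the analyses assume:

- `simulate_tree`: Yule process, waiting time Exp(k·birth_rate) with k
  lineages, extended past the last split by one waiting time; expected
  depth Σ_{k=2..n} 1/(k·b). Default birth rate 1.
- `simulate_oxygen_states`: exactly `n_transitions` flips on distinct
  uniformly chosen edges, inherited from an anaerobic root. Flips, not a
  continuous-time Markov chain, because the analyses need controlled
  transition counts (few transitions per tree, as real oxygen-requirement
  evolution shows). Adjacent flips can merge, so recovered events ≤
  transitions.
- `simulate_gc_trait`: y = intercept + slope·x + ε, x the 2/3 code, ε ~
  MVN(0, σ²C(λ)). This is exactly the generative model PGLS assumes.
- `generate_cds`: every codon drawn from a fourfold family, with second
  bases split AT-second (Leu, Val) vs GC-second (Ser, Pro, Thr, Ala, Arg,
  Gly) and third bases assigned G/C vs A/T by count, so realised 4FDS and
  ZRS GC equal round(target·n)/n — within 1/n of any target in [0,1], with
  no stop codons possible.
- `generate_16s_pair`: mutates round((1−identity/100)·length) positions
  and optionally interleaves gap-bearing columns that must not change
  mismatch-only identity.

The pipeline preset ("table1") simulates 80 organisms, 10 transitions,
obligate sub-labels assigned with probability 0.5 within each merged
state, graded true 4FDS GC (0.38/0.43/0.50/0.58 from obligate anaerobe to
obligate aerobe — spanning the realistic prokaryote range with the
strongest elevation in obligate aerobes), Brownian fraction-scale noise of
sd 0.04 per unit depth, 300 codons per organism, and per-event synthetic
16S identities in [88, 100].

What the generators do **not** emulate: realistic substitution processes
(GTR, codon models), indel evolution, rate variation, selection on codon
usage, horizontal transfer, or annotation error. A green test therefore
establishes correctness of the statistical machinery under its stated
assumptions, not recovery of the published empirical numbers — those
derive from ~2000 database genomes that are out of scope here.

## Numerical choices and degenerate inputs

- NJ Q-ties: lexicographic smallest label pair; bootstrap determinism from
  the numpy Generator seeded explicitly.
- Covariance Cholesky failures report the condition number.
- GC fractions print at 6 decimals in TSV outputs.
- Exact-test tail comparisons use a 1e-9 slack when comparing rank sums to
  the observed statistic (mid-ranks are exact halves, so this is safe).
- Empty inputs raise typed errors (`UndefinedCompositionError`,
  `UndefinedDistanceError`, `DegenerateDataError`, `InsufficientPairsError`,
  `EmptyGroupError`) rather than propagating NaN.

## Limitations

- The event rule is a normative reconstruction of a procedure the source
  defines by example; other adjacency conventions (e.g. parsimony-based
  transition counting) could pair differently on polytomies or deeply
  nested mixed clades.
- PGLS assumes Brownian residuals; no Ornstein-Uhlenbeck or measurement
  error models, and no phylogenetic logistic regression.
- The ordinal 2/3 coding treats the oxygen contrast as a fixed regressor;
  uncertainty in trait assignment is not modelled.
- p-distance NJ is a distance method; likelihood or Bayesian inference is
  out of scope, as is alignment computation (inputs arrive aligned).
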