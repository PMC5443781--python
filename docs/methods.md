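# Methods

## Allele identity

An allele is an amino-acid sequence of the analysed *csd* fragment (exon 7:
the hypervariable region, HVR, plus part of the proline-rich domain).  Two
fragments are the same allele exactly when their amino-acid strings are
equal, so synonymous nucleotide variants collapse.  Reads are translated
with the standard genetic code from a configured frame offset; an IUPAC
ambiguity letter or an in-frame stop inside the analysed region aborts
translation rather than guessing a residue (degenerate primer positions may
carry ambiguity codes outside the region; inside it they would silently
fabricate alleles).

Coordinates are 0-based half-open amino-acid positions.  Because the HVR
length varies between alleles, the fragments themselves vary in length, and
a single fixed end coordinate cannot describe a dataset.  The pipeline
therefore specifies the region per dataset as a frame offset plus the two
conserved flank lengths, and derives each record's HVR span as
`[flank_left_len, length - flank_right_len)`.  No per-sequence HVR
detection heuristic is applied; the spans are arithmetic consequences of
the dataset-level configuration.

## Pairwise differences

Each unordered pair of distinct alleles is globally aligned with a protein
similarity matrix (BLOSUM62) and affine gaps (open 10, extend 0.5, both
configurable).  The fragment termini are conserved, so before aligning,
identical 7-residue sentinels (`WWWWWWW`) are appended to both ends of both
sequences; they align to themselves — equivalent to infinite end-gap
penalties — and are stripped from the result.  Counts per pair:

* `d_len_hvr` — absolute HVR length difference, computed from the annotated
  spans (alignment-independent);
* `n_subst` — alignment columns where both sequences contribute a residue
  and the residues differ (`n_subst_hvr` restricts to columns inside both
  HVR spans);
* `d_total = d_len_hvr + n_subst`.

Gap placement inside a repeat tract is score-degenerate; the aligner's
first (deterministic) alignment is taken, and all reported counts are
invariant to that choice: length difference comes from the spans, and the
mismatch-column count of an optimal anchored alignment is tie-stable for
these repeat structures.

Functional-heterozygosity criteria: the three-inequality rule
(`d_HVR >= 6`, `d_PSD >= 1`, `3 d_PSD + 2 d_e8 >= 9`) takes `d_PSD` as all
substitution columns of the fragment (the fragment lies inside the
potential specifying domain) and `d_e8 = 0` unless the user configures an
exon-8 sub-span, because the sequenced fragment ends before exon 8; with
`d_e8 = 0` the rule effectively demands three PSD substitutions and is
strict on HVR-only variation.  The minimal rule asks for at least 5
amino-acid differences in the HVR; the HVR difference defaults to
`d_len_hvr + n_subst_hvr` with a length-only variant reported alongside,
since published usage does not fix which convention was applied.  All-pairs
summaries report both, so either convention can be audited.

## Occupancy chain and the richness estimator

Drawing alleles uniformly from a pool of `N`, the number of distinct
alleles `Y_n` after `n` draws is a Markov chain: from state `u` it stays
with probability `u/N` and advances with `(N-u)/N`.  The distribution of
`Y_D` is computed by exact forward dynamic programming in double precision
(`O(min(N,D)·D)` time; no transition matrix is materialised).  Closed forms
serve as oracles: `E[Y_D] = N(1-(1-1/N)^D)` and
`Var[Y_D] = N a + N(N-1) b - N² a²` with `a=(1-1/N)^D`, `b=(1-2/N)^D`; the
DP agrees with both to 1e-9 and with brute-force enumeration of all `N^D`
outcomes for small `N, D`.

Given `D` draws showing `U` distinct alleles, the estimator returns

    n_hat = min { N : P_N(Y_D >= U) >= 1 - α },      α = 0.05.

The tail probability is non-decreasing in `N`, so the ascending search from
`N = U` finds the unique crossing.  Interpretation: any pool smaller than
`n_hat` would put the observed distinct count in its lower `α` tail.
Sampling-from-known-pool simulations (`N* = 133`, `D = 372`) show the
estimate is conservative: `n_hat >= N*` in about 96% of replicates, i.e. a
~95% upper confidence bound on the richness compatible with the observed
diversity; the package documents it as the *minimal* richness in the sense
of the stopping rule above.  Two alternative conventions are provided for
audit: `inclusive` (`P(Y_D > U) >= 1-α`, one pool size larger on typical
inputs, and the convention under which the small-sample example
`D=3, U=1 -> 5` holds) and `literal` (the verbatim arg-min reading of the
rule, which is degenerate because every `N <= U` satisfies it; it returns 1
with a warning).  A step-count switch (`draws` vs `transitions`) covers the
off-by-one ambiguity of the chain notation; it shifts estimates by at most
one allele.  `U = D` (every draw distinct) raises an "estimate unbounded"
error: saturated draws carry no upper information under the inclusive
reading, and the contract treats saturation as out of range.

Drone sampling: a heterozygous queen's two alleles both appear among `n`
drone haplotypes with probability `1 - 2^(1-n)`; six drones give 0.96875,
above the 0.95 design bound used when planning per-colony sampling.

## Null models

Reference datasets are pools of `D` iid draws with replacement from `N`
equally frequent elements.  Expected occurrence spectra and expected
two-population overlaps are means over 100 replicate pools by default
(means, not medians), with analytic oracles used in tests:
`E[#seen exactly k] = N·C(D,k)(1/N)^k (1-1/N)^(D-k)` and
`E[shared] = N(1-(1-1/N)^{D_a})(1-(1-1/N)^{D_b})`.

Observed-vs-null comparison uses the Pearson chi-square statistic over
aligned categories with `df = bins - 1`.  Published analyses of this kind
do not state their binning; here, bins with expected count below 1 are
pooled into the adjacent tail bin (trailing sparse bins fold back into the
last retained bin), the pooling is reported with the statistic, and the
threshold is configurable — so any binning convention can be reproduced and
audited.  Reported p-values therefore depend on the binning choice and are
not comparable across conventions.

Within-apiary deduplication (`redAB`-style) keeps one row per
(apiary, allele) pair, recording how many colonies in the apiary carried
the allele; it is idempotent.

## Worldwide novelty

An allele is worldwide-unique when its amino-acid sequence has no exact,
case-insensitive match in a user-supplied reference FASTA of previously
described alleles trimmed to a comparable region.  Exact matching mirrors
the allele-identity criterion and keeps the classification reproducible and
offline; near-identity (alignment-based) matching is deliberately out of
scope.  The 2×2 table partitions distinct alleles by apiary range (one vs
more than one apiary) against novelty, with per-row unique proportions.

## Synthetic populations

The generator emulates a maternal-allele survey:

* **Alleles**: conserved flanks (defaults `RSRERSYG` / `PPQSPPSQ`,
  arginine/serine-rich and proline-rich, in the spirit of the real flanking
  domains) around an HVR of `NY` repeat units; lengths uniform on
  `hvr_len_range` (default 5–25 units) with per-residue substitution
  probability 0.03 sprinkled in so equal-length alleles can differ.  Pools
  are collision-checked to be pairwise distinct.
* **Frequencies**: uniform by default (the estimator's assumption);
  geometric (`r^i`, normalised) or Dirichlet families model unevenness
  without committing to a parametric form the data do not identify.
* **Structure**: 18 apiaries × 11 colonies ≈ the surveyed 193 colonies,
  6 drones per colony; each queen draws two distinct alleles
  (resampling on collision); with `swarm_dup_prob` (default 0.1) a colony
  copies a same-apiary queen's genotype, emulating swarms settling in their
  apiary of origin.
* **Mutation**: with probability `mutation_prob` (default 0.02 per queen
  allele — the high end of published slippage rates for microsatellite-like
  tracts) an allele is replaced by a fresh mutant: one repeat unit inserted
  or deleted, or one residue substituted, collision-checked against every
  existing sequence so novelty tests have exact truth.
* **Back-translation**: fixed codons (`N→AAT`, `Y→TAT`, one codon per
  residue) regenerate nucleotide FASTA that round-trips through the
  translation stage.

What the generator does *not* emulate: real allele genealogies and
selection dynamics, paternal alleles, sequencing error, chromatogram
artefacts, or the true (unknown) allele frequency law — the frequency
families are stand-ins.  Passing tests demonstrate the machinery is
correct under the stated sampling model, not that real populations satisfy
that model.

## Problem sizes in tests

Exhaustive enumeration oracles run at `N, D <= 6`; closed-form moment
checks up to `N = D = 500`; Monte-Carlo oracle comparisons use 200–400
replicates with empirical 3-standard-error tolerances; estimator
calibration uses 500 replicates at the pooled-survey scale
(`N* = 133`, `D = 372`), with estimator results memoised across repeated
(D, U) pairs.  The singleton-excess experiment runs at sampling saturation
`D/N ≈ 2.9`, matching the pooled survey (372 draws / 133 alleles); in much
shallower sampling the singleton signal of slippage mutants is masked by
the null's own singleton-rich spectrum.

## Known limitations

* The estimator assumes locally uniform allele frequencies; under skewed
  frequencies it underestimates richness (fewer distinct alleles surface),
  which is the direction the analysis itself argues makes worldwide totals
  underestimates.
* `d_e8` defaults to 0 because the sequenced fragment ends before exon 8;
  the three-inequality rule is then harsher than in studies with longer
  fragments.
* Chi-square p-values depend on the (configurable, reported) binning and
  should be compared only within one convention.
* Novelty is exact-match only; a reference set trimmed to a different
  region will spuriously classify everything unique.
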