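# Methods

This note documents the models, parameter choices and numerical decisions
behind each module, and what the synthetic-data tests do and do not show
about real data.

## Read cleaning

Reads are single-end, adapter-ligated small RNAs.  The 3' adapter is found
by scanning every read offset left to right and accepting the first offset
where the overlapping adapter prefix (minimum overlap 5 nt) matches with a
mismatch fraction <= 0.1; the insert is everything upstream.  An adapter at
offset 0 is an insert-null read.  The quality filter requires mean Phred
>= 20 and no base below 10; both thresholds are configurable, since
published pipelines rarely state theirs.  Retained insert lengths are
18-32 nt: the lower bound is the conventional small-RNA cutoff, the upper
bound caps at the Dicer product range.  Reads are binned into exactly one
discard category (quality, insert-null, length); N-containing inserts go
to the quality bucket because downstream Hamming matching cannot score an
N.  Reads above the length cap land in the length bucket.

A note on clean-read accounting: in the study this package models, the
printed clean-read percentages (e.g. 96.01% for the black-skin library) do
not equal clean/raw computed from the printed totals (19,649,441 /
20,502,959 = 95.84%); the intermediate denominator was not stated.  This
package reports clean/raw.

## Annotation

BLAST-style search is replaced by ungapped Hamming matching: with 18-32 nt
queries, gaps buy nothing and exact semantics make oracle testing easy.
The search uses pigeonhole seeding (a query allowed m mismatches is split
into m+1 exact seeds, each looked up in a cached k-mer index), with a
brute-force scan retained as the test oracle.  Tolerances: 1 mismatch for
the ncRNA/genome tiers, 2 for conserved-miRNA calling (anchored at the 5'
end, up to 2 nt of 3'-length slack, since mature 3' ends are heterogeneous).

Each unique sequence gets exactly one category by the fixed priority
ncRNA (GenBank > Rfam) > known miRNA > repeat > exon > intron; ties within
a tier break on (fewest mismatches, lexicographically smallest reference
id) for reproducibility.  Counts of multi-mapping reads are counted once,
toward the single assigned category.  Repeat/exon/intron assignments come
from genome hits intersected with interval sets (0-based, half-open).

Family names are derived by string normalization (strip species prefix,
arm suffix, paralog letter: ccr-miR-125b-5p -> miR-125), because family
membership in practice is encoded in mature names.

The novel-miRNA screen is deliberately minimal and labeled a *candidate*
screen: extract the mapped locus +-70 nt, fold the mature against every
same-length (+-2) window in the opposite flank with the package's duplex
energy model, and accept when the best duplex reaches -18 kcal/mol with
>= 14 paired mature bases and the mature wholly inside one arm.  It is not
a replacement for full precursor prediction (no Drosha/Dicer processing
signatures, no read-stack evidence).

## Differential expression

TPM = count / clean-read total x 10^6, at full floating precision.  Fold
change is log2(treatment/control); the contrast orientation must be given
explicitly (e.g. `WS:BS` = white over black).

The exact two-library test treats the second library's count y,
conditional on x, as negative-binomially distributed:
p(x|y) = (N2/N1)^y (x+y)! / (x! y! (1+N2/N1)^(x+y+1)), which sums to 1
over y.  Implementation notes:

* terms are evaluated in log space via log-gamma — the printed factorial
  form overflows beyond x+y ~ 170, while real counts reach millions;
* the lower tail C sums y' = 0..y directly (all terms positive, no
  cancellation); the upper tail D is 1 - C(y-1), never an infinite sum;
* the two-sided p is min(1, 2 min(C, D)) — the tail-doubling convention,
  chosen because the source workflow displays both tails without stating a
  combination rule;
* a useful check identity (verified in tests): swapping (x, N1) with
  (y, N2) complements the inclusive lower tail, C + C_swapped = 1, and
  D = C_swapped + p(x|y) since both inclusive tails count the boundary
  term.  The naive "C and D swap places" statement holds only up to that
  shared term.

Zero counts need no special handling in the test; for fold-change display
a count + 0.5 pseudo-count is used when a side is zero.  q-values are
Benjamini-Hochberg within each pairwise comparison (the source workflow
reports q-values without naming a method; BH is the field default).  The
default DEM criterion is |log2FC| >= 1 with p < 0.05; the stricter
q <= 0.001 variant is available as a mode flag, since both criteria appear
in published practice without reconciliation.

## Target rules

Sites are scored as gapless antiparallel duplexes; with guides <= 26 nt
and adjacency-based rules, a +-register-shift model captures the rule
semantics without internal bulges (gap support is out of scope).  Per
guide position the state is Watson-Crick, G:U wobble (weight 0.5),
mismatch (1.0) or unpaired overhang (1.0).  Rule 4 ("no mismatches at
positions 10-11") treats a wobble as a violation — it carries weight
0.5 > 0, so the position is not perfectly paired; rules 2-3 count any
non-Watson-Crick state by default, with a lenient switch that exempts
wobbles (the published rule text does not resolve this).

Energies use a bundled versioned nearest-neighbor table
(`data/nn_stacks_v1.tsv`): the 16 Watson-Crick dinucleotide stack free
energies (Turner-2004 values, kcal/mol at 37 C), a +0.5 kcal/mol penalty
per G:U pair per stack, and a +4.1 duplex-initiation term.  Deriving G:U
stacks as "WC value + penalty" guarantees monotonicity: converting any
wobble to Watson-Crick can never weaken the duplex, a property the tests
assert.  Broken pairs contribute nothing and interrupt stacks.  The duplex
energy is capped at 0 so the energy ratio (duplex / perfect complement)
stays in [0, 1] even for two-pair duplexes where the initiation term
dominates.  An external folding engine could be plugged in; the bundled
table is the reference for all tests.

Scanning slides windows of guide length +-2 at step 1; overlapping passing
windows merge to the best site (lowest weighted mismatch score, then
lowest energy, then smallest site/guide length difference, then leftmost —
the length-difference key prevents a 2-nt-overhang window from displacing
the exact-length site it contains).

## Reference-gene stability

Quantities assume PCR efficiency 2 (q = 2^-Ct), so log2 ratios of genes
are Ct differences.  geNorm: V_jk = SD across samples (ddof = 1) of
Ct_k - Ct_j; M_j = mean V_jk over partners; iterative exclusion removes
the highest-M gene until two remain (the best pair); the surviving pair is
ordered by M in the final three-gene round so the consensus tie-break has
a strict geNorm rank.  V_n/n+1 uses log-scale normalization factors (mean
of -Ct over the n most stable genes).  NormFinder follows the
variance-decomposition idea: with groups, stability = mean over groups of
|intergroup effect| + sqrt(intragroup variance / n_g), without the
original's shrinkage of the intergroup term; without groups it reduces to
the SD of the gene's residual after removing the per-sample mean profile.
BestKeeper is descriptive: SD and CV of raw Ct, Pearson R against the
per-sample geometric mean of all candidates; a constant gene has undefined
R and is reported missing.  The consensus is the mean of the three
per-method ranks, ties broken by the geNorm rank.  Missing Ct cells are
imputed with the gene median (warned); genes > 20% missing are dropped.

The study's printed stability values (e.g. the 0.661 pair M) are not
reproducible here because the underlying Ct measurements were never
published; the acceptance checks are therefore property-based, on
simulated Ct with planted orderings.

## Synthetic data

One integer seed drives everything through independent derived streams,
so any component regenerates in isolation and outputs are bit-identical
across runs.

* **Libraries.**  Clean-read classes are drawn at study-like proportions
  (miRNA 80%, tRNA/rRNA ~0.9% each, minor snRNA/snoRNA/scRNA, repeat
  0.5%, exon 1%, intron 2.6%, unannotated remainder); insert lengths come
  from one shared distribution with P(22) + P(23) = 0.74, emulating the
  ~74% 22-23 nt fraction of the real libraries.  miRNA abundances are
  log-normal (sigma = 1.5) to mimic the observed dynamic range (from
  tens of millions of counts down to singletons); planted fold changes
  scale condition-specific weights.  Sequencing errors are injected at
  0.1%/base — low enough that mismatch-tolerance tests stay
  interpretable.  Corrupted reads (~1.7%: insert-null, short, low-quality,
  N-containing) exercise each filter; every read's realized trimming fate
  is validated at construction (resampling the rare insert that happens
  to contain an adapter-like stretch), so truth fate buckets are exact.
* **Count tables** for DE testing are drawn multinomially at depth 10^6
  per library over 200 miRNAs with 20 planted 4-fold changes (half up,
  half down); unplanted miRNAs share identical relative abundances and are
  true nulls.
* **Ct matrices** follow Ct = baseline_g + tissue_effect_s + N(0, sigma_g),
  10 genes x 15 tissues; baselines 17.5-25.5 cycles, tissue-effect SD
  0.25, noise SDs 0.10/0.12 for the two planted stable genes and 0.6-1.3
  for the rest.  The tissue effect is kept moderate because BestKeeper
  ranks raw-Ct scatter, in which a large common tissue effect would mask
  the per-gene noise ordering; values are range-checked against [15, 32]
  (generation fails rather than clipping), matching the Ct range reported
  for real reference-gene panels.
* **UTR fixtures.**  Per miRNA: a transcript with a perfect site, one with
  a site violating exactly one rule, one with no site.  Violation patterns
  are analytic — e.g. rule 1 via nine G:U wobbles (score 4.5, but cheap in
  energy: each wobble costs at most 2 x 0.5 kcal/mol, keeping rule 6
  satisfied); rule 5 puts full mismatches at duplex ends where they break
  a single stack — and each constructed site is verified against the rule
  engine before being emitted.  Guides whose base composition cannot host
  a pattern (rule 1 needs nine wobble-capable positions) fall back to the
  always-feasible rule-4 pattern, and the truth label records what was
  actually planted.

What passing these tests shows — and does not.  The generator produces
uniform random reference sequences, position-independent errors, no
quality-score structure, no hairpin-processing signatures and no
replicate-level biological variance.  Recovery of planted effects
therefore demonstrates the correctness of the algorithms under their own
model assumptions, not performance on real libraries with adapter dimers,
ligation bias or expression-dependent error structure.

## Problem sizes

Default test and acceptance scales were chosen to exercise every code
path at comfortable statistical margins: simulated libraries of 1,500-
20,000 reads on a 50-kb toy genome, 20 replicate count-table simulations
at depth 10^6, 200 replicate Ct simulations, and 2-kb UTR fixtures.  All
scales are parameters of the public API and can be raised freely.
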