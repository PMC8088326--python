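# Methods

## Codon model and objective

A synthesized codon position is a mixture of nucleotides; we represent a
codon as three 4-blocks of fractions over (T, C, A, G), each block summing
to one (tolerance 1e-9). The binary support of a codon is its *base
codon*; base codons are in bijection with three-letter IUPAC ambiguity
strings, and exactly `15^3 = 3375` exist because each block is a non-empty
subset of four nucleotides. A degenerate codon is the equimolar spiked
codon on its support.

Under a genetic code (the standard table by default; any NCBI table id, a
64-row TSV, or per-codon reassignments with user-defined symbols are
accepted) a codon encodes a distribution over the symbol alphabet — the
20 canonical residues plus STOP, extended by any reassigned labels. The
weight of a symbol is the summed probability of the concrete codons
translating to it, each concrete codon's probability being the product of
its three position fractions. A multiset of `l` codons encodes the
equal-weight mixture of its codons' distributions; the design objective is
the L2 norm (L1 and L∞ are selectable) of the difference between this
mixture and the target distribution. Because the square root is monotone,
the optimizer compares squared L2 internally and reports the norm.

The forbidden-codon condition is structural, not probabilistic: codon
pattern `m` excludes concrete codon `f` iff some tuple position where `f`
is non-zero is zero in `m`, which is equivalent to `f` lying outside the
expansion of `m`'s support (verified exhaustively over all 3375 × 64
pairs in the test suite).

## Pre-selection

Before the search, the 3375 base codons are filtered: any base codon able
to produce (a) a user-forbidden concrete codon, (b) a stop codon (unless
stops are explicitly allowed), (c) a codon of a residue with target
weight zero, or (d) — when a codon-usage table with a `min_usage`
threshold is supplied — a concrete codon with relative usage below the
threshold, is removed. The usage option is a hard filter rather than an
objective weight: it keeps the objective unchanged and guarantees the
ordered oligo contains no rare codon at any probability. An optional
`max_degeneracy` cap bounds the expansion size of eligible base codons.
If the surviving pool cannot encode every positive-weight target residue,
the designer raises an error naming the offending residues.

## Search

The optimizer is a strict-improvement stochastic hill climb over codon
multisets:

1. initialize `M` with `l` independent random codons from the pool;
2. repeat: draw a random codon `c` (see proposals below), replace a
   uniformly random element of `M` by `c`, accept iff the objective
   strictly decreases (ties reject), resetting the rejection counter on
   acceptance;
3. stop once `rejection_factor × l` consecutive proposals have been
   rejected (`rejection_factor` defaults to 1000).

Proposals: in degenerate mode, the equimolar codon on a uniformly chosen
pool base codon. In spiked mode, the same base-codon draw with each
block's fractions drawn from a flat Dirichlet over the support — the
maximum-entropy choice given no preference among support nucleotides. An
optional local move (`ratio_shift_prob`, default 0) instead re-draws one
position's block of an existing codon in `M`; it can refine nearly
converged solutions but is off by default, since whole-codon proposals
already reach L2 ≈ 3e-4 at length 33 and ≈ 6e-4 at length 100 under the
default settings, and the simpler move set is easier to reason about.

Implementation note: proposals are state-independent, so they are drawn
and evaluated in vectorized chunks; within a chunk, proposals are scanned
in order, the state is updated at the first improvement, and the
remainder is re-evaluated against the new state. This reproduces the
sequential accept/reject semantics — including stopping exactly at the
consecutive-rejection budget — while making runs of rejections cheap
(chunks grow up to 8192 during rejection streaks). All randomness flows
from one `numpy.random.default_rng(seed)` stream, so identical
(configuration, seed) pairs give bit-identical results. Replicate runs
use seeds `seed, seed+1, …`; the best replicate is the lowest final
distance, ties broken by replicate order.

Spiked fractions stay continuous during the search and are quantized only
at export (default step 1%), because synthesis resolution is a property
of the vendor, not of the design problem. Quantization uses
largest-remainder rounding so each block sums to exactly 100%, and never
zeroes a support nucleotide (it is bumped to one step, taken from the
largest entry).

## Distance reporting

Deviations are reported on two scales: distance metrics (L1, L2, L∞, the
sum of squared differences, and the per-symbol mean of squared
differences, all on the 0–1 probability scale) and signed per-residue
deviations in percentage points on the 0–100 scale. The headline figure
is always the L2 norm — the largest of the three squared-error variants
for deviations below one, so a bound on L2 implies the same bound on
either squared interpretation.

## In-silico validation

`sample_sequences` draws concrete DNA sequences position-by-position and
independently according to the design fractions, with constant flanks
attached verbatim — i.e. it emulates ideal solid-phase synthesis with
exact mixing ratios and no coupling bias, no synthesis errors, and no
position-neighbour effects. Real oligonucleotide batches show
vendor-dependent per-position composition bias, so passing validation
here bounds the design error only, not the synthesis error.

Statistics computed from a sampled ensemble:

* pooled residue composition of the randomized region and its deviation
  from a target (both scales as above);
* uniqueness fraction (#distinct/#total), at the DNA level by default
  (protein level optional);
* per-position nucleotide frequency matrix (4 × 3l, rows T/C/A/G,
  columns summing to one — logo-ready TSV);
* molecular-weight mean and SD of the encoded protein, including constant
  prefix/suffix residues, using average residue masses by default (the
  linear-mode MALDI convention; monoisotopic by flag). Sequences
  containing an in-frame stop are excluded from mass statistics — they
  would not yield the tagged full-length product — but counted and
  reported, and retained in DNA-level composition and uniqueness. The
  closed-form mode conditions each position's residue distribution on not
  being a stop; because positions are independent, this equals the
  stop-free ensemble mean exactly, and sampled and closed-form means
  agree within Monte-Carlo error in the tests.
* diversity: the exact DNA diversity is the big-integer product of
  per-position support sizes; protein diversity is estimated by birthday
  collision counting on a seeded sample (`m(m-1)/2c` for `c` colliding
  pairs among `m` draws; with no collisions only a lower bound is
  certified and infinity is returned).

## Built-in targets

Three target families ship as code for examples and benchmarking: the
uniform 20-residue distribution; the uniform distribution over the
ten-residue "early" alphabet A, S, D, G, L, E, T, I, P, V; and the
average Swiss-Prot (2019-era release) residue frequencies as a natural
composition. Libraries designed against them exercise a reduced alphabet,
the full alphabet, and a strongly non-uniform target respectively.

## Problem sizes and numerical choices

The test suite runs the designer at lengths 2–100 with 10 replicates
where replication matters, sampling-based checks at 5e4–6e5 sequences
with three-standard-error bounds, and exhaustive oracles (all 3375 base
codons, all 3375 × 64 exclusion pairs, all 36 size-2 multisets of an
8-codon pool) where enumeration is feasible. Acceptance runs use 10
replicates at lengths 33 and 100, matching the replicate convention used
throughout.

Degenerate-input handling: an empty codon pool and a target residue no
pool codon can encode raise errors naming the cause; an all-forbidden
enumeration returns an empty list with a warning; empty multisets are
rejected; distributions reject negative weights and zero totals and
normalize otherwise.

## Known limitations

* The hill climb accepts only strict improvements, so small instances can
  stall in local optima; replicates mitigate this (the suite checks the
  exhaustive optimum is reached in ≥ 90% of seeded runs on a frozen
  8-codon instance). For one- to three-position saturation mutagenesis,
  exact integer-programming designs are preferable; this package targets
  composition control over long randomized regions.
* Codon order in the exported single oligo is the optimizer's order (an
  optional seeded shuffle is available); composition is order-invariant.
* No position-specific or covariation constraints; no minimization of the
  number of distinct codons; no RNA-level representation.
* The sampler does not model synthesis, amplification, transcription or
  translation biases; measured libraries will deviate from the design by
  those process errors.
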