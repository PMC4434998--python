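# Methods

## Model

The package compares two DNA sequences by conditional information
content rather than by alignment. An order-`k` finite-context model
(FCM) — a Markov model whose next-symbol distribution depends on the
preceding `k` symbols — is trained by simple counting on the reference
`y`. The probability of symbol `s` in context `c` is estimated as

    P(s|c) = (N(s|c) + α) / (N(c) + 4α)

where `N(s|c)` are reference counts, `N(c) = Σ_s N(s|c)`, and `α > 0`
keeps every probability strictly positive. The information profile of
the target `x` is `n_i = −log₂ P(x_i | context)` in bits per symbol.
Its sum over positions `i ≥ k` is the conditional compressed-size
estimate of `x` given `y` — a practical upper bound on conditional
Kolmogorov complexity — and its local level is what the segmentation
thresholds.

The underlying assumptions are: (i) shared evolutionary material shows
up as contexts the reference has seen, driving `n_i` towards 0, while
unrelated material stays near the 2-bit ceiling of a 4-symbol alphabet;
(ii) homology is locally contiguous at the scale of the smoothing
window, so block rearrangements appear as long low runs; (iii)
inversions are visible only against the reverse-complemented reference,
which is handled by training a second model on it.

The model is strictly static while profiling: no counts are updated
from the target, so the profile measures information flowing from `y`
to `x` only.

## Procedure

1. **Preprocess.** Both inputs are upper-cased; every byte outside
   {A,C,G,T} (N runs, IUPAC ambiguity codes) is replaced by a uniform
   random nucleotide, drawn from a seeded generator. Length is
   preserved and the replaced intervals are recorded. Random fill is
   incompressible under any model, so these stretches can never pair —
   which is the desired behaviour for unsequenced regions.
2. **Forward scan.** Profile `x` under the model of `y` (direct) and
   under the model of `revcomp(y)` (inverted); smooth each profile with
   a centred moving average; mark maximal runs below `T`, merge runs
   separated by at most `merge_gap`, and drop runs shorter than
   `min_block`.
3. **Orientation resolution.** Positions low in exactly one
   orientation keep it. A run low in both orientations is assigned,
   as a whole, to the orientation with the smaller mean smoothed bits
   over the run (ties go to direct); this rule covers the conflict case
   the basic unmarked-region rule leaves open, and is deliberately
   isolated in one function. Positions high in both stay unmarked.
   The result is re-filtered by `min_block`.
4. **Localisation.** Each surviving target region becomes a training
   sequence (reverse-complemented first if inverted); the reference is
   profiled against it and segmented with the same parameters, which
   yields the partner region(s). One target region may localise to
   several reference regions (duplications); all are reported under the
   same hue. A region that localises nowhere is dropped with a logged
   warning — this is the main source of the method's approximate (not
   exact) commutativity, together with the min-block filter.
5. **Rendering.** Pairs are coloured by HSV hues `i·360°/n` in target
   order, with fixed saturation 0.65 and value 0.95; inverted pairs get
   a diagonal-hatch overlay so orientation survives grey-scale
   reproduction. The SVG is byte-deterministic for a fixed map.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `k` | 14 | symbols | context order; memory of the model |
| `α` | 0.001 | — | estimator smoothing; near-ML behaviour |
| `T` | 1.5 | bits | segmentation threshold in [0, 2] |
| `window` | 1000 | positions | smoothing window |
| `min_block` | 20000 | positions | minimum reported block |
| `merge_gap` | 0 | positions | bridge between low runs |
| `seed` | 1 | — | non-ACGT randomisation |

`k` must lie in [1, 28]. Low `k` saturates context counts and flattens
the contrast between related and unrelated material; high `k` makes
almost every context unique, pushing unrelated material to exactly
2 bits and related material towards 0 — good contrast, but increasingly
brittle under substitution noise, since one mismatch disturbs `k+1`
positions. `k = 14` is a good operating point for sequences longer than
about 1 Mb (adopted here as the package convention) and is the CLI
default; for much shorter or highly repetitive sequences it may need
tuning.

`T` is data-dependent: it should sit well below the average profile
level of the material you want to capture, which means lower values for
closely related sequences and higher values for distant ones. The
admissible range [0, 2] bits is the alphabet ceiling, stated here as an
implementation convention. The default 1.5 is a permissive
starting point; the synthetic experiments in the test-suite use
`T = 1.0` against 1%-diverged copies whose profile level is ≈ 0.35
bits.

`window` trades breakpoint resolution against noise tolerance: recovered
breakpoints are reliable to roughly ±2·window, and blocks shorter than
the window cannot be resolved at all. `min_block` (20 kb default,
following the practice of discarding matched regions smaller than
20 kb) suppresses incidental short matches. With small windows and
noisy copies, occasional spikes above `T` can split a block;
`merge_gap` re-bridges them.

The forward scan and the localisation pass share `k`, `T` and `window`
throughout; nothing in the procedure requires them to differ and a
single parameter set keeps runs reproducible from one record.

## Counting representations

Counts live in a dense `4^k × 4` table for `k ≤ 12` (≈ 0.5 GB of
transient memory at the boundary) and in sorted sparse key arrays with
binary-search lookup above that; 4²⁸ dense entries would be infeasible.
The two representations are value-identical — tested against a
brute-force substring counter — and counting is exact: no hashing with
tolerated collisions, no count aging. Queries are vectorised over whole
profiles (numpy), which is what makes megabase runs take seconds.

## Numerical choices and edge cases

- Positions `i < k` have no full context and are assigned exactly
  2.0 bits (uniform fallback) so the profile length always equals the
  target length; for sequences ≫ k this is negligible.
- Smoothing is a centred moving average with the window truncated at
  the boundaries; constant profiles are fixed points and `window = 1`
  is the identity. The global mean is preserved up to boundary effects
  of order `window/length`.
- Thresholding is strict (`< T`); values exactly at `T` count as high.
- A reference shorter than `k+1` symbols yields an empty model: every
  probability is 0.25 and every code length 2 bits.
- The substitution convention of the generator replaces a hit position
  by one of the three *other* nucleotides, so the nominal rate is the
  realised mismatch rate.
- The single generator seed expands into one independent stream per
  edit-script operation, so scripts are extensible without perturbing
  earlier blocks.

## What the synthetic generator does and does not emulate

The generator plants exactly the events the method claims to detect:
copied blocks with i.i.d. substitution noise, reverse-complemented
blocks, novel (information-unrelated) blocks and N-runs. It does not
model indels, tandem or interspersed repeat families, GC skew, or
realistic divergence processes; real genomes also contain low-complexity
and repetitive regions that raise the false-match floor, and
real rearrangements have micro-homologies at breakpoints that blur them.
Passing the planted-recovery tests therefore demonstrates the machinery
(profiling, two-orientation segmentation, localisation, drawing) under
clean block structure, not calibrated sensitivity or specificity on real
chromosomes — on real data the threshold `T` must be chosen per pair,
and repeats produce multi-region localisations by design.

## Known limitations

- Breakpoint precision is limited by the smoothing window; there is no
  sub-window refinement step.
- Blocks shorter than `min_block` (or the window) are invisible.
- The method is approximately, not exactly, commutative in
  reference/target order; the measured reciprocal overlap on planted
  fixtures is ≈ 99.9%, but asymmetric threshold effects can drop
  marginal pairs on one side only.
- Whole-genome all-pairs comparison is out of scope: one run maps one
  sequence pair, and multi-chromosome comparisons are done by
  concatenating each side (record offsets are kept in the sequence
  metadata).
- Plain FASTA only; no gzip streaming, FASTQ or quality handling.
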