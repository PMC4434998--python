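# rearrmap

Alignment-free detection and visualisation of genomic rearrangements —
direct homologies, inversions, translocations — between a reference and
a target DNA sequence, using the information content of one sequence
measured under a compression model of the other.

**Who it is for.** Comparative genomicists and cytogeneticists who want a
quick, assembly-tolerant picture of how two chromosomes (or chromosome
sets concatenated into one sequence each) relate structurally, without
running an aligner. Because the method only counts k-mer contexts, it
works even when one side is an unassembled, block-permuted collection of
contigs: shared content is still found, only its ordering is deferred to
assembly.

## The method

Let `y` be the reference and `x` the target, both preprocessed to the
alphabet {A,C,G,T} (every other symbol is replaced by a uniformly random
nucleotide, so those stretches are maximally incompressible and cannot
match anything). An order-`k` finite-context model (FCM) is trained on
`y` by counting: `N(s|c)` is the number of times symbol `s` followed the
`k`-symbol context `c`. The model serves the additively smoothed
estimator

    P(s | c) = (N(s|c) + α) / (N(c) + 4α),       α = 0.001 by default,

and the per-position information profile of the target is the code
length

    n_i = −log₂ P(x_i | x_{i−k} … x_{i−1})   bits,

computed with reference counts only. Where `x` shares material with
`y`, `n_i` collapses towards 0; elsewhere it sits near the 2-bit random
ceiling. A smoothed version of the profile is compared against a
threshold `T`; maximal runs below `T` (at least `min_block` long,
20 kb by default) are the regions of interest. The same scan against
the reverse-complemented reference picks up inversions; a stretch low in
both orientations is assigned to the one with smaller mean bits, and a
stretch high in both is left unmarked (unique or unsequenced sequence).
Each surviving target region is then itself used as a training sequence
and the reference is profiled against it, which localises the partner
region(s) on the reference side. Pairs are coloured by equally spaced
HSV hues and drawn as a two-bar SVG ideogram.

## Worked example

Build a synthetic pair with planted rearrangements — a 1 Mb random
reference, and a target made of a 300 kb direct copy, a 300 kb inverted
copy, 200 kb of novel sequence and a 200 kb direct copy (copies carry 1%
point substitutions):

```python
from rearrmap import *

ref = random_sequence(1_000_000, 42, "chrA")
script = [CopyOp(0, 300_000, "direct", 0.01),
          CopyOp(400_000, 300_000, "inverted", 0.01),
          NovelOp(200_000),
          CopyOp(700_000, 200_000, "direct", 0.01)]
target, truth = apply_script(ref, script, seed=7, target_name="chrB")
write_fasta(ref, "chrA.fa"); write_fasta(target, "chrB.fa")
```

then map one against the other:

```sh
rearrmap -r chrA.fa -x chrB.fa -k 14 -t 1.0 -o run --svg
```

which logs

```
INFO parameters: k=14 alpha=0.001 T=1 window=1000 min_block=20000 merge_gap=0 seed=1
INFO reference chrA: 1000000 bp (0 masked intervals); target chrB: 1000000 bp (0 masked intervals)
INFO mapping: 4.90 s, 3 pairs
```

and writes `run.map.json`, `run.target.bed`, `run.reference.bed` and
`run.svg`. The target-side BED reads

```
chrB	0	299891	pair0	0.34891002224823264	+
chrB	300134	599853	pair1	0.35241662705461924	-
chrB	800129	1000000	pair2	0.34907433079115047	+
```

All three planted copies are recovered with the right orientation (the
`-` strand marks the inversion) and breakpoints within a few hundred
bases of the truth (0/300 000/600 000/800 000); the 200 kb novel block
is correctly left unpaired. The score column is the mean smoothed
information inside the block, ≈ 0.35 bits — far below the 2-bit ceiling,
as expected for a 1% diverged copy under `k = 14`.

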