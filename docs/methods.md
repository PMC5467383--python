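# Methods

This note records the modelling choices behind `delfilter`: what the
simulator emulates, how each feature is defined, how the classifier is
trained, and where the open design decisions were resolved.

## The read simulator

The simulator stands in for both real sequencing data and the aligner.  A
uniform-random A/C/G/T reference is generated; deletion spans are excised
from two donor haplotypes (homozygous deletions from both, heterozygous from
one); fragments are drawn on each haplotype and mapped back to reference
coordinates by exact lift-over.  Because the lift-over is exact, the three
alignment signatures of a deletion appear by construction rather than by
running an external aligner:

- pairs whose fragment straddles a deletion become **discordant** — their
  reference-implied insert is the fragment length plus the deletion length;
- reads crossing a breakpoint are **soft-clipped**, keeping the longer
  flanking segment as the anchor, provided that segment reaches the minimum
  anchor length (15 bp, mimicking an aligner's seed requirement);
- when neither segment reaches the anchor length the read is emitted
  unmapped with its mate mapped (**one-end-anchored**).

Defaults describe a low-coverage human short-read library: 425 bp mean
insert, 57 bp insert SD (so ±3σ spans roughly a 254–596 bp size-selected
range), 79 bp reads, 10.6x target depth, 0.1% uniform substitution error.
Fragment lengths are truncated at ±3σ, so a deletion-free library contains no
discordant pairs by the 3σ rule.  Deletion lengths are drawn log-uniformly
within five strata (50–200, 200–500, 500–1000, 1000–10000, 10000–20000 bp)
weighted 147 : 275 : 65 : 172 : 24, the shape seen in population-scale
deletion call sets; the top stratum is capped at 20 kb to keep a simulated
chromosome small.  Deletions are placed disjoint and separated by more than
one mean insert, which also guarantees a read never spans two deletions.

Multi-mapping is emulated by drawing a set of "repeat" intervals covering 2%
of the reference; reads aligned inside one get MAPQ 0 and an `XA`
alternative-hit tag.  This produces the observable consequences of repeats
(the uniqueness features fire) without mutating the reference sequence.

Caveats.  With 79 bp reads the longer breakpoint segment is always ≥ 40 bp,
so the default configuration yields soft-clips but no one-end-anchored reads;
shorter read lengths produce them (this is exercised in the tests).  The
simulator does not model indel sequencing errors, chimeric fragments, GC
bias, or a real aligner's mapping heuristics, so passing tests demonstrate
that the pipeline recovers deletions whose alignment signatures are clean —
not that it matches any particular aligner's clipping behaviour on real data.

### Emulated caller output

The ensemble input is emulated rather than produced by running SV callers:
each implanted deletion is "detected" by each of four panel callers (two
split-read, two discordant-pair) independently with probability 0.7, with
breakpoints jittered by up to 0.5% (split-read) or 1.5% (discordant-pair) of
the deletion length — always inside the 2% duplicate window, so every true
call still matches the truth set.  Decoy calls with stratum-distributed
lengths are placed anywhere that neither duplicates nor reciprocally overlaps
(≥ 50%) a true deletion.  The standard benchmark uses 300 implanted deletions
and 300 decoys on a 1.6 Mb reference; that genome size is the smallest that
comfortably fits 300 stratum-distributed deletions (~0.5 Mb of deleted
sequence) with the required separations.

## Candidate merging

"Distance between two deletions" is defined as the larger of the two
breakpoint offsets, so both edges must agree to within 2% of the shorter
length.  Duplicate groups are closed transitively (single linkage), which
makes the result independent of input order; the sweep implementation is
checked against an O(n²) transitive-closure oracle.  When a group's bounds
disagree, a split-read supporter wins; ties fall back to a fixed source
priority list (`pindel`, `svseq2`, `breakdancer`, `delly` by default).
Merging is per sample; candidates from different individuals never merge.

## Features

All thresholds that the feature definitions need but that have no canonical
value are explicit in `FeatureConfig`:

| parameter | default | meaning |
|---|---|---|
| flank | 500 bp | upstream/downstream window for depth and read counts (≈ mean insert + read length) |
| breakpoint_tolerance | ±10 bp | how close a soft-clip boundary must sit to a breakpoint |
| mapq_min | 20 | below this (or with an XA/SA tag) a read counts as multi-mapped |
| insert model | estimated | mean/SD from up to 10 000 well-formed pairs unless given |

A pair "spans" a candidate when its outer fragment interval contains both
breakpoints; discordance is |insert − mean| > 3σ or non-FR orientation.
"With mismatches" means NM > 0.  For one-end-anchored reads the mapped mate
must lie within one mean insert of a breakpoint and supplies the uniqueness
call.  The four depth features are the three mean pileup depths (region,
upstream flank, downstream flank) plus the region-to-mean-flank ratio — the
classic depth signal, ≈ 0 for homozygous and ≈ 0.5 for heterozygous
deletions — with the ratio defined as 0 when the flanks are empty.  Depth is
raw (not base-quality filtered); the only normalization is the global
min–max map to [0, 1], fitted on training data, with unseen values clipped.

The feature order is fixed as listed in `FEATURE_NAMES`; the classifier's
performance is insensitive to the ordering, so no reordering logic exists.

## The classifier

Architecture (conv + pool + dense + dense): 8 feature maps with a 1×4 filter
at stride 1 (49 → 46), max-pooling of width 2 (46 → 23), a 32-unit hidden
layer, dropout 0.3 on the hidden layer, one logistic output unit.  Filter
size, stride, pooling mode and dropout rate follow the recommended settings
for this task; the map count (8) and hidden width (32) are free choices kept
small because the input is tiny.  Deeper conv+pool stacks are constructible
through `CNNArchitecture` but only the default is tuned.  Weights are
initialised with a symmetric scaled-uniform (Glorot) scheme.

Training minimises mean binary cross-entropy by plain mini-batch SGD
(θ ← θ − α∇J), α = 0.1 and batch 64 by default, tanh activations (ReLU and
softplus are available; softplus is computed as log1p·exp via `logaddexp`
for overflow safety).  20% of the training examples are held out for
validation; after each epoch the validation loss is compared with the
previous check and training stops after 3 consecutive increases, returning
the best-validation checkpoint.  Because the validation slice can be small
and its loss noisy in the first epochs, the stop rule only starts counting
after a burn-in of 20 epochs; setting patience to 1 and the burn-in to 0
recovers the strict "stop as soon as it rises" rule.  Examples are shuffled
once per epoch (disable with `shuffle_each_epoch=False`).  All randomness —
initialisation, the validation split, shuffling, dropout masks — derives from
one seed, so training is bit-reproducible.

Grid search trains one model per (learning rate × batch) cell, averaging
precision/sensitivity/F over seeded replicates, and reports a "mortality"
count: runs whose final training accuracy does not beat the majority-class
rate.  Single runs of under-trained configurations are noisy — on a balanced
candidate set an under-trained network sometimes degenerates to all-positive
calls — so directional comparisons between cells should use replicate means
(the acceptance test uses 10).

## Evaluation

Accuracy is precision over positive calls, tp/(tp+fp): in a false-positive
filtering task the interesting failure mode is keeping a bad call.
Sensitivity counts fn over truth deletions (not candidates), so the union's
sensitivity ceiling is representable.  F = 2AS/(A+S), 0 when both are 0.
Candidate/truth matching reuses the labeling rule.  Reported tables round to
4 decimal places.  `cross_validate` repeats the split/train/score cycle with
independent seeds and reports per-round and mean metrics; with `by_sample`
whole individuals are assigned to one side (70/30 by default).

## Numerical notes and degenerate inputs

- Gradients of every layer are validated against central finite differences
  (relative error < 1e-4) for all three activations and both pooling modes.
- A zero-weight network outputs exactly 0.5 everywhere (logistic of 0).
- Constant feature columns normalize to 0; an unfitted normalizer raises.
- `mean_depth` truncates out-of-contig regions with a warning and raises on
  an empty region; candidates on contigs absent from the BAM header raise.
- VCF deletion ends are taken from INFO/END, else |SVLEN|; records with
  neither are skipped with a warning; calls shorter than 50 bp are dropped.
- Probabilities are clipped to [1e-12, 1 − 1e-12] inside the cross-entropy.

## Known limitations

The synthetic benchmark's class structure is cleaner than real data: decoys
are drawn away from true deletions, breakpoint jitter is bounded, and the
aligner is idealised, so held-out F-scores near 1.0 on simulation say the
pipeline is wired correctly, not that real-data performance will match.  The
feature extractor assumes one sample per BAM and primary alignments only; it
does not use base qualities or local assembly evidence.  Training assumes
roughly balanced or mildly imbalanced labels; heavily imbalanced call sets
may need a threshold other than 0.5.
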