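# delfilter

False-positive filtering for ensemble deletion calls with a small 1-D
convolutional network.

## The problem

Structural-variant callers on low-coverage short-read data (≈10x) are
individually weak: split-read tools (Pindel, SVseq2), discordant-pair tools
(BreakDancer) and hybrids (DELLY) each miss different deletions, and pooling
their calls recovers most true deletions at the cost of flooding the call set
with false positives.  `delfilter` keeps the sensitivity of the pooled union
while restoring precision: it merges the callers' candidate deletions,
describes each candidate with 49 features read off the BAM around its
breakpoints, and trains a small convolutional network to separate real
deletions from artefacts.

The package is for methods developers and analysts who already have per-caller
deletion calls (as VCF or BED), a coordinate-sorted indexed BAM, and a
benchmark deletion set to train against.  A bundled simulator generates
aligned paired-end reads with implanted deletions, so the entire pipeline runs
and is tested without any external data.

## Method

1. **Union of candidates.**  Calls from all callers are pooled; two calls are
   duplicates when both breakpoint offsets are below 2% of the shorter
   deletion's length, max(|Δstart|, |Δend|) < 0.02·min(L_a, L_b).  Duplicate
   groups are closed transitively and each group is reported once, preferring
   breakpoints from split-read callers (base-accurate) over discordant-pair
   callers (interpolated).
2. **49 features per candidate** from the BAM: the deletion length; 8 counts
   of spanning read pairs — (discordant | concordant) × (error-free | with
   mismatches) × (uniquely | multiply mapped), where a pair is discordant
   when its reference-implied insert deviates from the library mean by more
   than 3σ or its orientation is not forward–reverse; 24 counts of
   breakpoint reads — (fully mapped | soft-clipped | one-end-anchored) ×
   (left | right breakpoint) × (anchor upstream | downstream) × (unique |
   multi); 4 read-depth values — mean pileup depth Σᵢ depth(i)/l over the
   candidate region and its two flanks, plus the region/flank depth ratio;
   and 12 read counts in (region | flanks) × (error | uniqueness) cells.
   Features are min–max normalized to [0, 1] on the training set.
3. **Labels** come from matching candidates against the benchmark under the
   same 2% breakpoint rule (a 50% reciprocal-overlap rule is available).
4. **Classifier.**  Each normalized vector is treated as a 1×49 image and fed
   to a conv + pool + dense + dense network (8 maps, 1×4 filter, stride 1,
   max-pooling width 2, 32 hidden units, tanh, dropout 0.3, logistic output)
   trained by mini-batch SGD, θ ← θ − α∇_θJ(θ; xᵢ; yᵢ), on the mean binary
   cross-entropy with α = 0.1, batch 64, and validation-based early stopping.
   The network is implemented directly in numpy; its gradients are verified
   against finite differences in the test suite.
5. **Evaluation** uses the SV-filtering conventions: accuracy A = tp/(tp+fp)
   (precision over positive calls), sensitivity S = tp/(tp+fn) (recall over
   the truth set) and F = 2AS/(A+S), plus per-length-stratum tables
   (50–200, 200–500, 500–1000, 1000–10000, 10000+ bp).

## Worked example

Run the whole chain on synthetic data from one config file:

```sh
cat > pipe.yaml <<EOF
genome_length: 400000
n_deletions: 60
n_decoys: 60
seed: 5
EOF
delfilter run --config pipe.yaml --out runout
```

which simulates a 400 kb sample at 10.6x with 60 implanted deletions, emulates
four callers' outputs plus 60 decoy calls, and prints:

```json
{
 "n_candidates": 121,
 "n_true": 61,
 "union": {"accuracy": 0.55,  "sensitivity": 1.0, "f_score": 0.7097},
 "cnn":   {"accuracy": 1.0,   "sensitivity": 1.0, "f_score": 1.0},
 "read_counts": {"fragments": 20760, "concordant_pairs": 19556,
                 "discordant_pairs": 1204, "soft_clipped_reads": 624,
                 "one_end_anchored_reads": 0, "multimapped_reads": 934}
}
```

Read: the unfiltered union of caller calls contains every true deletion
(sensitivity 1.0) but only 55% of its calls are real; the trained filter keeps
the full sensitivity while removing every decoy on the held-out third of the
candidates.  Each stage is also available separately (`delfilter simulate`,
`merge`, `featurize`, `label`, `train`, `predict`, `evaluate`); see
`delfilter <cmd> --help`.

## Layout

- `src/delfilter/simulator.py` — reference/donor generation, lift-over read
  simulation, truth VCF, emulated caller output
- `src/delfilter/candidates.py` — VCF/BED ingestion, duplicate merging
- `src/delfilter/features.py` — the 49-feature extractor and normalizer
- `src/delfilter/labeling.py` — benchmark matching, train/test splits
- `src/delfilter/model.py` — the numpy CNN, SGD training, grid search
- `src/delfilter/evaluate.py` — metrics, length strata, cross-validation
- `src/delfilter/pipeline.py`, `cli.py` — end-to-end drivers
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
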