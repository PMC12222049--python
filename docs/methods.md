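# Methods

## Problem and overall design

Bacterial gene annotation decomposes into two decisions: which open reading
frames (ORFs) are real protein-coding genes, and — within a coding region —
which of several in-frame start codons is the true translation initiation
site (TIS). `bactgene` implements this as a two-stage classifier pipeline
over k-mer-tokenized DNA:

1. **CDS stage.** Every ORF group (the nested ORFs sharing one stop codon on
   one strand) is represented by its longest member, truncated to 510 nt
   from the start codon, tokenized as overlapping 6-mers at stride 3
   (frame-aligned dicodon tokens), and classified coding / non-coding.
2. **TIS stage.** For each coding group, every candidate start codon gets a
   60-nt window (30 nt upstream, 30 nt downstream; the start codon occupies
   window offsets 30–32), tokenized at stride 1, and classified true / false
   TIS. The candidate with the highest predicted probability is retained and
   flagged `prediction_max_likelihood = 1`; ties break toward the 5'-most
   (longest-ORF) candidate, and groups whose every window crosses a contig
   boundary fall back to the longest member's start with flag 0 — silently
   dropping a predicted gene seemed worse than an unrefined start.

ORF extraction scans both strands in all three frames for intervals that
begin with one of {ATG, TTG, GTG, CTG}, end at the next in-frame stop
{TAA, TAG, TGA}, and contain no internal in-frame stop; nested ORFs are
retained. Codons containing N match neither set. The minimum ORF length
defaults to 90 bp (30 codons), a conventional floor for bacterial gene
callers; it is configurable.

Coordinates are uniformly 0-based half-open on the forward strand with the
strand stored separately; GFF's 1-based inclusive convention exists only at
the I/O boundary. A gene's identity is its (strand, stop-coordinate) pair —
the 3'-anchored convention that matched-end benchmarking uses — and the 5'
boundary is the TIS stage's responsibility.

## Dataset construction

CDS examples are labeled per ORF group: positive iff the group's stop
coincides with an annotated CDS 3' end (the example sequence is the longest
member, 5'-most 510 nt kept on truncation — start-proximal composition
carries the signal the first stage must learn). Negatives are downsampled
per 50-bp length bin to at most the positive count in that bin, so sequence
length alone cannot separate the classes; 50 bp is fine enough to match the
distributions while keeping bins populated.

TIS windows come only from groups that match a reference CDS; the window of
the annotated start is positive, all other candidate windows negative, and
random undersampling equalizes the classes. Windows that would cross a
contig end are skipped rather than N-padded: padding would inject artificial
tokens into the most-attended region of a fixed-length input.

Splits are by organism: whole organisms are assigned to train/test/eval
(default fractions 0.6/0.2/0.2), so held-out performance measures
cross-organism generalization, not memorization.

## Model

A BERT-style transformer encoder implemented directly in numpy, with
explicit forward and backward passes: token + learned absolute position
embeddings (with embedding LayerNorm), post-LayerNorm blocks of multi-head
scaled-dot-product self-attention (padded keys excluded before the softmax)
and a GELU feed-forward network, a tanh pooler on the [CLS] hidden state,
one linear layer to two logits, and a softmax. The explicit implementation
keeps every intermediate inspectable — the per-head attention tensors feed
the interpretability module unchanged — and numerical gradient checks in
the test-suite pin the backward pass to the forward definition.

Vocabulary: the 4^6 = 4096 6-mers plus {[PAD], [UNK], [CLS], [EOS]}; k-mers
containing N map to [UNK] to preserve positional structure. Input lengths
are fixed per task: 57 tokens for TIS (55 stride-1 6-mers of a 60-nt window
plus the two specials — also the side of the attention matrices the
interpretability module analyzes) and 512 for CDS (169 stride-3 6-mers of a
510-nt sequence plus specials plus padding).

Two configurations matter: the full-scale architecture (12 layers, 768
hidden, 12 heads) is constructible, and the **desk-scale** configuration
(2 layers, 64 hidden, 4 heads, d_ff = 256) is what the tests, benchmarks
and acceptance runs exercise. Weights initialize from normal(0, 0.02)
truncated at 2 sigma under a fixed seed.

## Training

AdamW (decoupled weight decay 0.01 on weight matrices only) with a linear
warm-up over the first 10% of steps to the peak learning rate, then linear
decay to zero; two-class cross-entropy loss with probabilities clamped at
1e-12. The default peak is 3e-5, the conventional fine-tuning rate for a
pretrained encoder. Desk-scale models train *from random initialization*,
where 3e-5 cannot escape the initialization in a few hundred steps, so the
desk presets use 3e-4, batch 16, 6 epochs, and keep the parameters of the
best-eval-F1 epoch instead of stopping at the first F1 plateau — at a few
hundred examples per epoch, epoch-to-epoch F1 is noisy enough that a
plateau rule (gain < 1e-3, also implemented and on by default in
`TrainConfig`) triggers before the model has left chance level. Metric
computation thresholds the positive probability at 0.5; undefined
precision/recall (zero denominator) is reported as 0 with a degeneracy
flag, avoiding NaN propagation.

Training is deterministic under the config seed (shuffling, dropout and
initialization all derive from it). A NaN loss aborts with a diagnostic
rather than continuing; `seed_sweep` re-trains under several seeds for
run-to-run variability probes without asserting anything about spike
counts.

## Synthetic study conditions

The generator stands in for a real multi-genome corpus. Defaults are the
study conditions used throughout: 30 organisms, 20 genes per 22-kb genome
(about one gene per kilobase, matching real bacterial gene density), GC
0.5 i.i.d. intergenic background, gene bodies drawn from a per-organism
codon profile (Dirichlet concentration 50 around a shared GC3-preferring
profile with 4:1 preferred:unpreferred weights), start codons sampled
ATG/GTG/TTG at 0.80/0.12/0.08, stops TAA/TGA/TAG at 0.60/0.30/0.10, and
gene lengths uniform over 30–160 codons so coding and background ORF length
distributions overlap and length balancing retains most negatives. Each
true start carries an AGGAGG hexamer ending 8 nt upstream (a
Shine-Dalgarno-like signal whose rediscovery by the attention analysis is a
meaningful test), and two decoy in-frame start codons are planted in the
stop-free upstream context so every gene's ORF group offers ambiguous TIS
candidates.

Per-organism codon-profile draws make held-out-organism evaluation
nontrivial; planted genes are recoverable by construction (3'-end recall
1.0 for the extractor), so end-to-end benchmark losses are attributable to
the classifiers, not the scan. What passing on this corpus does **not**
show: robustness to operons, overlapping genes, GC skew, repeats,
pseudogenes, or real intergenic structure — none of which the generator
emulates.

At these conditions the desk pipeline reaches held-out-organism accuracies
well above the 0.90 (CDS) and 0.85 (TIS) levels the test-suite asserts, and
annotating an unseen genome recovers ≥ 90% of planted genes at the 3' end;
the acceptance script recomputes all of these from scratch. A full run
(corpus, both trainings, annotation, disruption sweep) takes a few minutes
on one CPU core.

## Interpretability

Attention analysis uses the final layer. The mean attention landscape is
the per-sequence mean over heads, then the mean over sequences — the
average of row-stochastic matrices, hence itself row-stochastic (asserted
to 1e-4). Nucleotide-level importance spreads each k-mer token's [CLS]-row
attention uniformly over its k covered bases; the disruption experiment
replaces the top- (mode "high") or bottom-ranked (mode "low")
ceil(ratio·60) positions with a base drawn uniformly from the three
alternatives, re-tokenizes and re-scores. Ratio 0 returns the original
probability bit-exactly; ratio 1 leaves no position unchanged. Whether the
original experiment disrupted nucleotides or tokens, with uniform or fixed
replacement, is not specified anywhere we could verify; these are this
package's documented choices, made deterministic under a seed.

## Numerical choices and degenerate inputs

- Attention masking adds -1e9 to padded key scores before the softmax;
  padded keys receive exactly zero mass after exponentiation underflow.
  Classification is invariant to pad-position embeddings to 1e-5 (tested).
- LayerNorm epsilon 1e-12; GELU uses the tanh approximation.
- float32 parameters by default; float64 available via `ModelConfig.dtype`
  and used by the gradient-check tests.
- Empty genomes (all N) annotate to an empty set; an all-masked attention
  input, an empty candidate list in TIS selection, an empty evaluation set,
  and a one-class undersampling input are errors, not silent results.
- `length_balance` leaves a bin under-filled (with a warning) when it has
  positives but no negatives.

## Known limitations

- Desk-scale results quantify the pipeline's behavior on synthetic
  conditions; they say nothing about accuracy on real genomes, which in the
  original setting required a pretrained encoder and a corpus of thousands
  of genomes.
- The CDS stage scores only each group's longest member; sub-maximal
  members are never rescored (whether the original pipeline did is
  unspecified).
- Single-exon prokaryotic gene models only; no partial genes at contig
  edges, no programmed frameshifts.
- Loading externally pretrained DNABERT-style weights is an interface hook
  (`TransformerClassifier.load`) and intentionally untested here.
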