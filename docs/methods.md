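# Methods

## Problem and pipeline

`taxonembed` classifies nucleotide sequences by host organism (bacteria,
fungi, human, plant) with taxonomic ranks (family, clade) as auxiliary
supervision. The pipeline has five stages:

1. **Segmentation.** Sequences are normalized (uppercase, U→T, ambiguity
   codes → a PAD symbol) and cut into fixed-length windows (default
   3000 nt) with 50% overlap; windows start at multiples of
   `round(L·(1−overlap))` and a new window opens only while the previous
   one ends before the sequence does, so every base is covered. Short
   tails are completed with PAD, which one-hot encodes to an all-zero row
   and is excluded from k-mer tokens — padding therefore injects no
   composition signal.
2. **4-mer embedding.** Each segment becomes a sentence of overlapping
   4-mers (stride 1), indexed 1…256 in lexicographic order (AAAA=1,
   AAAC=2, …). A skip-gram model with a full softmax over the 256-token
   vocabulary learns dense vectors: each focus token predicts its
   neighbors within window w (default 1). Because the loss is a sum over
   (focus, context) pairs, training runs on the aggregated co-occurrence
   count matrix; one "epoch" is one exact full-batch Adam step, making
   training deterministic and cheap at any corpus size. The per-position
   focus/context relationship matrices are retained for inspection.
3. **Autoencoding.** The embedded segment (T×d, channels = embedding
   dimensions) feeds a convolutional autoencoder: three conv+ReLU+maxpool
   blocks, a flatten, and a fully connected bottleneck; the decoder
   mirrors the encoder with stride-2 transposed convolutions and a final
   linear convolution. The stacked variant (SCAE) has a deterministic
   bottleneck; the variational variant (VCAE) emits a diagonal Gaussian
   (mu, log-variance) sampled with the reparameterization trick
   z = mu + exp(log_var/2)·eps during training. Inference features are
   the bottleneck activations (SCAE) or the mu vector (VCAE), so
   downstream behavior is deterministic; the variance can be exported
   and concatenated on request.
4. **MLELM chain.** An extreme learning machine (ELM) draws its input
   weights and biases once from Uniform(−1,1) and never updates them;
   only the output weight matrix is learned, as the minimum-norm
   least-squares solution via Moore–Penrose pseudo-inverse, in one batch
   operation. Two ELMs run in series: features → soft per-label scores,
   then soft scores → labels. Per-label thresholds are calibrated on a
   validation split by maximizing F1 over the 99 percentiles of observed
   scores (ties → lowest threshold); hard labels come from thresholding
   with an argmax fallback inside any block that must contain exactly
   one label.
5. **Evaluation.** Host predictions are the argmax over the host block
   of the soft scores. Reported metrics: confusion matrix, one-vs-rest
   precision/recall/F1, accuracy, and macro-averaged one-vs-rest ROC AUC
   with partial AUC over FPR ∈ [0, 0.2] (normalized by the interval
   width; ties on the step curve count one half). Evaluation is per
   segment by default; `vote="sequence"` aggregates segments by majority
   (ties → lexicographically first host).

## Multilabel targets

Each instance's binary target concatenates block-wise one-hots: the host
block first, then one block per selected rank, label names sorted within
blocks. Rank blocks act as auxiliary outputs trained jointly; metrics are
computed on the host slice. Selecting more than two ranks is allowed but
warned against (joint training over three or more rank blocks tends to
overfit). Segments inherit all labels of their source sequence.

## Synthetic corpora

The generator emulates the statistical shape of a skewed four-host viral
corpus: host proportions default to 36.3/20.6/29.7/13.5% (bacteria/
fungi/human/plant; the printed percentages total 100.1%, so they are
renormalized when drawing), highly variable sequence lengths, and a
host → family → clade label tree. Every tree node carries a nucleotide
motif (drawn without replacement, so sibling motifs are pairwise
distinct). Sequences are i.i.d. uniform background in which motifs are
planted on non-overlapping, motif-length-aligned slots covering a
`motif_density` fraction of the sequence; each planted slot carries the
clade, family, or host motif according to `ancestor_mix`, and planted
bases are substituted independently at `mutation_rate`. An RNA option
writes U instead of T to exercise the normalization path.

What this emulates: class-specific nucleotide composition with a
hierarchical structure, length variability, and host imbalance. What it
does not: codon structure, phylogenetic substitution processes, shared
background homology, GC-content gradients, or sequencing error. Passing
tests therefore demonstrate that the pipeline recovers planted
composition signal at realistic noise levels — not performance on real
viral genomes.

## Study conditions for the standard benchmark

`PipelineConfig.desk_scale()` fixes the benchmark conditions: 200
sequences of 120–360 nt over a 4-host × 2-family × 2-clade taxonomy;
motif length 12, density 0.9, per-base mutation 0.01, clade-signature
planting (`ancestor_mix = (1, 0, 0)`, i.e. family and host signal arise
from the tree structure over clades); 120-nt segments with 50% overlap;
16-dimensional embeddings trained 250 epochs; autoencoder filters
(32, 32, 32), kernel 13, bottleneck 32, batch 32, Adam 3e-3, 40 epochs;
chain with 128 stage-1 hidden nodes and ridge 1.0. Splits are 70/10/20
at the source-sequence level, stratified by host, so the 50% window
overlap can never leak bases across splits.

Three of these choices deserve explanation:

- **Equal filter counts (32, 32, 32).** A decoder that mirrors a
  narrowing encoder has, at its coarsest stage, as many channels as the
  encoder's last layer. Every length-8 output block is then painted
  through shared expansions of that many channel values, capping the
  local output rank at that filter count. With 16 clade templates to
  reconstruct, an 8-channel coarse stage cannot represent them, the
  reconstruction loss plateaus, and which directions the bottleneck
  captures becomes initialization lottery. Equal filter counts keep the
  cap above the number of classes. The full-scale defaults
  (128, 64, 32) do not bind at realistic segment lengths.
- **Kernel 13.** One planted motif spans 12 nt, i.e. a period of 12 in
  4-mer token space; a kernel of 13 covers a full period, letting first-
  layer filters act as motif detectors.
- **beta = 1/(100·T·d) for the VCAE.** The reconstruction term is a
  mean over T·d elements while the KL sums over latent dimensions;
  weighting the KL per reconstructed element (1/(T·d)) makes the two
  comparable, and the additional factor keeps the prior-matching pull on
  the log-variance from inflating sampling noise over training at this
  small scale. beta is exposed because no canonical scaling exists for
  mean-reduced reconstruction losses.

Library-scale defaults stay at the full-scale configuration (3000-nt
segments, filters 128/64/32, kernel 22, embedding 32, batch 100, Adam
1e-3, patience 10).

## Numerical choices

- ELM output weights default to the exact pseudo-inverse (ridge 0);
  a ridge term is available and used in the benchmark chain (ridge 1.0 on
  sigmoid hidden activations) because unregularized interpolation
  overfits when hidden nodes approach sample counts.
- Hidden-node defaults are twice the stage's input width.
- Autoencoder inputs are standardized per channel with training-split
  statistics; encoded features are likewise standardized before the
  chain.
- The VCAE's log-variance head starts with small weights and bias −6
  (posterior std ≈ 0.05), so early training is not drowned in sampling
  noise; the KL term can widen the posterior later.
- Early stopping restores best-validation weights; patience counts
  epochs without strict improvement.
- SMOTE balances host classes in whatever representation feeds the
  autoencoder (synthetic points are convex combinations of same-host
  neighbors; auxiliary labels are inherited from the seed instance).
- Argmax ties anywhere break toward the lowest index; threshold ties
  toward the lowest threshold; all randomness flows from explicit seeds,
  with stage seeds spawned from the master seed via `SeedSequence`.
- Degenerate inputs: sequences shorter than the window yield one padded
  segment; segments shorter than k after PAD removal yield an empty
  sentence (warning); single-class truth makes AUC undefined (NaN with
  warning); zero metric denominators yield 0 with a warning.

## Design choices where the design was open

- The skip-gram direction (focus predicts context) with a full softmax:
  at V = 256 negative sampling would only add variance.
- Convolutions are 1-D along the token axis with embedding dimensions
  as channels. The 4-mer color-platelet image (fixed bijective palette
  (i, 85i mod 256, 171i mod 256) over the 256 tokens) is produced for
  inspection and export; a 2-D convolutional path over those images is
  not implemented.
- The embedding is trained on training-split sentences only, to avoid
  leakage through the 50% overlap.
- VCAE inference features are mu only; `encode_with_variance`
  concatenates exp(log_var) when the downstream consumer wants it.
- The one-hot representation (`representation="onehot"`) is available
  as the autoencoder input as an alternative to the embedded matrix.

## Known limitations

- The NumPy training core is single-threaded BLAS-bound; full-scale
  settings (3000-nt segments, 128 filters) train slowly compared to GPU
  frameworks, so the benchmark runs at desk scale.
- Both architectures sit near the accuracy ceiling at desk scale (VCAE
  mean 0.989, SCAE 0.988 over five seeds), so architecture and
  label-set comparisons there resolve only coarse ordering, not effect
  sizes. In particular, adding the clade block to family-only
  supervision does not improve host accuracy at this scale: features
  are identical across the two label configurations and the extra 16
  output columns spread the chain's fixed capacity without adding
  information. The auxiliary-label benefit requires a representation
  that does not already separate hosts.
- Majority voting ignores segment confidence; no calibrated
  sequence-level posterior is produced.
- The generator's composition signal is planted, not evolved; distances
  between clades carry no phylogenetic meaning.
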