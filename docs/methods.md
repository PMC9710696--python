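# Methods

## The model

A DNA sequence is normalized to {A, C, G, T, N} and one-hot encoded as a
4 × L binary matrix (row order A, C, G, T; N columns are all-zero, so
ambiguous positions contribute nothing to any convolution). Sequences
longer than the network input are scanned with 1024 bp windows shifted by
500 bp; a trailing remainder shorter than 1024 bp is discarded, and a
sequence shorter than 1024 bp becomes a single window right-padded with
zero columns. Only the given strand is encoded; there is no
reverse-complement augmentation or canonicalization anywhere in the
package.

The feature-extraction CNN stacks eight modules of convolution → batch
normalization → ReLU → max pooling, followed by global average pooling and
a fully connected classification head. It is pre-trained for bacterial
species classification with softmax cross-entropy; afterwards only the
trunk is used. "Layer *l* feature maps" means the post-ReLU, pre-pooling
activations of module *l* — the post-activation tensor is what style
analysis correlates, and taking it before pooling keeps the map size M_l
as large as possible.

The style matrix of layer *l* is the Gram matrix G_ij = Σ_k F_ik F_jk of
the N_l × M_l feature-map matrix, computed per window without any
normalization by map size (all windows at a layer share one M_l, so the
elementwise window average is well-defined; a normalized variant is
available for experimentation). The feature vector lists the rows of the
averaged matrix in order — the full N_l², not the upper triangle. The
redundancy is harmless for Euclidean distances; it scales off-diagonal
contributions by √2 relative to a triangle encoding, uniformly for all
sequences. Per-window Gram matrices are averaged (not: feature maps
averaged and then one Gram taken — the two are not equivalent).

Binning is agglomerative clustering of the feature vectors with Euclidean
distance and Ward linkage, cut at a *given* number of bins; estimating the
species count and detecting unclassifiable contigs are out of scope. The
k-mer baseline counts length-k words (k = 3, 4 by default) at every offset
on the given strand, skips windows containing N, and normalizes by the
number of counted windows.

### Coverage augmentation

When per-contig coverage is available it is appended as a single extra
dimension. The scale adjustment is a package design choice: the appended
entry is the dataset z-score of the coverage times the mean per-dimension
standard deviation of the dataset's style vectors, so one standard
deviation of coverage spread is commensurate with a typical style
dimension. Degenerate datasets (constant coverage, or constant style) make
the extra dimension exactly zero. Population (ddof = 0) statistics are
used. The calibration must be computed over the full dataset being binned.

## Architecture and training defaults

The layer widths, filter sizes, pooling and optimizer are package
decisions (overridable via `FeatureCnnConfig`):

| parameter | default | rationale |
|---|---|---|
| filters per module | 64 | style dimension 64² is tractable for Ward clustering |
| filter sizes | 8, then 4 × 7 | an 8 bp first-layer span acts as a PWM-scale motif detector |
| pooling | max, width 2 per module | 1024 → 4 positions before global average pooling |
| batch-norm position | between convolution and ReLU | conventional ordering of the module stages |
| optimizer | Adam, lr 1e-3, batch 64 | standard; recorded in the training log |
| epochs | 20 (CLI default); 5 in the shipped experiments | the synthetic task converges in ~2 epochs |
| holdout | 10 % stratified split, scored each epoch | training-progress signal |

Initialization is He-scaled Gaussian, deterministic given the config seed.
The implementation is pure NumPy (activations in channels-last layout;
convolution as a sum of d shifted BLAS matmuls), with gradients verified
against finite differences in the test suite's triple-loop oracle.
Checkpoints store the config, all weights and the batch-norm running
statistics, and round-trip bit-identically on one platform.

## Synthetic data: what it emulates, what it does not

**Species models** are order-2 Markov chains over {A, C, G, T}. Rows are
Dirichlet(p/divergence) perturbations of the base distribution p implied
by a GC target, then exponentially tilted (bisection on the G/C column
weight) so the stationary GC matches the target to ~1e-4. This creates
codon-scale, species-specific word statistics plus a controlled GC
signal — the two signals composition-based binning exploits. The
`divergence` parameter sets how distinct species textures are:
divergence → 0 recovers the base distribution exactly.

**Pre-training sets** simulate one 100 kb genome per species and draw 1024
bp windows at uniform random starts (with replacement), mirroring random
extraction of training windows from whole genomes. **Benchmark contigs**
are non-overlapping 5120 bp cuts of freshly simulated genomes, so each
contig yields 9 scanning windows and the window-averaging path is
exercised.

**GC groups** are two sets of i.i.d.-base sequences with P(G) = P(C) =
x/200 and P(A) = P(T) = (100−x)/200, and the mirrored composition for the
second group — the simplest model consistent with "random sequences with
given GC content". Sequence length defaults to 5120 bp, again so that the
window-averaging path runs; at that length the per-sequence GC estimate
has σ ≈ 0.007, so groups at 55 % and 45 % are ~7σ from the midpoint and
the separation task is information-rich but not degenerate.

What the generators do **not** emulate: repeats, mobile elements, strand
asymmetry, codon/gene structure, sequencing error, chimeric contigs,
assembly artifacts, or abundance-dependent contig length distributions.
Passing the shipped experiments shows the pipeline extracts and uses
compositional signal correctly; it does not show field performance on real
metagenomes.

## The shipped experiments

All study conditions are fixed constants in `tests/test_acceptance.py` and
`scripts/acceptance.py`; every random draw derives from one seed via
spawned seed sequences.

1. **GC separation.** Pre-train on 8 species spanning GC 0.35–0.65
   (divergence 0.05, 500 windows each, 5 epochs — minutes on one CPU).
   Generate GC groups at x = 53, 55, 57; cluster layer-2 style vectors
   into 2 bins. At x = 55 and 57 the clustering is exact (ARI =
   homogeneity = completeness = 1.0), and accuracy is non-decreasing in x.
   At 5120 bp the x = 53 groups are already ~4σ apart per sequence, so
   unlike shorter-sequence settings this row also tends to saturate.

2. **Style vs. flattened feature maps.** The benchmark community is 8
   species *not seen in pre-training* (mirroring a train/test species
   split), all at GC 0.5, differing only in word-usage texture (divergence
   0.02), 50 contigs × 5120 bp each. Position-resolved flattened feature
   maps carry the class signal only in their per-position means, which
   window averaging cannot clean up, while the Gram correlation structure
   accumulates it quadratically over positions; style vectors beat
   flattened feature maps by a wide ARI margin (> 0.2 gate; observed
   ~0.3–0.8) at layers 2 and 4. With strongly separated species (e.g. the
   pre-training community itself) both features saturate at ARI 1.0 and
   the contrast vanishes — the regime where the contrast is visible is
   subtle-texture discrimination, which is also the realistic one.

## Numerical choices and degenerate inputs

- Gram matrices accumulate in float64 from float32 activations; symmetry
  and positive semi-definiteness hold to 1e-6 relative.
- Ward clustering uses the standard Lance–Williams recurrence (via scipy's
  linkage); bin labels are renumbered by first appearance, and assignments
  are deterministic for distinct pairwise distances. `n_bins = 1` and
  `n_bins = n` short-circuit without linkage.
- ARI uses the Hubert–Arabie contingency closed form; the all-identical
  degenerate case scores 1. Homogeneity/completeness use natural-log
  entropies with the convention that zero unconditional entropy scores 1.
  The pair F-measure returns 0 when TP = 0.
- k-mer profiles of sequences whose every window contains N are all-zero
  and flagged (`all_invalid`) rather than NaN.
- Empty sequences, single-class training sets, out-of-range layers or bin
  counts, and id mismatches between tables raise validation errors naming
  the offender.

## Known limitations

- Homogeneity and completeness trade off against each other, but
  completeness is **not** monotone under refinement of the predicted
  clustering (splitting a mixed bin can raise it); only homogeneity is.
  The test suite asserts the true one-sided property.
- An all-singleton prediction against balanced true classes has
  completeness strictly between 0 and 1 under the entropy definitions
  (0.5 for two balanced classes), not 0.
- Pre-training at the shipped scale uses 8 synthetic species; absolute
  scores on real communities with hundreds of species will differ.
- The species count must be supplied; no model selection is provided.
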