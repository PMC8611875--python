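# Methods

This note documents the models and procedures implemented in `hostgraph`,
the parameter choices that matter, what the synthetic data generator does
and does not emulate, and the numerical decisions a maintainer should know
about.

## Pipeline overview

1. **Proteins.** Per-genome protein FASTA is used verbatim when supplied
   (ids `<genome>_<n>`); otherwise a naive six-frame ORF caller (ATG→stop,
   ≥ 60 aa, standard code) stands in for a trained gene finder.  The
   caller is deliberately simple; for real data, externally predicted
   proteins are the recommended path.
2. **Protein clusters.** All-vs-all protein alignment (built-in aligner or
   external tabular input) becomes a similarity network: an edge for each
   pair with best E-value < 1e−5, weighted −log10(E) with E clamped to
   ≥ 1e−180 so reported E = 0 stays finite.  Markov clustering runs per
   connected component (exact, since components cannot merge) with
   expansion 2, inflation 2.0, pruning 1e−5, convergence 1e−8 or 100
   iterations.  Self-loops are set to each column's maximum edge weight,
   which makes the iteration invariant to uniform rescaling of the
   weights.  Attractors (nonzero diagonal mass) are merged into attractor
   systems; each remaining node joins the system holding most of its
   column mass, ties broken toward the cluster whose smallest member id
   sorts first, so output is deterministic.  Inflation and the weighting
   are exposed in configuration; log base 10 is conventional for E-values
   and harmless given scale invariance.
3. **Virus–virus edges.** For profiles with *a* and *b* clusters sharing
   *c*, the tail probability of the equal-probability hypergeometric null
   is computed in log space (`gammaln` + `logsumexp`); an edge requires
   −ln(P·C(N,2)) ≥ τ₁ = 1, i.e. a multiplicity-corrected expected count
   below e^(−1).  The equal-probability null is a deliberate
   simplification: cluster sizes vary, so this is a pragmatic, not an
   exact, significance test.  *c* counts shared clusters (set
   intersection), not shared proteins.  *N* counts all virus sequences in
   the graph (train and test), since query contigs participate in cluster
   profiles; hosts carry no profiles and are excluded.  The log base is a
   configuration knob paired with τ₁.
4. **Virus–host edges.** Best nucleotide-alignment E-value < τ₂ = 1e−5,
   or a known interaction (always connected, provenance recorded).  At
   most one edge per pair, keeping the smallest E-value.
5. **Node features.** See encoder below; host features are the
   E-value-weighted averages of neighboring virus features, with weight
   −log10(E) and weight 180 (the clamp ceiling) for known-interaction
   edges lacking an alignment — a confirmed interaction should dominate
   weak alignment neighbors.  Hosts with no virus neighbors get the zero
   vector and a warning, and are flagged.
6. **Per-rank GCNs, prediction, evaluation.** Below.

## Built-in fallback aligner

The package runs without external aligner binaries.  Candidate pairs are
found by shared exact k-mers (proteins: 5-mers, ≥ 3 shared; nucleotide:
15-mers grouped by diagonal into windowed regions), then scored with exact
local affine-gap alignment (Biopython's PairwiseAligner): BLOSUM62 with
gap open 11 / extend 1 for proteins, +2/−3 with gap open 5 / extend 2 for
nucleotide.  Bit scores use the Karlin–Altschul form
bit = (λS − ln K)/ln 2 with standard ungapped constants (λ = 0.267,
K = 0.041 for BLOSUM62; λ = 0.625, K = 0.41 for +2/−3), and
E = m·n·2^(−bit) over full sequence lengths.  This E-value dialect is
approximate — seeding bounds sensitivity and the constants are not
regime-exact — but it separates homologs from chance matches by tens of
orders of magnitude at the scales involved, and the 12-column tabular
interface means DIAMOND/BLASTN output can replace it everywhere.

## Sequence encoder

Genomes are segmented into non-overlapping 2 kbp windows; a trailing
remainder ≥ 1 kbp is kept N-padded to 2 kbp, shorter remainders are
dropped (whole sequences under 2 kbp give one padded segment).  The
padding rule is a package decision: it keeps short-contig information
without admitting mostly-N windows.

A skip-gram model with negative sampling (d = 100, window 4, 5 negatives,
unigram^0.75 noise) embeds the 4^k overlapping k-mers (default k = 3;
k ∈ {3..6} configurable).  K-mers containing non-ACGT characters embed as
zero vectors, so N padding is neutral.  Updates are applied in vectorized
batches with a generous ±10 clip on embedding entries; on tiny
vocabularies the duplicate-index batch updates could otherwise overshoot.

The segment classifier applies parallel convolutions of widths {4, 8, 16}
(64 filters each) to the (L−k+1)×d embedding matrix — the row count is the
sliding-window count — followed by global max pooling, concatenation
(192), a 512-unit ReLU dense layer, a 256-unit ReLU dense layer, and a
SoftMax over genus labels.  Training minimizes cross-entropy with
minibatch Adam (lr 3e−3, batch 64, 25 epochs) with dropout 0.5 on the
pooled layer; segments inherit their genome's label, and the embedding
table is frozen during CNN training.  Dropout and the epoch budget were
chosen because at desk scale (tens of training genomes) the unregularized
model memorizes genome-specific motifs instead of genus-level signal.
The first dense layer is fixed at 512 units because its post-ReLU output,
averaged over a genome's segments, *is* the node feature vector; the
encoding is therefore nonnegative and invariant to segment order.  The
convolution is computed by table lookup per filter column (a segment is a
stream of vocabulary indices), a factor-d saving over dense convolution,
in float32.

## GCN, calibration and prediction

The adjacency with self-loops is symmetrically degree-normalized,
Ā = D̃^{−1/2}(A+I)D̃^{−1/2}, guaranteeing spectrum in [−1, 1].  Two graph
convolutions (512→256→128, ReLU) feed a dense SoftMax layer sized to the
rank's label vocabulary.  One model per rank (phylum→genus) is trained on
the same graph; labels differ per rank.

The objective is L = ECE + L2 over labeled nodes only (every host plus the
known-interaction viruses).  L2 is the mean over labeled nodes of the mean
over classes of squared differences from the one-hot label — scale-free in
the class count.  ECE uses 10 uniform bins over the SoftMax maximum
(half-open bins, top bin closed): ECE = Σ_i (T_i/T)·|Acc_i − conf_i| with
conf_i the bin's mean confidence and T_i its sample count.  Its gradient
is taken through the confidences only; bin membership and per-bin
accuracies are treated as constants within a step (the only differentiable
reading, since both are piecewise constant).  Correctness inside the loss
is measured against training labels, and all masked nodes — including the
always-correct host nodes — enter the bins (a flag restricts to virus
nodes).  MSE through a SoftMax has notoriously flat gradients once a
class's probability collapses; full-batch Adam at lr 1e−3 therefore runs
1000 epochs by default, which costs seconds at desk scale and is required
for the graph-extension scenario where a label class is supported by only
two nodes.

Prediction takes the per-rank argmax with its SoftMax value as confidence;
ranks below the user's confidence threshold abstain.  The reported lineage
walks phylum→genus and truncates at the first abstention or at the first
taxon that is not a child of the taxon above, keeping the higher ranks —
so inconsistent low-rank calls reduce prediction rate, not accuracy.
Viruses with no edges at all are still predicted (self-loops pass their
own features through) but carry a `no_neighbors` flag.  Metrics follow the
prediction-rate/accuracy convention: rate = predicted/total, accuracy =
correct/predicted, accuracy undefined when nothing is predicted.

Graph extension adds labeled host nodes (possibly of novel taxa) to a copy
of the graph, recomputes edges only for pairs involving the new nodes,
derives their features from their virus neighbors, and retrains; the new
labels propagate both through edges and through the feature-space mapping
the dense layer learns from the new hosts' (virus-averaged) features.

## Synthetic communities

The generator plants exactly the structure the method exploits, at a scale
that trains in minutes on one CPU:

- a five-rank taxonomy (phylum..genus) built by collapsing genera upward
  with configurable fan-outs; the default community uses 5 genera with
  fan-outs (2,2,1,1) so every rank retains at least two labels and every
  per-rank model is trainable;
- per-genus pools of 30 random 120-aa genes plus a community-wide pool of
  60 noise genes; each of the 20 viruses per genus carries 10 pool genes
  and 2 noise genes, as mutated copies (i.i.d. substitutions at 2 %).
  Proteins are emitted directly as protein FASTA *and* back-translated
  (uniform codon choice, stop appended) into the 15 kbp genome so the ORF
  caller can rediscover them;
- 2 host genomes (100 kbp) per genus; half the viruses
  (`fragment_insert_prob` = 0.5, mirroring the reported ~46 % of viruses
  with detectable host alignment in reference data) carry a 500 bp
  mutated fragment of their true host's genome;
- genus-specific 4-mer composition: host genomes and intergenic virus
  sequence are sampled from per-genus 4-mer distributions
  (1 + 3·U(0,1), normalized), giving the k-mer encoder a learnable
  genus signal;
- a truth table (virus → host and full lineage) and a known-pairs table
  covering 75 % of viruses; the remainder are the query set.

All outputs are byte-deterministic in the seed.  The generator does *not*
emulate realistic phage genome architecture, codon usage, GC skew,
sequencing error, or shared genes between host and virus beyond the
planted fragment; passing tests therefore demonstrate that the machinery
recovers planted signal under the stated noise, not field performance on
real metagenomes.  Conversely the planted signals are not trivially
strong: gene-pool overlap between two same-genus viruses is c ≈ 3–5 of
~200 clusters, which the corrected significance test converts into a
sparse (not complete) within-genus edge set, and the CNN must generalize
from 75 genomes.

## Problem sizes and determinism

Default experiment sizes: 100 viruses + 10 hosts, ~1200 proteins, ~800
2 kbp segments, knowledge graph of 110 nodes.  The full pipeline runs in
about 3 minutes single-threaded (CNN training dominates); each GCN rank
trains in seconds.  Every stochastic component (generator, skip-gram, CNN
init/shuffling/dropout, GCN init) draws from a `numpy` Generator seeded
from the run seed, so repeated runs are bit-identical; alignment, MCL and
graph construction are deterministic by construction.

## Known limitations

- The ORF caller has no model of translation initiation beyond ATG and no
  GFF output; it under- and over-calls relative to a real gene finder.
- The built-in aligner's E-values are dialect-approximate (documented
  above); threshold decisions near τ₂ can differ from BLASTN's.
- The equal-probability hypergeometric null ignores cluster-size
  variation, as stated.
- Single-label output per rank: polyvalent (broad-host-range) phages are
  reported with one taxon per rank only.
- No post-hoc calibrators (e.g. temperature scaling); calibration is
  trained in via the ECE term only.
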