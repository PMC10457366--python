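# Methods

## The problem

Geometric graph neural networks (GGNNs) operate on residue-level protein
graphs: N nodes at the Cα positions **x** ∈ ℝ^{N×3} carrying
roto-translationally invariant scalar features **h** ∈ ℝ^{N×ψ_h}
(residue classes and the like). Because every quantity such a network
sees is invariant to rigid motions — and, for message passing, local —
the *sequence position* of a residue is invisible unless it is encoded
into the features. This package implements (i) the graph-construction
and feature-injection machinery that puts per-residue protein
language-model (PLM) representations **h′** ∈ ℝ^{N×ψ_PLM} onto graph
nodes, (ii) a desk-scale experiment demonstrating the position
blindness and its rescue, and (iii) the evaluation statistics used for
downstream structure-ranking, docking, interface and affinity tasks.

## Graph construction

Three connectivity schemes over Cα coordinates:

* **KNN** (default K = 10): directed edges i→j to the K nearest
  neighbours of i; distance ties break toward the smaller node index so
  edge sets are deterministic. Edges are not symmetrised unless
  requested (`symmetrize=True` adds the reverse closure).
* **r-ball** (default cutoff 8.0 Å): undirected edges for pairs with
  distance strictly below the cutoff, stored in both directions. The
  strict inequality matches the convention used for interface residues.
* **FC**: all N(N−1) ordered pairs.

Edge sets depend on coordinates only through pairwise distances and are
therefore exactly invariant under rotations, translations and
reflections (property-tested over random rigid motions). Cross-chain
complexes are concatenated coordinate lists; chain membership is node
bookkeeping, never a connectivity constraint.

## Sequence–structure reconciliation

Deposited structures are usually incomplete, so the structure-derived
sequence is a fragment of the full-length sequence. Two reconciliation
modes are provided:

* **fragment** (default): embed the fragmentary sequence directly;
* **align**: globally align full vs fragment (Needleman–Wunsch, linear
  gaps, default scores match=1 / mismatch=−1 / gap=−2) and drop
  full-sequence residues aligned to gaps. Mismatch columns are kept —
  only residues absent from the structure are abandoned.

Traceback ties prefer diagonal over a gap in the second sequence over a
gap in the first, fixing one canonical alignment; the score is
oracle-checked against exhaustive enumeration of alignments and against
Biopython's aligner. Positions everywhere are 1-based ranks in the
ordered residue list, never author numbering.

## Embeddings

`EmbeddingProvider` is a deterministic sequence → (N × ψ_PLM) matrix
interface; ψ_PLM defaults to 1280 (the width of the ESM-2 650M model)
but is provider-defined. Real PLM plugins are optional and never
required: the bundled mock provider hashes (seed, residue letter,
position) into pseudo-random rows, so matrices encode identity and
position and are bitwise reproducible — sufficient for every pipeline
contract and for the toy experiment's "embedding as positional
information" regime. Integration modes: `replace` (default for
residue-level graphs), `concat`, and `add` (requires ψ_h = ψ_PLM).
Multi-chain complexes are embedded per chain and concatenated node-wise,
since sequence models are trained on single chains.

## The reference network

The toy conclusions rest on symmetry, not on a specific architecture,
so the reference model is the minimal network with the right
invariances: L = 2 rounds of message passing where the message on edge
(i, j) is `tanh(W_m [h_i; h_j; d_ij²/s] + b_m)` (s = 100 Å² keeps tanh
responsive for 4–12 Å edges), aggregated (mean) over in-edges, followed
by a tanh update; the readout concatenates input features with the
final hidden state, standardises, and applies a one-hidden-layer ReLU
MLP (192 units) producing class logits or a scalar per node.

The geometric encoder's weights stay frozen at their seeded random
initialisation; only the readout is trained, by mini-batch Adam
(batch 2048, 300 epochs, lr 0.01, cross-entropy or MSE; regression
targets standardised for conditioning). This random-features design
keeps each run deterministic and ~10 s on one CPU while preserving the
property that matters: any positional signal the readout can exploit
must already be present in the node features or the invariant geometry.
Softmax logits are clamped at −30 below the row maximum — probabilities
below e⁻³⁰ only contribute denormal-range numbers and denormal-speed
arithmetic. A non-finite loss raises a divergence error naming the
epoch. Everything is reproducible from (dataset, config): all
randomness flows from named seeds.

## Synthetic cohort

Real protein backbones are replaced by self-avoiding 3D random walks:
consecutive Cα atoms exactly 3.8 Å apart (the canonical trans-peptide
spacing), turning angles bounded at 75° from the previous step
direction, and non-consecutive residues kept ≥ 3.0 Å apart by rejection
sampling (per-step retries, then whole-chain restarts, then a generator
error suggesting looser constraints). Residue letters are uniform over
the 20 standard amino acids. The default cohort is 300 chains with
lengths uniform in [30, 80], split 240/30/30 by seeded shuffle — small
enough to train in minutes on one CPU, long enough that per-residue
chance accuracy E[1/N] ≈ 2% is well separated from the informed regime.

What the generator does *not* emulate: secondary structure, residue-
dependent local geometry, realistic length distributions, or any
sequence–structure correlation. That is deliberate — the experiment's
logic only needs geometry that carries no positional information beyond
chain connectivity, and a real PDB cohort would merely add nuisance
structure. Passing results therefore demonstrate the information-flow
argument, not performance on real proteins.

## The two tasks and the feature regimes

* **APR** (absolute position recognition): classify each residue's
  1-based index; classes run to the cohort's maximum length and
  positions beyond a chain's length simply never occur as labels;
  metric is accuracy.
* **RPE** (relative position estimation): regress each residue's
  minimum distance to the two chain ends, counted in residue steps
  (min(i−1, N−i); ends score 0); metric is RMSE. Residue steps, not Å,
  because the task probes sequence position; the boundary value 0 is
  canonical since any constant offset is absorbed by the model.

Feature regimes: `structure_only` is the 21-class residue one-hot;
`with_embedding` swaps in per-residue embeddings (replace mode);
`with_index` appends an explicit positional block
[i/S, (N−i+1)/S, sin/cos(2πk·i/S), k ≤ 4] with S the cohort maximum
length. The forward *and reverse* scaled indices are the design choice
that makes both labels identifiable per node: a single normalised
position i/N cannot determine either the absolute index or the
distance-to-end without knowing N, whereas the pair does (APR reads the
first column; RPE is the min of the two, a piecewise-linear function a
ReLU readout represents exactly). The Fourier terms ease the 80-way
classification.

Each experiment trains three networks with distinct seeds on the same
dataset and reports mean ± population std. The expected signature,
which the acceptance suite asserts on the default cohort: blind APR
accuracy at chance (≈ 2%), informed APR ≈ 100%; informed RPE RMSE a
fraction of a residue step, blind RPE RMSE more than an order of
magnitude larger (≈ 11 steps, roughly the label standard deviation);
and the informed regime dominates run by run.

## Evaluation metrics

* **Ranking** (structure quality assessment): per-target "mean" and
  pooled "global" Spearman, Pearson and Kendall correlations — the
  mean/global split follows the CASP community convention, since the
  column names alone do not define it. Kendall is tau-b (tie-corrected);
  Spearman uses average ranks. Targets with one model are excluded from
  per-target averages with a warning; zero-variance targets contribute
  0 (not NaN, not dropped) so aggregation stays deterministic. The true
  quality score (e.g. GDT-TS) is always consumed as input, never
  computed.
* **First Rank Loss**: per target, max(true) − true(argmax pred),
  averaged; prediction ties break toward the smaller model id.
* **AUROC**: Mann–Whitney pair counting with ties worth ½, computed via
  mid-ranks; undefined (error) for single-class input.
* **pK transform**: −log₁₀ K, K in molar.
* **Kabsch**: SVD superposition returning a proper rotation
  (det = +1; the reflection branch is corrected), translation and RMSD;
  collinear inputs warn but still solve.
* **Docking RMSDs**: the default `fixed_receptor` convention compares
  coordinates in the frame where true and predicted receptors coincide
  — no superposition of the compared sets; the `kabsch` convention
  superposes each compared set first and is provided for cross-checks
  (its RMSDs lower-bound the fixed-receptor ones). Interface residues
  are those in any cross-molecule Cα–Cα pair strictly closer than 8 Å
  in the ground-truth complex; the threshold is exposed because
  residue-level graphs only see Cα distances.

## Numerical and degenerate-input choices

KNN ties → smaller index; r-ball strictly `<`; altloc → highest
occupancy, ties alphabetical; residues without Cα dropped with a
warning; HETATMs skipped except MSE (kept, coded 'X'); model 1 only by
default (multi-model NMR files would duplicate residues); empty chains
are lookup errors rather than empty sequences; embedding/feature row
mismatches raise an error that points to reconciliation rather than
guessing an alignment.

## Reproducibility

Every run is a strict flat config (unknown keys rejected); outputs are
sorted-key JSON/TSV with no timestamps; a manifest records the config
snapshot, package version and SHA-256 checksums of inputs and outputs.
Re-running a manifest with the same seeds reproduces deterministic
outputs bitwise and trained results exactly (fixed training seeds).

## Known limitations

Residue-level graphs only (no atom-level graphs, no edge features —
distances enter the reference network directly); no affine gap
penalties or MSA alignment; no real-PLM weights, downloads, or
fine-tuning; the reference network is not a reimplementation of any
published GGNN architecture and its absolute numbers are not comparable
to benchmark results on external datasets; the synthetic cohort is a
stand-in, not a PDB subset.
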