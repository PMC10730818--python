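# Methods

## The segmentation model

`domseg` casts protein domain segmentation as bottom-up residue clustering.
A backbone structure enters the network as three channels: a single
representation (the 20-class one-hot sequence projected to 512 dimensions),
a pairwise representation (the CA–CA distance map embedded to 32 dimensions
by a linear layer), and per-residue rigid frames built by Gram–Schmidt
orthogonalisation of the N–CA–C atoms (rotation columns e1 = C−CA
normalised, e2 the orthogonalised N−CA direction, e3 = e1 × e2; translation
= CA).

The encoder applies one invariant point attention (IPA) block six times with
shared weights. The block follows the AlphaFold2 IPA contract — scalar
attention with 16 heads, an additive pair bias, and frame-local point
attention whose squared point distances are weighted by per-head softplus
gates — but the frames are read-only: the network reads a structure into a
latent representation instead of refining coordinates. Rotary positional
encoding (RoPE, base 10 000) is applied to the scalar queries and keys only;
the points already carry geometry through the frames, so rotating them would
double-encode position. Because attention sees only frame-local quantities
and inter-point distances, the updated single representation is invariant to
global rigid motions of the input (verified to < 1e-4 in the tests). In
place of a feed-forward transition, each encoder iteration ends with a
two-layer bidirectional GRU over the residue sequence whose output is
projected back to 512 dimensions, with pre-norm placement and residual
connections.

The decoder concatenates k = 20 learnable domain-mask embedding tokens to
the N residue tokens and runs 10 pre-norm multi-head attention blocks (16
heads). ALiBi positional penalties −slope·|i−j| with the geometric slope
sequence 2^(−8i/h) act between residue tokens only; mask tokens have no
sequence position and receive zero bias. After the stack, residue and mask
tokens are each passed through a linear layer and layer normalisation;
per-residue domain logits are the inner products between the updated single
representation s'' and the conditioned mask embeddings d', scaled by
1/sqrt(512), and a row softmax yields [N, k] domain probability
distributions. Two heads read the decoder output: a two-layer bi-GRU (hidden
256) projecting to two classes per residue, index 0 flagging a non-domain
residue (NDR), and a two-layer bi-GRU (hidden 512) that consumes the k-dim
probability rows of each predicted domain and projects its final state
through a sigmoid to a per-domain pIoU confidence in [0, 1].

### Parameter budget

The published architecture fixes the dimensions named above and the totals
(20.4 M encoder, 16.8 M decoder, ≈37 M overall) but not every internal
width. The free widths are pinned by reconciling the analytic parameter
count with those totals: IPA scalar head dim 16, point query/key 4, point
value 8 (the AlphaFold2 defaults), transition bi-GRU hidden 806, decoder
inner width 368 (16 heads × 23), and 512→512 output projections. This
yields 20,369,744 encoder and 16,833,315 decoder parameters — 20.4 M /
16.8 M at one decimal, 37.2 M total. The weight-shared IPA block is counted
once regardless of encoder depth. A training-only auxiliary linear head
(512→k) used for encoder-side affinity supervision is reported separately
and excluded from that split.

## Training objectives

The ground-truth domain map supervises the network through its co-membership
(affinity) matrix A, with A[i,j] = 1 iff residues i and j share one nonzero
label. Predicted co-membership is P[i,j] = Σ_c p_i[c] p_j[c] and the loss is
the mean binary cross-entropy over unordered residue pairs, excluding pairs
that touch a label-0 residue or a holding-pen-masked residue (CATH's
unfinalised domains). Affinity loss is exactly invariant to permutations of
the ground-truth labels, so the network may use any class index for any
domain. The loss is applied twice — at the encoder output through the
auxiliary head and at the decoder probabilities — matching the two
"IPA and decoder" loss terms of the training recipe. The NDR head takes a
two-class cross-entropy; the pIoU head a mean-squared error against the
achieved IoU of each predicted (cleaned) domain under a
maximum-intersection matching to the ground truth. The exact published loss
formulas live in supplementary material that is not part of this
reconstruction; the forms above are the canonical affinity-learning choices
consistent with the described behaviour, kept behind `composite_loss` so
they can be swapped.

Stage weighting: `initial` sums the four terms with unit weights;
`finetune` doubles both affinity terms; `afdb_ndr` trains the NDR head
cross-entropy alone with every other parameter frozen; `afdb_distill`
trains on the model's own cleaned predictions (self-knowledge distillation)
with proxy-derived NDR labels, scaling AFDB-style targets' total loss by
0.2 while CATH-style targets keep the finetune weighting. Distillation
cleaning removes any domain still below 30 residues (rather than coalescing
it) so the distilled supervision never contains undersized domains or
segments.

Optimisation uses rectified Adam at learning rate 1e-4, minibatch size one,
gradients averaged over 32 accumulated minibatches (averaging rather than
summing keeps the learning-rate meaning independent of the accumulation
count), random contiguous crops of 512 residues, ~30 epochs initial and ~10
finetune. Epochs are dataset passes. Non-finite losses abort with the last
good weights restored.

## Post-processing

Raw argmax labels are cleaned deterministically: sweeping N-to-C, an
undersized domain (< 30 residues) coalesces as a whole into the preceding
domain — each of its segments takes the label of the nearest preceding
nonzero segment with a different label, the first segment falling back to
the following one — and any segment shorter than 10 residues coalesces the
same way on its own; sweeps repeat to a fixed point because one merge can
push a neighbour below threshold. Label-0 stretches are transparent to
"preceding" and are never created or consumed; a chain whose only label is
undersized stays a single domain (a 25-residue protein is still one
domain). When label-0 gaps isolate a short stretch whose only possible
merge targets alternate, the iteration stops at the first revisited state;
this cannot occur on the dense label vectors produced at inference.

At full-chain inference only, residues sharing a label whose spatial
clusters are more than 10 Å apart (minimum CA–CA distance; ≤ 10 Å is "in
contact") are split into separate domains via connected components of the
label-restricted contact map. The predicted NDR mask then zeroes its
positions, labels are renumbered 1..ndom by first residue, and each split
component inherits its parent label's pIoU.

## Evaluation

Per-domain IoU uses a one-to-one maximum-total-intersection matching
(Hungarian assignment) between predicted and true domains; matched pairs
score |∩|/|∪| over residue sets restricted to ground-truth domain residues
(truth label 0 is excluded everywhere; predicted-NDR residues inside true
domains count against the union), unmatched true domains score 0, and the
per-target summary weights each true domain by its length. Corpus-level
summaries pool the same length weighting over all true domains of all
targets — the natural corpus extension of per-target length weighting.
Boundary MCC treats the N−1 inter-residue junctions as the decision set:
predicted and true boundaries are matched one-to-one greedily by increasing
separation with a ±m tolerance (m = 20), giving TP/FP/FN, TN the remaining
junctions, and the standard Matthews coefficient (0 when a marginal is
empty). Domain-count MAE and under/over tallies, and best-of-two-references
scoring (keep whichever ground truth yields the higher weighted IoU, ties to
the first), complete the report.

Baselines estimate the domain count by Domain-Guess-by-Size, reduced to its
essence: max(1, round(n/125)) — one domain per ~125 residues, the constant
exposed in `domseg.baselines`. Targets are then cut into equal or unequal
contiguous segments or labelled per-residue at random.

## NDR proxy and dataset splitting

On predicted models, NDR ground truth comes from a proxy: plDDT < 60 AND
population standard deviation of the residue's PAE row < 0.4. The row
statistic is computed over off-diagonal entries: the self-error diagonal is
structurally ~0 and would otherwise dominate the spread of an informative
near-constant high-PAE row, which is the disorder signature the criterion
keys on.

The train/test split builds a graph whose nodes are homologous
superfamilies, with an edge wherever one chain contains domains from two
superfamilies. The largest connected component goes to training; each
remaining component is held out independently with probability 1/20
(seeded Bernoulli — the published fractions are approximate); chains travel
with their components, so no superfamily straddles the split. Redundancy
filtering at 99% sequence identity is performed by a greedy k-mer
containment filter (5-mers, shared k-mers over the smaller set, first
occurrence becomes the representative) — an in-repo stand-in filling the
role an external clustering tool plays in the original pipeline.

## Synthetic fixtures

The generator emulates the geometry that drives the method, not protein
chemistry. Domains are compact self-avoiding walks (CA steps 3.72–3.88 Å,
clash floor 3.6 Å) confined to spheres of radius 2.5·size^(1/3) Å; linkers
and terminal tails are extended directed walks; discontinuous domains place
two sequence-separated parts in one sphere wrapped around an insert domain.
N and C atoms are placed at idealised local geometry around each CA —
frames and distances, not chemistry, feed the network. Confidence fields
are tuned to the NDR proxy deliberately so proxy labelling recovers the
generator's truth exactly (plDDT ~ U(75, 95) for domain residues, U(30, 55)
for NDRs; variable PAE rows for domain residues, near-constant high rows
for NDRs): stage-one fine-tuning needs supervisable proxy labels. Corpus
defaults: domain sizes U(90, 150) residues (CATH-like), domain counts drawn
from {1, 2, 3} with weights (0.2, 0.4, 0.4) — multi-domain emphasis
matching the method's target regime — NDR fraction U(0, 0.3), and a 0.2
probability of a discontinuous first domain (roughly the frequency of
discontinuous domains in curated classifications). Sequences are random, so
passing tests demonstrate geometric clustering, not sequence-profile
learning; real structures add secondary-structure regularity, non-spherical
domains, and annotation noise that these fixtures do not probe.

## Desk-scale configuration and what the tests show

The numerical stack is an in-repo reverse-mode autodiff engine over float64
numpy arrays with a fused, hand-derived backpropagation-through-time bi-GRU
(gradients verified against finite differences to ~1e-7). Everything is
single-threaded and bit-deterministic for a fixed seed.

The scaled-down learning check trains `ModelConfig.tiny()` — single dim 64,
pair dim 8, 4 heads, k = 8, 2 decoder blocks, 3 encoder iterations, GRU
hiddens 32–64 — on 40 fixtures (seed 0) for at most 2,000 accumulated
updates with lr 3e-3, accumulation 1 and crop 256; these problem sizes keep
a full run around ten minutes on one CPU. The crop must be wide enough to
cover the insert of a wrapped domain plus some of both flanking stretches,
or the co-membership of the two stretches is never supervised and the model
falls into a local optimum that places boundaries geometrically but assigns
class indices by sequence position. The affinity loss typically plateaus
near ln 2 (the merge-everything solution) for a few hundred updates before
the clusters separate. On 10 held-out fixtures the run reaches pooled
weighted IoU ≈ 0.94 and NDR accuracy ≈ 0.99 against a random-assignment
floor of ≈ 0.27 (values recomputed by the test suite). The trained model
also assigns both stretches of the canonical wrapped discontinuous fixture
one label with the insert kept separate — a labelling no contiguous-cut
segmenter can reproduce perfectly — though reassembly at this desk scale is
not yet robust across arbitrary wrap geometries.

## Known limitations

Published benchmark results on experimental and predicted-structure sets
require the original trained weights and external databases and are out of
scope. The loss forms and several internal widths are reconstructions
constrained by printed totals, not transcriptions. The PDB reader keeps the
first model and altloc only and drops residues missing any backbone atom;
mmCIF and multi-chain complexes are unsupported. The identity filter is a
k-mer heuristic, not an alignment-based clustering. Fixture realism is
geometric only.
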