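# Methods

## Problem setting and assumptions

The package addresses graph classification on a *fixed atlas*: every sample
is a weighted, undirected, nonnegative graph on the same ordered node set
(connectome-style data: one connectivity matrix per subject over a shared
parcellation), with a class label per sample and, for some or all classes,
a single expert-drawn annotation — a node mask M′_c ∈ [0,1]^N and/or an
edge mask E′_c ∈ [0,1]^{N×N} that is *global*: one mask per class, shared
by all of that class's samples.  The central modelling assumption is that
class-discriminative structure sits at fixed atlas locations, which is what
makes a per-class mask meaningful; the synthetic generator enforces the
same assumption by planting each class's motif on fixed nodes.

Graphs are dense N×N matrices throughout (N is tens of nodes); the loader
treats the upper triangle as authoritative and mirrors it, diagonals are
zero, and node indexing is 0-based everywhere including mask files.
Adjacency weights are passed to the model unchanged (no thresholding or
binarization on input).

## Backbone and saliency

The classifier is the standard GCN layer rule with self-loops and
symmetric degree normalization, ReLU activations, global average pooling
(GAP) over nodes, and a single affine softmax head.  Defaults: 3 conv
layers of width 16, Adam at learning rate 0.001, 200 epochs, full batch.
Full-batch training is deliberate at this scale (tens to hundreds of
samples): the per-class global aggregates used in the loss are then exact
at every step rather than mini-batch surrogates, and runs are
bit-reproducible from one seed.

Local explanations are gradient-flavoured and differentiable in the
weights:

* **gradient** — node n's score is the L2 norm over feature channels of
  ReLU(∂y_c/∂F_n⁽ˡ⁾); the edge (n,m) score is ReLU(∂y_c/∂A_{nm}) with the
  chain rule through the degree normalization, symmetrized as
  (s_{nm}+s_{mn})/2.  The norm is configurable (L1/L2; the choice of norm
  over feature channels is a free parameter of the formulation).
* **guided_bp** — same, with negative upstream gradients zeroed at every
  rectifier during the backward pass.
* **grad_cam** — node scores ReLU(Σ_k α_k F⁽ˡ⁾_{nk}) with channel weights
  α_k = mean_n ∂y_c/∂F⁽ˡ⁾_{nk}; the edge analogue differentiates the total
  CAM mass w.r.t. the adjacency with α held fixed.

y_c is the pre-softmax logit: softmax compresses gradients toward zero on
confidently classified samples, which would starve the supervision signal.

**Explained layer.** The default layer is L−1, not the last conv layer L.
With GAP and an affine head, ∂y_c/∂F⁽ᴸ⁾ is identical for every node (the
pooling distributes the head weights uniformly), so last-layer gradient
node saliency is structurally constant — normalized, it is an all-ones
vector regardless of the input, and supervising it is meaningless.  One
layer below is the deepest layer whose node gradients vary across nodes.
The layer remains a flag for experimentation.

Perturbation- and surrogate-based explainers are out of scope by design:
they require their own inner optimization and cannot be differentiated
end-to-end, which is the property this whole framework rests on.

## Objective

Summed over classes: L_Pred,c (that class's share of the mean
cross-entropy) + αₙ·dist(M_c,M′_c) + αₑ·dist(E_c,E′_c) +
β·Ω^con + γ·Ω^s, with `dist` the mean elementwise absolute (default) or
squared difference.  M_c and E_c are max-normalized into [0,1] before the
loss so they are commensurate with the binary masks; the normalizing max is
detached, so gradients flow through the scores but not the scale (uniform
rescaling of saliency is loss-neutral, which prevents trivial shrinkage
from masquerading as progress).  Missing node (edge) masks contribute no
node (edge) term; the two regularizers apply to every class, annotated or
not.

Defaults: αₙ=1, αₑ=0.1, β=0.1, γ=0.01.  The guiding principle is that no
explanation term may dominate the prediction loss.  αₑ sits an order of
magnitude below αₙ because the edge target is much sparser than the node
target (O(N) motif edges among N² entries): at αₑ=1 the cheapest descent
direction is to deaden the network's input sensitivity outright — all edge
saliency collapses to zero and prediction degenerates to chance.  This was
observed directly on the synthetic conditions; αₑ=0.1 keeps the edge term
active without that failure mode.  All four weights are configuration.

The supervised fine-tune defaults to 2× the baseline epoch count: the
explanation loss moves second-order quantities (gradients of gradients), a
slower process than fitting logits at the same learning rate.

## Concept-based global explanation

Binarization keeps the ⌈top_fraction·nnz⌉ highest-scoring edges of a local
edge explanation (default top_fraction 0.25; ties broken by lexicographic
node-pair order; all-zero maps are flagged degenerate and excluded).  The
kept subgraph is encoded by a 2-layer graph convolution over one-hot node
identities with mean pooling over kept nodes — permutation-*aware* on
purpose: on a fixed atlas, *which* nodes participate is signal, and
identical subgraphs embed identically.  Soft assignment to m prototypes is
softmax(−d) with Euclidean d (ties in hard assignment go to the lowest
index).

The explainer is fitted by minimizing: logic-layer cross-entropy against
the backbone's predictions + prototype pull and cover distance terms + an
entropy penalty sharpening assignments + L1 on the logic weights (600
epochs, Adam 0.01).  Formulas are read off the trained logic layer
exactly: all 2^m Boolean prototype patterns are classified, patterns never
observed in training are treated as don't-cares, and the claimed minterms
are minimized to DNF (exact at these m; presets m=4 and m=2 are recorded
for cortical-cohort and case-control-style tasks respectively).  Since node
masks encode presence, a minimized formula with no positive literal falls
back to the plain DNF of observed minterms.  The class formula is projected
to node space by taking, per positive prototype, the membership-weighted
mean node indicator of its cluster, combining ∨ by elementwise max and ∧
by elementwise min, and max-normalizing.  Negated literals contribute no
mass.

### Iterative training

Concept mode runs: (1) plain training; (2) one explainer fit, whose
encoder, logic layer and formulas are then *frozen*; (3) prototypes are
re-initialized uniformly at random and the backbone is fine-tuned under the
full objective while the prototypes update against the frozen explainer's
own objective (logic cross-entropy + a soft-k-means distance whose fixed
point is the membership-weighted cluster centroid + a small cover term
preventing dead prototypes), finishing with a prototype-only refinement at
the explainer's learning rate.  Step (3) repeats until the maximum
prototype displacement between consecutive rounds falls below 10% of the
mean inter-prototype distance (max 10 rounds; non-convergence returns the
best state with a flag rather than raising).

Two design choices here were forced by implementation experience.  First,
the encoder is fit once and frozen rather than re-fit each round: re-fitting
re-draws the embedding space itself, making "prototype displacement across
rounds" incommensurable.  Second, the convergence tolerance is *relative*:
the backbone continues to take optimizer steps every round, so embeddings —
and hence the prototype fixed point — jitter at a few percent of the
prototype spread indefinitely; an absolute threshold of order 10⁻³ is
unattainable in principle, while the relative criterion detects the actual
fixed point (in practice reached by the second round on separable data).
Within step (3) the prototype terms see detached embeddings, so this
auxiliary signal moves only the prototypes, never the backbone.

## Synthetic data

The generator emulates the structure of restricted connectome cohorts, not
their marginal statistics: a fixed atlas of N nodes; per class a planted
motif (clique, cycle, or star) at class-specific, disjoint, fixed node
subsets with edge weight max-combined into an Erdős–Rényi-style background
(edge presence with probability `background_density`, weights uniform on
(0, `background_weight_scale`), matching row-normalized nonnegative
connectivity values in spirit); optional truncated symmetric Gaussian noise;
binary class masks marking motif members.  Node features default to
weighted degree plus a constant column — real cohorts rarely publish their
node features, and degree makes connectivity motifs visible to a GCN.
Defaults N=12, Z=60, C=2 (a 4-clique class vs a 4-cycle class),
density 0.2, weight scale 0.5, noise 0.

What passing on this data does and does not show: motifs here are
noise-free in location (always the same nodes), perfectly class-pure, and
structurally simple, so recovery results demonstrate that the supervision
machinery steers saliency correctly — not that it would overcome
between-subject anatomical variability, site effects, or annotation noise
in real cohorts.

## Canonical studies (`ggnes.studies`)

* **Mask recovery** — N=12, Z=60, clique vs cycle, 80/20 stratified split,
  5 paired seeds; baseline (no supervision) vs `mode="avg"` with αₙ=1,
  αₑ=0 — node-level supervision only, mirroring cohorts whose expert
  annotation marks regions rather than connections (the node-mask-only
  regime); β=0.1, γ=0.01.  Reported: per-seed node MAE and test ACC for
  both arms, win fraction, ACC-preserved fraction (within 0.05).
* **Concept sanity** — noiseless N=12, Z=40, m=2; purity and fidelity of
  the fitted explainer on training subgraphs, then convergence of the full
  iterative loop (5 outer rounds max, 60 fine-tune epochs per round — the
  scaled-down problem sizes chosen for desk-scale runs).

Both studies are what `scripts/acceptance.py` recomputes end to end.

## Numerical choices and degenerate inputs

* Reverse-mode autodiff engine with VJPs expressed in engine ops, so
  second-order gradients (loss through saliency) are exact; verified
  against central finite differences.  ReLU's derivative mask is treated as
  locally constant (the standard subgradient convention); min/max propagate
  through the selected element, first index on ties.
* Softmax/log-sum-exp use a detached max shift for stability.
* The L2 feature norm uses a masked square root: exactly zero (with zero
  gradient) where the rectified gradient vanishes.
* All-zero explanations are returned unnormalized (zero vector), and
  all-zero edge-score maps binarize to a flagged-degenerate subgraph that
  is excluded from clustering and counted.
* Finite-difference test oracles exclude stencil entries that straddle a
  ReLU kink (detected by halving the step), where central differences are
  not estimates of the one-sided derivative the engine computes.
* One integer seed drives data generation, weight initialization,
  prototype re-initialization and splits; training is full batch, so runs
  are bit-reproducible.

## Known limitations

* Dense N×N computation throughout: appropriate for atlas-scale graphs
  (N ≲ a few hundred), not for large sparse graphs.
* Edge supervision is structurally prone to saliency collapse when weighted
  aggressively (see αₑ above); the default mitigates but does not remove
  the tension.
* Concept-mode backbone gradients flow through the kept edges' continuous
  scores only — the discrete binarization boundary itself is not
  differentiated, so the explanation loss cannot move an edge into or out
  of the kept set directly; in practice the avg-aggregated edge term and
  the prediction loss do that reshaping.
* The logic layer is linear over concept activations; formulas requiring
  XOR-like structure over prototypes are not representable exactly.
* An alternative message-passing backbone can be swapped in behind the
  explainer API (which only needs layer activations and input gradients),
  but none is bundled.
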