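# Methods

This note documents the model implemented by `s3rl`, the choices made where
the design was genuinely open, and what the synthetic fixtures do and do not
establish about behavior on real tissue.

## Problem setting

Spot-based and imaging-based spatial transcriptomics assign each capture
location ("spot") a gene-expression vector, a 2-D pixel coordinate, and —
on platforms with a histology scan — an image patch. The package learns,
without supervision, (i) a latent embedding per spot, (ii) a partition of
spots into `c` spatial domains, and (iii) a denoised ("enhanced")
reconstruction of the expression matrix. The central assumptions are that
spatially adjacent spots tend to share a domain, that histological
appearance correlates with domain identity, and that expression similarity
is informative but noisy (dropout, overdispersion).

## Preprocessing

Counts are library-size scaled to a fixed total (default 10⁴) per spot and
log1p-transformed. Scaling can be disabled (`library_scale=False`) for a
bare log transform; the scaled variant is the default because the
downstream losses are cosine-based and per-spot depth differences would
otherwise dominate angles. Highly variable genes are ranked by a
Seurat-flavor normalized dispersion (variance/mean, z-scored within 20
equal-width mean bins; singleton or zero-spread bins fall back to the
global z-score; scores rounded to 10 decimals, ties to the lower gene
index) so selection is deterministic and reproducible without an external
toolkit; a cross-check against the scanpy routine is part of the test
suite. The default of 3,000 HVGs matches common practice; targeted panels
with fewer genes keep all of them.

Patches are `size × size × 3` crops centered on each spot (16 px default,
matching spot-level platforms; 40/60 px suit imaging platforms). Even patch
sizes use the floor convention — the central pixel pair brackets the
coordinate — and border patches are completed by reflection padding rather
than zero padding, which would otherwise inject black corners into the
contrastive similarity structure.

## Visual semantics

A convolutional encoder with an MLP projection head is trained with the
NT-Xent objective (temperature 0.5, Adam, learning rate 0.005, weight decay
1e-6, batch 256) on pairs of augmented views (random resized crop with area
0.6–1.0, horizontal/vertical flips at p = 0.5, color jitter 0.4 in
brightness/contrast/saturation). The denominator convention is the
standard one — all 2N−1 non-self views; a `paper_printed` switch drops the
positive pair from the denominator, which changes only the normalization.
After training, the 256-d features of the *un-augmented* patches become the
spot's visual embedding; embedding the raw patch (rather than one stochastic
view) keeps the output deterministic.

The default backbone, `tiny_cnn`, is a compact two-conv-layer encoder
(3→8→16 channels, stride 2, ELU) trained from scratch. At patch scale the
discriminative content is color and coarse texture, which this capacity
captures; a `pretrained_resnet50` slot exists for environments that provide
local weights. All gradient training in the package runs on an in-package
reverse-mode autodiff core over numpy (float64), which keeps runs
bit-reproducible on one CPU; its gradients are verified against central
differences in the test suite.

## Signed graph

The spatial graph connects each spot to its k nearest neighbors (Euclidean,
union-symmetrized). k = 6 by default, the coordination number of the
hexagonal packing used by the dominant spot-based platform; it is exposed
in config because square-lattice data has a natural 4-neighborhood.
Semantic edges are added per modality: each spot gains a positive edge to
its `n_pos` most cosine-similar spots and a negative edge to its `n_neg`
least similar (defaults 1 and 1, reading "highest similarity" as top-1;
Pearson similarity available in config). The full pipeline overrides the
counts for the *visual* modality to 3 positive and 3 negative edges per
spot: on data with informative histology, patch-embedding similarity is a
far cleaner domain signal than dropout-ridden expression similarity (on
the synthetic benchmark its top-3 edges are essentially always
within-domain while expression top-1 edges are right only about two thirds
of the time), so densifying the visual edge set adds long-range
same-domain connectivity without adding noise — expression stays at the
top-1 reading. The positive union with the spatial edges forms E′; the
negative union minus any pair already in E′ forms E−. Dropping contradicted negatives means no pair is simultaneously
attracted and repelled by the structure loss. All rankings break ties
toward the lower index, so graph construction is bit-reproducible and
permutation-equivariant.

## Representation learning

Encoder and decoder are each two gated graph-transformer layers
(m → 128 → 64 and mirrored):

    z_i ← ELU( β_i · W1 z_i + (1 − β_i) · Σ_{j∈N_i} α_ij W2 z_j )

with α from scaled dot-product attention over the E′ neighborhood and β_i a
sigmoid gate on a learned linear map of (self-transform, aggregate,
difference). Nodes without neighbors aggregate the zero vector. During
training, ⌊0.1·n⌋ spots per epoch have their profiles replaced by a shared
learnable mask token; reconstruction is scored on all spots by default
(`loss_on="masked_only"` restricts it), with the mean cosine error
L_rec = mean_i (1 − cos(x_i, x̃_i)). The signed structure loss

    L_topo = Σ_{E′} −log σ(z_i·z_j) + Σ_{E−} −log(1 − σ(z_i·z_j))

is evaluated through softplus (no overflow up to |z_i·z_j| ≈ 1e4), each
undirected edge counted once, unnormalized as printed; a mean-reduction
option exists. Zero-norm rows in the cosine loss contribute 1
(orthogonality convention), guarded by ε = 1e-12 inside the autodiff path.

## Hyperspherical prototype clustering

`c` unit prototypes are pre-placed by minimizing a log-sum-exp surrogate of
the maximal pairwise inner product (sharpness ramped 10→200 geometrically,
step size 0.1→0.01, tangent-projected gradient, row renormalization each
step, 2000 steps). For c ≤ d+1 this reaches the regular-simplex optimum
−1/(c−1) to well within 0.01. Embeddings are row-normalized and aligned by
a learnable rotation R (initialized at identity, kept orthogonal by
polar-decomposition retraction after every step; the tested invariant is
‖RᵀR−I‖_F ≤ 1e-3). Affinities are softmax over embedding–prototype inner
products and labels are the row argmax (ties to the lower prototype index).

Two scalars in this head were open design choices:

- **Concentration.** Inner products of unit vectors lie in [−1, 1], so a
  bare softmax over them is nearly uniform and provides almost no gradient
  to R. Inside the training objective the dots are scaled by a
  concentration κ = 10 (a von-Mises–Fisher-style inverse temperature).
  Labels are argmax-invariant to κ, and the standalone affinity operation
  keeps the plain softmax.
- **Separability regularizer.** The implemented form is
  L_clu = (√c − n^{−1/2} Σ_j ‖y_·j‖₂)/(√c − 1), the unique natural
  normalization that is 0 exactly at hard, balanced assignments and 1 at
  uniform affinities — matching the stated intent (confident assignments,
  even occupancy, no empty clusters). A raw −Σ‖y_·j‖₂ objective is
  available in config for sensitivity checks.

Prototypes update dynamically: every 100 epochs after a 150-epoch warmup,
each prototype's affinity column is compared to its ideal column (ones at
its ⌊n/c⌋ strongest spots — the best attainable ideal — zeros elsewhere;
both ε-smoothed at 1e-8 and L1-normalized) via KL divergence (direction
current‖ideal by default, switchable), scaled by t = 0.1, and the prototype
is perturbed by N(0, d_j·I) and renormalized, with t = 0.1 keeping jumps
commensurate with unit vectors (at t = 1 a prototype can jump across the
sphere and the rotation never settles).

Three refinements make the update signal target actual misfit. First, the
KL deviation has a data-dependent floor — a soft softmax column never
matches a binary ideal, and on tissue with uneven domain sizes a perfectly
settled large domain deviates from the ⌊n/c⌋-ones ideal simply by being
large — so the best-fitting prototype's deviation is subtracted and only
the excess drives the perturbation. Second, updates fire only for
prototypes that have gone near-empty (holding under a quarter of the
balanced share n/c): an empty cluster is precisely the failure mode the
mechanism exists to correct, whereas perturbing a settled prototype whose
domain is merely bigger or smaller than n/c only injects noise. Third, the
variance is annealed by (1 − epoch/epochs) — exploration early, refinement
late — and updates stop one update-interval before the end of training so
the rotation can re-align after the final jump. Prototype-update noise
also draws from its own random stream, so enabling or disabling dynamic
updates does not perturb the masking draws of an otherwise identical run.

The total objective is L = L_rec + λ1·L_topo + λ2·L_clu with λ1 = 1 and
λ2 = 0.3 by default — the separability term exists to align and sharpen
assignments, and a larger weight visibly distorts embeddings toward
equal-occupancy clusters when true domain sizes are uneven — optimized by
Adam (lr 1e-3 for the network and mask token;
lr 0.02 for R, which otherwise tracks the moving embedding too slowly) for
at most 2000 epochs (400 by default at desk scale; optional plateau early
stopping, off by default). Ablation switches reproduce the model variants:
no visual edges (graph built from expression only), frozen prototypes (no
dynamic updates), or both.

## Synthetic fixtures

The generator emulates the study conditions the model targets: spots on a
`rows × cols` lattice; domains as Voronoi regions of c random lattice seeds
(re-seeded until every domain is 4-connected — spatially contiguous, so the
spatial graph is genuinely informative); negative-binomial counts
(gamma–Poisson, dispersion θ = 2) with base mean 2 and per-domain marker
blocks (10 genes per domain by default) elevated by a natural-log fold
change of 2; independent Bernoulli dropout (0.3) zeroing observed counts;
and patches whose mean RGB is a domain hue mixed toward neutral gray by
1 − separation (0.8 default) plus Gaussian pixel noise (sd 12). Identical
configs (including seed) produce bit-identical datasets, and ground-truth
labels are stored for evaluation only — training code never reads them.

What the fixtures do *not* emulate: real histology morphology (nuclei,
texture at multiple scales), segmentation errors, spatially varying capture
efficiency, batch effects, or curved/irregular tissue boundaries. Passing
the recovery tests therefore demonstrates that the machinery works end to
end under controlled signal, not that the headline accuracy transfers to
any particular real dataset.

## Evaluation

Clustering accuracy is the adjusted Rand index (chance-corrected, computed
from the contingency table; verified against exhaustive pair counting).
For ligand–receptor analyses the package implements the quadrant summary
metrics only — significance values per L-R pair (−log10 FDR scale, from an
external communication model) are supplied as a table, classified at a
threshold (default −log10 0.05) into newly-significant (top-left),
consistently significant (top-right), lost (bottom-right) and never
significant (bottom-left), and summarized as ESR = N_tl/N_br,
EEP = 100·N_tl/(N_tl+N_br), SSP = 100·N_tr/(N_tr+N_br). Zero denominators
yield explicit sentinels (inf / null) rather than silent NaN.

The enhanced matrix is the decoder output in the log-normalized HVG space;
negative values may occur (the cosine loss does not constrain sign) and
clipping to zero is opt-in for downstream tools that require non-negative
expression.

## Problem sizes and numerical choices

Desk-scale defaults — 900 spots, 200 genes, 400 training epochs, 40
contrastive epochs — were chosen so a full run completes in a few minutes
on one CPU core; all of them scale up through config. Numerical guards:
softplus for every log-sigmoid, ε = 1e-12 under square roots of norms,
ε = 1e-8 KL smoothing, detached max-shifts inside every softmax, and SVD
retraction for R. Known limitations: no multi-slice alignment, no
count-likelihood (NB/ZINB) decoder, no automatic selection of c, no
multi-head attention, and the tiny backbone is not a substitute for a
pretrained encoder when real histology texture matters.

One limitation deserves emphasis because it is intrinsic to the objective
rather than to scale: the separability regularizer rewards even occupancy
across prototypes, so when one true domain holds roughly half of all spots
the regularizer's optimum *splits* that domain between two prototypes even
when the latent embedding separates domains nearly perfectly (k-means on
the same embedding recovers them). On synthetic tissues this appears once
domain-size imbalance passes ≈45% of spots for the largest domain;
weakening λ2, sharpening or softening the affinity, and longer training do
not remove it, because the balance term's preference for splitting
oversized clusters is by construction. Users with visibly dominant domains
should compare the end-to-end labels against an external clustering of the
exported embedding.
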