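"""Hyperspherical prototype clustering and the end-to-end training loop.

Clusters are represented by c unit-norm prototype vectors pre-placed on the
latent hypersphere to be maximally separated (the pairwise inner-product
optimum for c ≤ d+1 is the regular simplex value −1/(c−1)).  Embeddings are
row-normalized and aligned to the prototype frame by a learnable orthogonal
rotation R; softmax over embedding–prototype inner products gives a
row-stochastic affinity matrix, whose argmax is the cluster label.  A
separability regularizer drives affinities toward confident, balanced
assignments, and prototypes are periodically perturbed by a Gaussian whose
variance is the (scaled) KL divergence between each prototype's current
affinity column and its ideal balanced column — large deviations move, good
prototypes stay put.

The combined objective is  L = L_rec + λ1·L_topo + λ2·L_clu.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import SpatialDataset
from .graph import SignedGraph, build_signed_graph
from .gtn import (GTNAutoencoder, GTNConfig, mask_spots,
                  reconstruction_loss_t, topological_loss_t)
from .nn import Adam, Parameter, Tensor, take_rows
from .visual import VisualFeatures

__all__ = [
    "ClusterLossConfig",
    "TrainConfig",
    "TrainResult",
    "place_prototypes",
    "project_to_sphere",
    "compute_affinity",
    "assign_labels",
    "clustering_loss",
    "prototype_deviation",
    "update_prototypes",
    "total_loss",
    "train",
]


@dataclass
class ClusterLossConfig:
    lambda1: float = 1.0
    lambda2: float = 0.3
    t: float = 0.1
    update_every: int = 100
    warmup_epochs: int = 150
    kl_epsilon: float = 1e-8
    max_epochs: int = 2000
    kl_direction: str = "current_ideal"  # or "ideal_current"

    def __post_init__(self):
        if self.max_epochs > 2000:
            raise ValueError("max_epochs is capped at 2000")
        if self.t <= 0:
            raise ValueError("t must be > 0")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("loss weights must be ≥ 0")


# ---------------------------------------------------------------------------
# prototype geometry
# ---------------------------------------------------------------------------

def place_prototypes(c: int, d: int, steps: int = 2000, seed: int = 0) -> np.ndarray:
    """c unit vectors in R^d minimizing the maximal pairwise inner product.

    Descends a log-sum-exp surrogate of max_{i≠j} p_i·p_j, with the
    sharpness γ ramped geometrically from 10 to 200 and the step size
    decayed from 0.1 to 0.01; gradients are projected onto the sphere's
    tangent space and rows renormalized after every step.  For c ≤ d+1 the
    optimum is the regular simplex with all pairwise dots −1/(c−1).
    """
    if c < 2:
        raise ValueError("need at least 2 prototypes")
    if d < 2:
        raise ValueError("latent dimension must be ≥ 2")
    rng = np.random.default_rng(seed)
    P = rng.standard_normal((c, d))
    P /= np.linalg.norm(P, axis=1, keepdims=True)
    off = ~np.eye(c, dtype=bool)
    for step in range(steps):
        f = step / max(steps - 1, 1)
        gamma = 10.0 * 20.0**f
        lr = 0.1 * 0.1**f
        G = P @ P.T
        logits = gamma * G[off]
        w = np.exp(logits - logits.max())
        w /= w.sum()
        W = np.zeros((c, c))
        W[off] = w
        grad = (W + W.T) @ P  # d/dP of Σ w_ij p_i·p_j
        grad -= (grad * P).sum(axis=1, keepdims=True) * P  # tangent projection
        P -= lr * grad
        P /= np.linalg.norm(P, axis=1, keepdims=True)
    return P


def project_to_sphere(Z: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Row-normalize embeddings and rotate into the prototype frame."""
    Z = np.asarray(Z, dtype=np.float64)
    norms = np.linalg.norm(Z, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero-norm embedding rows (collapsed training)")
    return (Z / norms) @ np.asarray(R)


def compute_affinity(Z_tilde: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Softmax over embedding–prototype inner products; rows sum to 1."""
    dots = np.asarray(Z_tilde) @ np.asarray(P).T
    dots -= dots.max(axis=1, keepdims=True)
    e = np.exp(dots)
    return e / e.sum(axis=1, keepdims=True)


def assign_labels(Y: np.ndarray) -> np.ndarray:
    """Argmax over prototypes; ties break toward the lower prototype index."""
    return np.argmax(np.asarray(Y), axis=1)


def clustering_loss(Y: np.ndarray) -> float:
    """Separability regularizer in [0, 1].

    (√c − n^{−1/2} Σ_j ‖y_·j‖₂) / (√c − 1): 0 at hard, exactly balanced
    assignments; 1 at uniform affinities.  Column norms of a row-stochastic
    matrix satisfy √(n/c) ≤ Σ_j ‖y_·j‖₂/√c ... the bound giving [0, 1]."""
    Y = np.asarray(Y, dtype=np.float64)
    n, c = Y.shape
    if c < 2:
        raise ValueError("clustering loss needs at least 2 prototypes")
    col = np.linalg.norm(Y, axis=0).sum()
    return float((np.sqrt(c) - col / np.sqrt(n)) / (np.sqrt(c) - 1.0))


def clustering_loss_t(Y: Tensor) -> Tensor:
    n, c = Y.shape
    col = (((Y * Y).sum(axis=0)) + 1e-30).sqrt().sum()
    return (np.sqrt(c) - col / np.sqrt(n)) / (np.sqrt(c) - 1.0)


def prototype_deviation(Y: np.ndarray, j: int, t: float = 1.0,
                        kl_epsilon: float = 1e-8,
                        direction: str = "current_ideal") -> float:
    """Scaled KL divergence between prototype j's affinity column and its
    ideal balanced column (ones at the ⌊n/c⌋ strongest spots, zeros
    elsewhere); both are ε-smoothed and L1-normalized."""
    if t <= 0:
        raise ValueError("t must be > 0")
    Y = np.asarray(Y, dtype=np.float64)
    n, c = Y.shape
    col = Y[:, j]
    n_ideal = max(n // c, 1)
    top = np.argsort(-col, kind="stable")[:n_ideal]
    ideal = np.zeros(n)
    ideal[top] = 1.0
    p = (col + kl_epsilon) / (col + kl_epsilon).sum()
    q = (ideal + kl_epsilon) / (ideal + kl_epsilon).sum()
    if direction == "ideal_current":
        p, q = q, p
    return float(t * np.sum(p * np.log(p / q)))


def update_prototypes(P: np.ndarray, deviations: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Perturb each prototype by N(0, d_j·I) (reparameterized as √d_j · η)
    and renormalize to the unit sphere.  d_j = 0 leaves p_j unchanged."""
    P = np.asarray(P, dtype=np.float64)
    d = np.asarray(deviations, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("deviations must be ≥ 0")
    eta = rng.standard_normal(P.shape)
    out = P + np.sqrt(d)[:, None] * eta
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def total_loss(L_rec: float, L_topo: float, L_clu: float,
               lambda1: float = 1.0, lambda2: float = 1.0) -> float:
    return float(L_rec + lambda1 * L_topo + lambda2 * L_clu)


# ---------------------------------------------------------------------------
# end-to-end training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    n_clusters: int = 4
    epochs: int = 400
    learning_rate: float = 1e-3
    rotation_lr: float = 0.02  # the orthogonal alignment needs larger steps
    # concentration (inverse temperature) applied to embedding–prototype dots
    # inside the training objective; argmax labels are invariant to it
    affinity_concentration: float = 10.0
    topo_reduction: str = "sum"
    gtn: GTNConfig = field(default_factory=GTNConfig)
    cluster: ClusterLossConfig = field(default_factory=ClusterLossConfig)
    prototype_steps: int = 2000
    freeze_prototypes: bool = False  # ablation: no dynamic prototype updates
    early_stop: bool = False
    patience: int = 100
    rel_tol: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be ≥ 2")
        if self.epochs > self.cluster.max_epochs:
            raise ValueError(
                f"epochs={self.epochs} exceeds max_epochs={self.cluster.max_epochs}"
            )


@dataclass
class TrainResult:
    Z: np.ndarray                 # latent embedding, n × d
    labels: np.ndarray            # end-to-end cluster labels
    X_enhanced: np.ndarray        # decoder reconstruction in the HVG space
    prototypes: np.ndarray        # final prototype set, c × d
    rotation: np.ndarray          # final orthogonal alignment, d × d
    affinity: np.ndarray          # final n × c affinity matrix
    loss_trace: dict = field(default_factory=dict)


def _retract_orthogonal(R: Parameter) -> None:
    """Polar-decomposition retraction: replace R by its nearest orthogonal
    matrix after each optimizer step."""
    U, _, Vt = np.linalg.svd(R.data)
    R.data = U @ Vt


def train(dataset: SpatialDataset, graph: SignedGraph | None = None,
          visual: VisualFeatures | None = None,
          config: TrainConfig | None = None) -> TrainResult:
    """Joint representation learning and clustering.

    ``dataset.X`` must already be log-normalized and restricted to the
    training gene space.  If ``graph`` is None it is built from the dataset
    (and ``visual``, when given).  Ablations: build the graph without visual
    features to drop the histology branch; set
    ``config.freeze_prototypes=True`` to disable dynamic prototype updates.
    Identical seeds and configs give bit-identical results on one device.
    """
    config = config or TrainConfig()
    X = np.asarray(dataset.X, dtype=np.float64)
    n, m = X.shape
    if graph is None:
        graph = build_signed_graph(dataset.S, expression=X,
                                   visual=None if visual is None else visual.H)
    if graph.n_nodes != n:
        raise ValueError(
            f"graph has {graph.n_nodes} nodes but dataset has {n} spots"
        )
    c, d = config.n_clusters, config.gtn.d_latent

    rng = np.random.default_rng(config.seed)
    # dedicated stream for prototype updates: masking draws stay identical
    # whether or not dynamic updates are enabled, so model variants differ
    # only through the prototype movement itself
    proto_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    model = GTNAutoencoder(m, config.gtn, rng)
    R = Parameter(np.eye(d))
    P = place_prototypes(c, d, steps=config.prototype_steps, seed=config.seed)

    pairs = graph.directed_pairs("E_prime")
    pos_edges = graph.edge_array("E_prime")
    neg_edges = graph.edge_array("E_minus")

    opt = Adam(model.params, lr=config.learning_rate)
    opt_R = Adam([R], lr=config.rotation_lr)
    cl = config.cluster
    trace = {"total": [], "rec": [], "topo": [], "clu": [],
             "rotation_orthogonality": []}
    best, since_best = np.inf, 0

    for epoch in range(config.epochs):
        X_masked, mask_idx = mask_spots(X, config.gtn.mask_ratio,
                                        model.mask_token.data, rng)
        # rebuild masked input through the learnable token so its gradient flows
        Xt = Tensor(X_masked)
        if mask_idx.size:
            onehot = np.zeros((n, 1))
            onehot[mask_idx] = 1.0
            Xt = Tensor(X * (1 - onehot)) + Tensor(onehot) * model.mask_token
        Z = model.encode(Xt, pairs)
        X_rec = model.decode(Z, pairs)

        if config.gtn.loss_on == "masked_only" and mask_idx.size:
            L_rec = reconstruction_loss_t(take_rows(Tensor(X), mask_idx),
                                          take_rows(X_rec, mask_idx))
        else:
            L_rec = reconstruction_loss_t(Tensor(X), X_rec)
        L_topo = topological_loss_t(Z, pos_edges, neg_edges,
                                    reduction=config.topo_reduction)
        zn = Z / ((Z * Z).sum(axis=1, keepdims=True) + 1e-12).sqrt()
        Y_t = _affinity_t((zn @ R) * config.affinity_concentration, P)
        L_clu = clustering_loss_t(Y_t)
        loss = L_rec + cl.lambda1 * L_topo + cl.lambda2 * L_clu

        opt.zero_grad()
        opt_R.zero_grad()
        loss.backward()
        opt.step()
        opt_R.step()
        _retract_orthogonal(R)

        trace["rec"].append(float(L_rec.data))
        trace["topo"].append(float(L_topo.data))
        trace["clu"].append(float(L_clu.data))
        trace["total"].append(float(loss.data))
        trace["rotation_orthogonality"].append(
            float(np.linalg.norm(R.data.T @ R.data - np.eye(d))))

        # dynamic prototype updates: after warmup, on a fixed cadence, but not
        # inside the final window — the rotation needs time to re-align after
        # each stochastic jump.  The KL deviation carries a data-dependent
        # floor (soft affinity columns vs a binary ideal, honest size
        # deviation from n/c on unbalanced tissue), so raw d_j cannot
        # distinguish a well-settled large domain from a collapsed
        # prototype.  Updates therefore target the pathology the mechanism
        # exists to fix — prototypes that have gone (near-)empty, holding
        # under a quarter of the balanced share — with variance equal to
        # their deviation excess over the best-fitting prototype, annealed
        # linearly over training.  Settled fits are left untouched.
        if (not config.freeze_prototypes and epoch + 1 > cl.warmup_epochs
                and epoch + 1 <= config.epochs - cl.update_every
                and (epoch + 1) % cl.update_every == 0):
            Y_now = compute_affinity(
                project_to_sphere(Z.data, R.data) * config.affinity_concentration, P)
            counts = np.bincount(assign_labels(Y_now), minlength=c)
            starved = counts < n / (4 * c)
            anneal = 1.0 - (epoch + 1) / config.epochs
            devs = np.array([
                prototype_deviation(Y_now, j, t=cl.t, kl_epsilon=cl.kl_epsilon,
                                    direction=cl.kl_direction)
                for j in range(c)
            ])
            devs = starved * anneal * (devs - devs.min())
            P = update_prototypes(P, devs, proto_rng)

        if config.early_stop:
            cur = trace["total"][-1]
            if cur < best * (1 - config.rel_tol):
                best, since_best = cur, 0
            else:
                since_best += 1
                if since_best >= config.patience:
                    break

    # final deterministic forward pass without masking
    Z_final = model.encode(Tensor(X), pairs).data
    X_enh = model.decode(Tensor(Z_final), pairs).data
    Y = compute_affinity(
        project_to_sphere(Z_final, R.data) * config.affinity_concentration, P)
    return TrainResult(Z=Z_final, labels=assign_labels(Y), X_enhanced=X_enh,
                       prototypes=P, rotation=R.data.copy(), affinity=Y,
                       loss_trace=trace)


def _affinity_t(Z_tilde: Tensor, P: np.ndarray) -> Tensor:
    dots = Z_tilde @ Tensor(P.T)
    shift = Tensor(dots.data.max(axis=1, keepdims=True))
    e = (dots - shift).exp()
    return e / e.sum(axis=1, keepdims=True)
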