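"""Graph-transformer autoencoder: gated attention layers, spot masking,
cosine reconstruction loss and the signed topological loss.

Each layer updates a node by gating between its own transformed feature and
an attention-weighted aggregate of its neighbors on the merged positive
graph E′:

    z_i ← σ( β_i · W1 z_i + (1 − β_i) · Σ_{j∈N_i} α_ij W2 z_j )

with σ = ELU, α from scaled dot-product attention restricted to N_i, and
β_i a learned sigmoid gate of (self-transform, aggregate, difference).
Encoder and decoder are each exactly two such layers; the decoder mirrors
the encoder's dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Parameter, Tensor, segment_sum, take_rows

__all__ = [
    "GTNConfig",
    "GTNLayer",
    "GTNAutoencoder",
    "mask_spots",
    "reconstruction_loss",
    "topological_loss",
]


@dataclass
class GTNConfig:
    d_latent: int = 64
    d_hidden: int = 128
    n_heads: int = 1
    mask_ratio: float = 0.1
    loss_on: str = "all"  # or "masked_only"
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.mask_ratio < 1:
            raise ValueError("mask_ratio must be in [0, 1)")
        if self.n_heads != 1:
            raise ValueError("only single-head attention is implemented")
        if self.loss_on not in ("all", "masked_only"):
            raise ValueError("loss_on must be 'all' or 'masked_only'")


class GTNLayer:
    """One gated graph-transformer layer (single head).

    Queries and keys project to ``d_attn = min(d_out, 32)`` dimensions: the
    attention weights only need enough capacity to rank neighbors, and a
    narrow projection keeps wide output layers (e.g. the decoder's gene
    layer) from dominating runtime.
    """

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        def glorot(shape):
            lim = np.sqrt(6.0 / (shape[0] + shape[1]))
            return rng.uniform(-lim, lim, shape)

        self.d_attn = min(d_out, 32)
        self.W1 = Parameter(glorot((d_in, d_out)))       # self transform
        self.W2 = Parameter(glorot((d_in, d_out)))       # neighbor value
        self.Wq = Parameter(glorot((d_in, self.d_attn)))  # attention query
        self.Wk = Parameter(glorot((d_in, self.d_attn)))  # attention key
        # gate: sigmoid of a linear map of [self, aggregate, self − aggregate]
        self.g_self = Parameter(np.zeros((d_out, 1)))
        self.g_agg = Parameter(np.zeros((d_out, 1)))
        self.g_diff = Parameter(np.zeros((d_out, 1)))
        self.g_bias = Parameter(np.zeros(1))
        self.d_out = d_out

    @property
    def params(self):
        return [self.W1, self.W2, self.Wq, self.Wk,
                self.g_self, self.g_agg, self.g_diff, self.g_bias]

    def __call__(self, Z: Tensor, pairs: np.ndarray, activation: bool = True) -> Tensor:
        """`pairs`: (n_directed_edges, 2) array of (src, dst) rows; both
        orientations of every undirected edge must be present.  Nodes with
        no neighbors aggregate the zero vector."""
        n = Z.shape[0]
        self_t = Z @ self.W1
        if pairs.shape[0] > 0:
            src, dst = pairs[:, 0], pairs[:, 1]
            q = Z @ self.Wq
            k = Z @ self.Wk
            logits = (take_rows(q, dst) * take_rows(k, src)).sum(axis=1) / np.sqrt(self.d_attn)
            # softmax over each destination's neighborhood, max-stabilized
            seg_max = np.full(n, -np.inf)
            np.maximum.at(seg_max, dst, logits.data)
            seg_max[~np.isfinite(seg_max)] = 0.0
            ex = (logits - Tensor(seg_max[dst])).exp()
            denom = segment_sum(ex.reshape(-1, 1), dst, n)
            alpha = ex / (take_rows(denom, dst).reshape(-1) + 1e-30)
            values = take_rows(Z @ self.W2, src)
            agg = segment_sum(alpha.reshape(-1, 1) * values, dst, n)
        else:
            agg = Tensor(np.zeros((n, self.d_out)))
        beta = (self_t @ self.g_self + agg @ self.g_agg
                + (self_t - agg) @ self.g_diff + self.g_bias).sigmoid()
        out = beta * self_t + (1.0 - beta) * agg
        return out.elu() if activation else out


class GTNAutoencoder:
    """Two-layer encoder (m → hidden → latent) and mirrored decoder."""

    def __init__(self, n_genes: int, config: GTNConfig,
                 rng: np.random.Generator):
        self.config = config
        self.enc1 = GTNLayer(n_genes, config.d_hidden, rng)
        self.enc2 = GTNLayer(config.d_hidden, config.d_latent, rng)
        self.dec1 = GTNLayer(config.d_latent, config.d_hidden, rng)
        self.dec2 = GTNLayer(config.d_hidden, n_genes, rng)
        self.mask_token = Parameter(np.zeros((1, n_genes)))

    @property
    def params(self):
        return (self.enc1.params + self.enc2.params + self.dec1.params
                + self.dec2.params + [self.mask_token])

    def encode(self, X: Tensor, pairs: np.ndarray) -> Tensor:
        return self.enc2(self.enc1(X, pairs), pairs)

    def decode(self, Z: Tensor, pairs: np.ndarray) -> Tensor:
        return self.dec2(self.dec1(Z, pairs), pairs)


def mask_spots(X: np.ndarray, mask_ratio: float, token: np.ndarray,
               rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Replace ⌊mask_ratio·n⌋ rows (chosen without replacement) by the shared
    mask token; returns the masked matrix and the selected indices."""
    if not 0 <= mask_ratio < 1:
        raise ValueError("mask_ratio must be in [0, 1)")
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    n_mask = int(np.floor(mask_ratio * n))
    idx = rng.choice(n, size=n_mask, replace=False) if n_mask else np.empty(0, dtype=np.intp)
    out = X.copy()
    out[idx] = np.asarray(token).reshape(1, -1)
    return out, np.sort(idx)


_EPS = 1e-12


def reconstruction_loss(X: np.ndarray, X_tilde: np.ndarray) -> float:
    """Mean cosine error (1 − cosine similarity) over spots; in [0, 2].

    A zero-norm row in either matrix contributes 1 (the orthogonality
    convention)."""
    X = np.asarray(X, dtype=np.float64)
    Xt = np.asarray(X_tilde, dtype=np.float64)
    if X.shape != Xt.shape:
        raise ValueError("input and reconstruction must have the same shape")
    nx = np.linalg.norm(X, axis=1)
    nt = np.linalg.norm(Xt, axis=1)
    dot = (X * Xt).sum(axis=1)
    zero = (nx == 0) | (nt == 0)
    cos = np.where(zero, 0.0, dot / np.where(zero, 1.0, nx * nt))
    return float(np.mean(1.0 - cos))


def reconstruction_loss_t(X: Tensor, X_tilde: Tensor) -> Tensor:
    """Autodiff cosine-error loss (matches :func:`reconstruction_loss` up to
    the ε guarding zero rows)."""
    nx = ((X * X).sum(axis=1) + _EPS).sqrt()
    nt = ((X_tilde * X_tilde).sum(axis=1) + _EPS).sqrt()
    cos = (X * X_tilde).sum(axis=1) / (nx * nt)
    return (1.0 - cos).mean()


def topological_loss(Z: np.ndarray, E_prime, E_minus,
                     reduction: str = "sum") -> float:
    """Signed-edge structure loss on embeddings.

    Σ_{(i,j)∈E′} −log σ(z_i·z_j) + Σ_{(i,j)∈E−} −log(1 − σ(z_i·z_j)), each
    undirected edge counted once, evaluated through softplus so no dot
    product overflows.  ``reduction='mean'`` divides each sum by its edge
    count."""
    Z = np.asarray(Z, dtype=np.float64)
    total = 0.0
    for edges, sign in ((E_prime, -1.0), (E_minus, +1.0)):
        e = np.asarray(sorted(edges), dtype=np.intp).reshape(-1, 2)
        if e.shape[0] == 0:
            continue
        dots = (Z[e[:, 0]] * Z[e[:, 1]]).sum(axis=1)
        terms = np.logaddexp(0.0, sign * dots)  # softplus(±dot)
        total += terms.mean() if reduction == "mean" else terms.sum()
    return float(total)


def topological_loss_t(Z: Tensor, pos_pairs: np.ndarray, neg_pairs: np.ndarray,
                       reduction: str = "sum") -> Tensor:
    """Autodiff topological loss; pair arrays hold each undirected edge once."""
    terms = []
    for pairs, sign in ((pos_pairs, -1.0), (neg_pairs, 1.0)):
        if pairs.shape[0] == 0:
            continue
        dots = (take_rows(Z, pairs[:, 0]) * take_rows(Z, pairs[:, 1])).sum(axis=1)
        sp = (dots * sign).softplus()
        terms.append(sp.mean() if reduction == "mean" else sp.sum())
    if not terms:
        return Tensor(0.0)
    out = terms[0]
    for t in terms[1:]:
        out = out + t
    return out
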