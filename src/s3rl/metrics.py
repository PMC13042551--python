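"""Evaluation utilities: ARI, ligand–receptor quadrant metrics, and export
of the enhanced expression matrix.

The quadrant metrics compare per-pair communication significance (on the
−log10 FDR scale) before and after expression enhancement.  Significance
values come from an external communication model and are supplied as a
table; this module implements the bespoke summary metrics:

    ESR = N_tl / N_br              (new discoveries per lost pair)
    EEP = 100 · N_tl / (N_tl+N_br) (share of changed pairs that are gains)
    SSP = 100 · N_tr / (N_tr+N_br) (retention of originally significant pairs)
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np
from sklearn.metrics import adjusted_rand_score

__all__ = [
    "adjusted_rand_index",
    "QuadrantCounts",
    "lr_quadrants",
    "lr_metrics",
    "export_enhanced",
    "DEFAULT_LR_THRESHOLD",
]

DEFAULT_LR_THRESHOLD = -np.log10(0.05)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Permutation-model-adjusted Rand index between two labelings."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError(f"label vectors differ in length: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("need at least 2 elements")
    return float(adjusted_rand_score(a, b))


@dataclass
class QuadrantCounts:
    """Scatter-plot quadrants of (raw significance, enhanced significance).

    top-left: significant only after enhancement; top-right: both;
    bottom-left: neither; bottom-right: only in raw data.
    """

    N_tl: int
    N_tr: int
    N_bl: int
    N_br: int

    def __post_init__(self):
        if min(self.N_tl, self.N_tr, self.N_bl, self.N_br) < 0:
            raise ValueError("quadrant counts must be non-negative")

    @property
    def total(self) -> int:
        return self.N_tl + self.N_tr + self.N_bl + self.N_br

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "QuadrantCounts":
        return cls(**json.loads(s))


def lr_quadrants(raw_sig, enh_sig,
                 threshold: float = DEFAULT_LR_THRESHOLD) -> QuadrantCounts:
    """Count ligand–receptor pairs per quadrant at a −log10(FDR) threshold."""
    raw = np.asarray(raw_sig, dtype=np.float64)
    enh = np.asarray(enh_sig, dtype=np.float64)
    if raw.shape != enh.shape:
        raise ValueError(
            f"raw and enhanced significance lists differ in length: "
            f"{raw.shape} vs {enh.shape}"
        )
    raw_on = raw >= threshold
    enh_on = enh >= threshold
    return QuadrantCounts(
        N_tl=int(np.sum(enh_on & ~raw_on)),
        N_tr=int(np.sum(enh_on & raw_on)),
        N_bl=int(np.sum(~enh_on & ~raw_on)),
        N_br=int(np.sum(~enh_on & raw_on)),
    )


def lr_metrics(q: QuadrantCounts) -> tuple[float | None, float | None, float | None]:
    """(ESR, EEP, SSP) from quadrant counts.

    Zero denominators yield sentinels rather than NaN: ESR is +inf when
    pairs were gained but none lost, and None when nothing changed; EEP/SSP
    are None when their denominator is empty.
    """
    if q.N_br > 0:
        esr = q.N_tl / q.N_br
    elif q.N_tl > 0:
        esr = float("inf")
    else:
        esr = None
    eep = 100.0 * q.N_tl / (q.N_tl + q.N_br) if (q.N_tl + q.N_br) > 0 else None
    ssp = 100.0 * q.N_tr / (q.N_tr + q.N_br) if (q.N_tr + q.N_br) > 0 else None
    return esr, eep, ssp


def export_enhanced(adata, X_tilde: np.ndarray, clip_negative: bool = False,
                    config: dict | None = None, seed: int | None = None):
    """Store the enhanced matrix as ``layers["enhanced"]`` with provenance.

    The matrix is kept in the log-normalized training space; with
    ``clip_negative`` any negative reconstruction values are set to 0 for
    downstream tools that require non-negative expression.
    """
    X_tilde = np.asarray(X_tilde, dtype=np.float64)
    if X_tilde.shape != adata.shape:
        raise ValueError(
            f"enhanced matrix shape {X_tilde.shape} does not match the "
            f"container shape {adata.shape}"
        )
    out = X_tilde.copy()
    if clip_negative:
        out[out < 0] = 0.0
    adata.layers["enhanced"] = out
    cfg_hash = hashlib.sha256(
        json.dumps(config or {}, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    adata.uns["enhanced_provenance"] = {
        "clip_negative": bool(clip_negative),
        "config_hash": cfg_hash,
        "seed": -1 if seed is None else int(seed),
    }
    return adata
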