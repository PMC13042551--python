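"""One-call pipeline: preprocess → visual features → signed graph → train.

Thin composition of the library stages, used by the CLI and by evaluation
scripts.  Ground-truth labels on the dataset are never consulted.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .data_io import SpatialDataset, normalize_expression, select_hvgs
from .graph import build_signed_graph
from .prototypes import TrainConfig, TrainResult, train
from .visual import ContrastiveConfig, train_visual_encoder

__all__ = ["run_pipeline"]


def run_pipeline(dataset: SpatialDataset, n_clusters: int, seed: int = 0,
                 n_hvgs: int = 3000, use_visual: bool = True,
                 freeze_prototypes: bool = False,
                 visual_config: ContrastiveConfig | None = None,
                 visual_features: np.ndarray | None = None,
                 train_config: TrainConfig | None = None,
                 k: int = 6, visual_n_pos: int = 3,
                 visual_n_neg: int = 3) -> TrainResult:
    """Run the full method on a raw-count dataset and return the result.

    ``use_visual=False`` drops the histology branch (the signed graph is
    built from expression similarity only); ``freeze_prototypes=True``
    disables dynamic prototype updates.  These two switches reproduce the
    ablation variants.  ``visual_features`` supplies a precomputed per-spot
    embedding and skips contrastive training (useful when comparing model
    variants on one dataset).  Histology similarity is a much cleaner domain
    signal than expression similarity, so the visual modality contributes
    three positive and three negative edges per spot by default while
    expression stays at the top-1 reading.
    """
    n_hvgs = min(n_hvgs, dataset.n_genes)
    hvg_idx = select_hvgs(dataset.X, n_top=n_hvgs)
    Xn = normalize_expression(dataset.X)[:, hvg_idx]

    visual_H = None
    if use_visual and visual_features is not None:
        visual_H = np.asarray(visual_features)
    elif use_visual and dataset.patches is not None:
        vcfg = visual_config or ContrastiveConfig(epochs=40, seed=seed)
        visual_H = train_visual_encoder(dataset.patches, vcfg).H

    graph = build_signed_graph(dataset.S, expression=Xn, visual=visual_H,
                               k=k, visual_n_pos=visual_n_pos,
                               visual_n_neg=visual_n_neg)

    tcfg = train_config or TrainConfig()
    tcfg = replace(tcfg, n_clusters=n_clusters, seed=seed,
                   freeze_prototypes=freeze_prototypes)
    ds_hvg = SpatialDataset(X=Xn, S=dataset.S,
                            gene_names=[dataset.gene_names[i] for i in hvg_idx],
                            spot_ids=list(dataset.spot_ids))
    return train(ds_hvg, graph, config=tcfg)
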