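"""Training orchestration: pretraining and self-optimizing main training.

The model is trained full-batch with Adam in two phases:

* **pretrain** minimizes ``L = L_recon + lambda_contrast * (-J)`` where
  L_recon is the ZINB negative log-likelihood of the raw HVG counts decoded
  from the un-augmented embedding, and J is the multi-view InfoNCE objective
  over two fresh augmented views drawn each epoch.
* **main training** adds the clustering term ``lambda_cluster * KL(P || Q)``
  with cluster centers initialized by spectral clustering of the pretrained
  embedding; the target distribution P is refreshed from the current soft
  assignment Q at the start of every epoch.

Ablation switches: ``use_appnp`` swaps the propagation encoder for a
two-layer graph convolution, ``use_augmentation`` disables the contrastive
branch, ``use_zinb`` replaces the likelihood with mean-squared
reconstruction of the normalized features through the same decoder trunk.

Everything runs on numpy with reverse-mode autodiff (autograd); gradients
flow through the propagation scheme, the decoder heads and the cluster
centers.  Training arrays are held in float32 (counts are small integers,
exact in single precision), which roughly quadruples full-batch throughput;
preprocessing and all public module functions remain float64.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import autograd.numpy as anp
import numpy as np
from autograd import grad
from autograd.misc import flatten

from . import adaptive_augmentation as aug
from .adaptive_augmentation import AugmentationConfig
from .appnp_encoder import EncoderConfig, encode, encode_gcn, init_encoder_params
from .cell_graph import CellGraph, NormalizedAdjacency, build_knn_graph, normalize_adjacency
from .contrastive_objective import (
    ContrastiveConfig,
    init_projection_params,
    objective,
)
from .dec_clustering import (
    hard_labels,
    init_centers,
    kl_loss,
    soft_assign,
    target_distribution,
)
from .preprocessing import CountMatrix, filter_genes, normalize_counts, select_hvg
from .zinb_decoder import (
    DecoderConfig,
    decode_linear,
    decode_zinb,
    init_decoder_params,
    mse_loss,
    zinb_nll,
)

__all__ = [
    "TrainConfig",
    "TrainLog",
    "Dataset",
    "ScZAGModel",
    "prepare_data",
    "pretrain",
    "main_train",
    "run_pipeline",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class TrainConfig:
    """Schedule, loss weights, seed and ablation switches."""

    pretrain_epochs: int = 1000
    pretrain_lr: float = 1e-4
    main_epochs: int = 300
    main_lr: float = 5e-4
    lambda_contrast: float = 1.0
    lambda_cluster: float = 1.0
    seed: int = 0
    use_appnp: bool = True
    use_augmentation: bool = True
    use_zinb: bool = True
    pretrain_contrastive: bool = True  # include the contrastive term in pretraining

    def __post_init__(self) -> None:
        if self.pretrain_epochs < 0 or self.main_epochs < 0:
            raise ValueError("epoch counts must be >= 0")
        if self.pretrain_lr <= 0 or self.main_lr <= 0:
            raise ValueError("learning rates must be positive")
        if self.lambda_contrast < 0 or self.lambda_cluster < 0:
            raise ValueError("loss weights must be >= 0")

    @classmethod
    def fast(cls, **kwargs) -> "TrainConfig":
        """Reduced schedule (pretrain 100 / main 50) for tests and smoke runs."""
        kwargs.setdefault("pretrain_epochs", 100)
        kwargs.setdefault("main_epochs", 50)
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path) -> "TrainConfig":
        """Read a ``key = value`` config file; unknown keys raise."""
        import ast
        from pathlib import Path

        valid = {f.name for f in dataclasses.fields(cls)}
        kwargs = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in valid:
                raise ValueError(f"unknown config key {key!r}")
            kwargs[key] = ast.literal_eval(value.strip())
        return cls(**kwargs)


@dataclass
class TrainLog:
    """Per-epoch loss components; ``total`` equals the sum of the others."""

    records: list[dict] = field(default_factory=list)

    def append(self, **kwargs) -> None:
        self.records.append(kwargs)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.records)

    def totals(self) -> np.ndarray:
        return np.array([r["total"] for r in self.records])


@dataclass
class Dataset:
    """Preprocessed training inputs: HVG counts, features, graph, adjacency."""

    counts_hvg: np.ndarray  # raw counts restricted to HVGs (reconstruction target)
    X: np.ndarray  # log-normalized HVG features (encoder input)
    graph: CellGraph
    A_hat: NormalizedAdjacency
    cell_ids: list[str]
    gene_ids: list[str]

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]


def prepare_data(
    counts: CountMatrix,
    n_hvg: int = 500,
    k: int = 15,
    min_cell_fraction: float = 0.01,
) -> Dataset:
    """Filter, normalize, select HVGs and build the KNN cell graph.

    ``n_hvg`` and ``k`` are capped at the available gene/cell counts so small
    inputs still run.
    """
    filtered = filter_genes(counts, min_cell_fraction)
    norm = normalize_counts(filtered)
    hvg = select_hvg(norm, min(n_hvg, norm.n_genes))
    keep = [filtered.gene_ids.index(g) for g in hvg.kept_gene_ids]
    graph = build_knn_graph(hvg, k=min(k, hvg.n_cells - 1))
    return Dataset(
        counts_hvg=filtered.counts[:, keep],
        X=hvg.values,
        graph=graph,
        A_hat=normalize_adjacency(graph),
        cell_ids=list(counts.cell_ids),
        gene_ids=list(hvg.kept_gene_ids),
    )


class ScZAGModel:
    """Parameter container: encoder, decoder, projection head, cluster centers."""

    def __init__(
        self,
        n_genes: int,
        n_clusters: int,
        encoder: EncoderConfig | None = None,
        decoder: DecoderConfig | None = None,
        contrastive: ContrastiveConfig | None = None,
        augmentation: AugmentationConfig | None = None,
        seed: int = 0,
    ) -> None:
        self.encoder = encoder or EncoderConfig()
        self.decoder = decoder or DecoderConfig()
        self.contrastive = contrastive or ContrastiveConfig()
        self.augmentation = augmentation or AugmentationConfig()
        self.n_genes = n_genes
        self.n_clusters = n_clusters
        seeds = _spawn_seeds(seed, 3)
        self.params: dict = {
            "enc": init_encoder_params(n_genes, self.encoder, seeds[0]),
            "dec": init_decoder_params(
                self.encoder.latent_dim, n_genes, self.decoder, seeds[1]
            ),
            "proj": init_projection_params(
                self.encoder.latent_dim, self.contrastive, seeds[2]
            ),
        }
        self.params = _cast_tree(self.params, _TRAIN_DTYPE)

    def encode(self, A_hat, X, use_appnp: bool = True):
        fn = encode if use_appnp else encode_gcn
        return fn(A_hat, X, self.params["enc"], self.encoder)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


_TRAIN_DTYPE = np.float32


def _cast_tree(tree: dict, dtype) -> dict:
    return {
        k: _cast_tree(v, dtype) if isinstance(v, dict) else np.asarray(v, dtype=dtype)
        for k, v in tree.items()
    }


def _training_view(data: Dataset) -> Dataset:
    """Single-precision copy of the arrays touched inside the training loop."""
    return Dataset(
        counts_hvg=data.counts_hvg.astype(_TRAIN_DTYPE),
        X=data.X.astype(_TRAIN_DTYPE),
        graph=data.graph,
        A_hat=NormalizedAdjacency(data.A_hat.matrix.astype(_TRAIN_DTYPE)),
        cell_ids=data.cell_ids,
        gene_ids=data.gene_ids,
    )


class _Adam:
    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = self.v = None
        self.t = 0

    def step(self, x: np.ndarray, g: np.ndarray) -> np.ndarray:
        if self.m is None:
            self.m = np.zeros_like(x)
            self.v = np.zeros_like(x)
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * g
        self.v = self.b2 * self.v + (1 - self.b2) * g**2
        mhat = self.m / (1 - self.b1**self.t)
        vhat = self.v / (1 - self.b2**self.t)
        return x - self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _ViewSampler:
    """Per-epoch augmented views from probabilities fixed on the original graph."""

    def __init__(self, data: Dataset, config: AugmentationConfig):
        self.data = data
        self.config = config
        sigma = aug.pagerank_centrality(data.graph, damping=config.damping)
        s_edges = aug.edge_centrality(sigma, data.graph)
        s_dims = aug.feature_dim_weights(data.X, sigma, dense=True)
        self.p_edge = [
            aug.edge_drop_probabilities(s_edges, p_e, config.p_tau)
            for p_e in (config.p_e1, config.p_e2)
        ]
        self.p_feat = [
            aug.feature_mask_probabilities(s_dims, p_f, config.p_tau)
            for p_f in (config.p_f1, config.p_f2)
        ]

    def draw(self, seed: int):
        subs = _spawn_seeds(seed, 4)
        views = []
        for i in range(2):
            A = aug.sample_edge_view(self.data.graph, self.p_edge[i], subs[2 * i])
            Xm, _ = aug.sample_feature_mask(self.data.X, self.p_feat[i], subs[2 * i + 1])
            A_hat = normalize_adjacency(CellGraph(self.data.graph.n_nodes, A))
            views.append(
                (A_hat.matrix.astype(self.data.X.dtype), Xm.astype(self.data.X.dtype))
            )
        return views


def _loss_components(
    params: dict,
    model: ScZAGModel,
    data: Dataset,
    views,
    P,
    config: TrainConfig,
    with_contrast: bool,
    with_cluster: bool,
):
    """All loss terms as a dict; ``total`` is their exact (weighted) sum."""
    enc_fn = encode if config.use_appnp else encode_gcn
    Z = enc_fn(data.A_hat, data.X, params["enc"], model.encoder)
    if config.use_zinb:
        recon = zinb_nll(
            data.counts_hvg,
            decode_zinb(Z, params["dec"], model.decoder),
            validate=False,
        )
    else:
        recon = mse_loss(data.X, decode_linear(Z, params["dec"], model.decoder))
    total = recon
    contrast = 0.0
    if with_contrast:
        (A1, X1), (A2, X2) = views
        U = enc_fn(A1, X1, params["enc"], model.encoder)
        V = enc_fn(A2, X2, params["enc"], model.encoder)
        contrast = -objective(U, V, params["proj"], model.contrastive.tau)
        total = total + config.lambda_contrast * contrast
    cluster = 0.0
    if with_cluster:
        Q = soft_assign(Z, params["centers"])
        cluster = kl_loss(P, Q)
        total = total + config.lambda_cluster * cluster
    return {"recon": recon, "contrast": contrast, "cluster": cluster, "total": total}


def _run_epochs(
    model: ScZAGModel,
    data: Dataset,
    config: TrainConfig,
    n_epochs: int,
    lr: float,
    with_contrast: bool,
    with_cluster: bool,
    epoch_seeds: list[int],
    phase: str,
) -> TrainLog:
    log = TrainLog()
    data = _training_view(data)
    sampler = _ViewSampler(data, model.augmentation) if with_contrast else None
    flat, unflatten = flatten(model.params)
    optimizer = _Adam(lr)

    def total_loss(p, views, P, stash):
        comps = _loss_components(
            p, model, data, views, P, config, with_contrast, with_cluster
        )
        # record loss components from inside the gradient trace
        stash.update(
            {k: float(getattr(v, "_value", v)) for k, v in comps.items()}
        )
        return comps["total"]

    grad_fn = grad(total_loss)
    for epoch in range(n_epochs):
        params = unflatten(flat)
        views = sampler.draw(epoch_seeds[epoch]) if sampler else None
        P = None
        if with_cluster:
            enc_fn = encode if config.use_appnp else encode_gcn
            Z = enc_fn(data.A_hat, data.X, params["enc"], model.encoder)
            P = target_distribution(soft_assign(Z, params["centers"])).astype(
                _TRAIN_DTYPE
            )
        stash: dict = {}
        g, _ = flatten(grad_fn(params, views, P, stash))
        if not np.isfinite(stash["total"]):
            raise RuntimeError(f"non-finite loss at {phase} epoch {epoch}")
        flat = optimizer.step(flat, g)
        log.append(phase=phase, epoch=epoch, **stash)
    model.params = unflatten(flat)
    return log


def pretrain(model: ScZAGModel, data: Dataset, config: TrainConfig) -> TrainLog:
    """Phase 1: reconstruction (+ contrastive) training of encoder/decoder."""
    with_contrast = (
        config.use_augmentation
        and config.pretrain_contrastive
        and config.lambda_contrast > 0
    )
    epoch_seeds = _spawn_seeds(config.seed + 1_000_003, max(config.pretrain_epochs, 1))
    return _run_epochs(
        model, data, config, config.pretrain_epochs, config.pretrain_lr,
        with_contrast, with_cluster=False, epoch_seeds=epoch_seeds, phase="pretrain",
    )


def main_train(
    model: ScZAGModel, data: Dataset, config: TrainConfig
) -> tuple[np.ndarray, TrainLog]:
    """Phase 2: add the KL clustering loss; returns hard labels and the log."""
    Z = model.encode(data.A_hat, data.X, config.use_appnp)
    centers_seed = _spawn_seeds(config.seed + 2_000_003, 1)[0]
    model.params["centers"] = init_centers(
        np.asarray(Z, dtype=float), model.n_clusters, seed=centers_seed
    ).astype(_TRAIN_DTYPE)
    with_contrast = config.use_augmentation and config.lambda_contrast > 0
    epoch_seeds = _spawn_seeds(config.seed + 3_000_003, max(config.main_epochs, 1))
    log = _run_epochs(
        model, data, config, config.main_epochs, config.main_lr,
        with_contrast, with_cluster=True, epoch_seeds=epoch_seeds, phase="main",
    )
    Z_final = model.encode(data.A_hat, data.X, config.use_appnp)
    Q = np.asarray(soft_assign(Z_final, model.params["centers"]))
    labels = hard_labels(Q)
    if len(np.unique(labels)) < model.n_clusters:
        warnings.warn(
            f"cluster collapse: only {len(np.unique(labels))} of "
            f"{model.n_clusters} clusters populated",
            RuntimeWarning,
        )
    return labels, log


def run_pipeline(
    counts: CountMatrix,
    n_clusters: int,
    config: TrainConfig | None = None,
    n_hvg: int = 500,
    k: int = 15,
    encoder: EncoderConfig | None = None,
    decoder: DecoderConfig | None = None,
    contrastive: ContrastiveConfig | None = None,
    augmentation: AugmentationConfig | None = None,
) -> dict:
    """Full pipeline: preprocess -> graph -> pretrain -> main training.

    Returns a dict with ``labels``, ``embedding``, ``Q``, the two train logs
    and the fitted model.
    """
    config = config or TrainConfig()
    data = prepare_data(counts, n_hvg=n_hvg, k=k)
    model = ScZAGModel(
        n_genes=data.counts_hvg.shape[1],
        n_clusters=n_clusters,
        encoder=encoder,
        decoder=decoder,
        contrastive=contrastive,
        augmentation=augmentation,
        seed=config.seed,
    )
    pre_log = pretrain(model, data, config)
    labels, main_log = main_train(model, data, config)
    Z = np.asarray(model.encode(data.A_hat, data.X, config.use_appnp))
    return {
        "labels": labels,
        "embedding": Z,
        "Q": np.asarray(soft_assign(Z, model.params["centers"])),
        "pretrain_log": pre_log,
        "main_log": main_log,
        "model": model,
        "data": data,
    }


def save_checkpoint(model: ScZAGModel, path) -> None:
    """Save all parameters (flat key = group/name) to an .npz archive."""
    arrays = {}
    for group, sub in model.params.items():
        if isinstance(sub, dict):
            for name, arr in sub.items():
                arrays[f"{group}/{name}"] = arr
        else:
            arrays[group] = sub
    np.savez(path, **arrays)


def load_checkpoint(model: ScZAGModel, path) -> None:
    """Restore parameters saved by :func:`save_checkpoint` into ``model``."""
    with np.load(path) as npz:
        for key in npz.files:
            if "/" in key:
                group, name = key.split("/", 1)
                model.params.setdefault(group, {})[name] = npz[key]
            else:
                model.params[key] = npz[key]
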