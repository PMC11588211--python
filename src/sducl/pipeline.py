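"""End-to-end orchestration: read → graph → augment → diffuse → train →
cluster → report, as one reproducible, fully configured run."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import datasets, diffusion, evaluation, features, graph, model

logger = logging.getLogger("sducl")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "run"]


@dataclass
class RunConfig:
    """Every tunable of the pipeline, serialized alongside each run.

    Ablation switches: ``use_image`` / ``use_katz`` drop the corresponding
    feature block; ``use_fusion=False`` uses the expression block alone;
    ``use_signal=False`` replaces per-node microenvironments by a single
    whole-graph summary (``n_sub = N``); ``alpha_rec=0`` / ``beta_con=0``
    drop a loss term.
    """

    # graph
    k: int = 6
    # diffusion microenvironment
    alpha_diffusion: float = 0.1
    n_sub: int = 20
    # feature augmentation
    beta_katz: float = 0.1
    katz_l_max: object = "closed-form"
    n_hvg: int = 3000
    d_i: int = 50
    d_s: int = 32
    backbone: str = "patchstats"
    patch_px: Optional[int] = None
    # model
    hidden_dim: int = 512
    embed_dim: int = 64
    epochs: int = 500
    lr: float = 1e-3
    weight_decay: float = 1e-4
    alpha_rec: float = 1.0
    beta_con: float = 1.0
    seed: int = 0
    # clustering
    n_clusters: Optional[int] = None
    cluster_method: str = "kmeans"
    # ablations
    use_image: bool = True
    use_katz: bool = True
    use_fusion: bool = True
    use_signal: bool = True

    def validate(self) -> None:
        if self.alpha_rec == 0 and self.beta_con == 0:
            raise ValueError(
                "alpha_rec=0 and beta_con=0 leave no training signal"
            )
        if self.k < 1:
            raise ValueError("k must be positive")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, default=str)


@dataclass
class PipelineResult:
    """All intermediate and final artifacts of one run."""

    config: RunConfig
    dataset: datasets.SpatialDataset
    graph: graph.SpatialGraph
    features: features.AugmentedFeatures
    microenvironments: diffusion.MicroenvironmentMap
    model: model.SDUCLModel
    embeddings: model.EmbeddingResult
    report: Optional[evaluation.ClusteringReport] = None

    @property
    def H(self) -> np.ndarray:
        return self.embeddings.H


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

        return wrapper

    return deco


def build_features(
    ds: datasets.SpatialDataset, g: graph.SpatialGraph, config: RunConfig
) -> features.AugmentedFeatures:
    """Assemble F = Eg ⊕ Ei ⊕ Es according to the config's ablation switches."""
    Eg = features.preprocess_genes(ds, n_hvg=config.n_hvg)
    if not config.use_fusion:
        return features.fuse(Eg)
    Ei = Es = None
    if config.use_image and ds.image is not None:
        patches = datasets.crop_patches(ds, patch_px=config.patch_px)
        Ei = features.extract_image_features(
            patches, backbone=config.backbone, d_i=config.d_i, seed=config.seed
        )
    if config.use_katz:
        _, Es = features.katz_features(
            g, beta=config.beta_katz, l_max=config.katz_l_max, d_s=config.d_s
        )
    return features.fuse(Eg, Ei, Es)


def run_pipeline(
    ds: datasets.SpatialDataset,
    config: Optional[RunConfig] = None,
    verbose: bool = False,
) -> PipelineResult:
    """Run the full method on an in-memory dataset and return everything."""
    config = config or RunConfig()
    config.validate()

    g = _stage("graph_construction")(graph.build_knn_graph)(ds.coords, k=config.k)
    logger.info("built KNN graph: %d nodes, k=%d", g.n_nodes, g.k)

    feats = _stage("feature_augmentation")(build_features)(ds, g, config)
    logger.info(
        "augmented features: %d x %d (blocks %s)",
        feats.n_spots,
        feats.dim,
        {k: (s.stop - s.start) for k, s in feats.block_slices.items()},
    )

    n_sub = config.n_sub if config.use_signal else g.n_nodes
    me = _stage("diffusion_microenvironment")(diffusion.discover_microenvironments)(
        g, alpha=config.alpha_diffusion, n_sub=n_sub
    )

    tcfg = model.TrainConfig(
        hidden_dim=config.hidden_dim,
        embed_dim=config.embed_dim,
        epochs=config.epochs,
        lr=config.lr,
        weight_decay=config.weight_decay,
        alpha_rec=config.alpha_rec,
        beta_con=config.beta_con,
        seed=config.seed,
    )
    mdl, emb = _stage("model_training")(model.train)(feats, g, me, tcfg, verbose)
    logger.info("training done: final loss %.4f", emb.losses[-1]["L"])

    report = None
    n_clusters = config.n_clusters
    if n_clusters is None and ds.labels is not None:
        n_clusters = len(ds.labels.categories)
    if n_clusters is not None or config.cluster_method == "leiden":
        report = _stage("clustering_evaluation")(evaluation.evaluate)(
            emb.H,
            n_clusters or 0,
            labels_true=np.asarray(ds.labels) if ds.labels is not None else None,
            method=config.cluster_method,
            seed=config.seed,
        )
        logger.info("clustering metrics: %s", report.metrics)

    return PipelineResult(
        config=config,
        dataset=ds,
        graph=g,
        features=feats,
        microenvironments=me,
        model=mdl,
        embeddings=emb,
        report=report,
    )


def load_dataset(path, fmt: str = "auto") -> datasets.SpatialDataset:
    """Dispatch to the right reader based on ``fmt`` or the path itself."""
    path = Path(path)
    if fmt == "auto":
        if path.is_dir():
            fmt = "visium"
        elif path.suffix == ".h5ad":
            fmt = "h5ad"
        else:
            raise ValueError(f"cannot infer format of {path}; pass fmt explicitly")
    if fmt == "visium":
        ds = datasets.read_visium(path)
        labels_file = path / "labels.csv"
        if labels_file.is_file():
            lab = pd.read_csv(labels_file).set_index("barcode")
            ds.labels = pd.Categorical(lab.loc[ds.spot_ids, "label"])
        return ds
    if fmt == "h5ad":
        return datasets.read_h5ad(path)
    raise ValueError(f"unknown format {fmt!r}")


def run(
    input_path,
    out_dir,
    config: Optional[RunConfig] = None,
    fmt: str = "auto",
    verbose: bool = False,
) -> PipelineResult:
    """File-to-files entry point: read input, run, write all artifacts.

    Writes embeddings.tsv, clusters.tsv (when clustering ran), losses.csv,
    metrics.json and config.json under ``out_dir``.
    """
    config = config or RunConfig()
    ds = load_dataset(input_path, fmt=fmt)
    result = run_pipeline(ds, config, verbose=verbose)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(result.H, index=ds.spot_ids).to_csv(
        out / "embeddings.tsv", sep="\t", header=False
    )
    result.embeddings.loss_frame().to_csv(out / "losses.csv", index=False)
    (out / "config.json").write_text(config.to_json())
    if result.report is not None:
        pd.DataFrame(
            {"barcode": ds.spot_ids, "cluster": result.report.labels_pred}
        ).to_csv(out / "clusters.tsv", sep="\t", index=False)
        (out / "metrics.json").write_text(result.report.to_json())
    logger.info("artifacts written to %s", out)
    return result
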