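"""Dimension-reduction baselines for head-to-head comparison with the encoder.

Two alternative front-ends feed the *same* clustering/orientation code path
as the main pipeline: (1) PCA keeping the minimal number of components whose
cumulative explained variance reaches 95%, followed by Cox screening of the
component scores; (2) direct univariate Cox screening of the prepared
gene-level expression. Both default to K = 2 clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from tallsurv.classifier import fit_standardizer
from tallsurv.evaluation import PipelineConfig, stage_seed
from tallsurv.io_preprocess import ClinicalTable, ExpressionMatrix, filter_cohort, prepare_encoder_input
from tallsurv.subtyping import SubgroupLabeling, cluster_kmeans, orient_labels, select_k_silhouette
from tallsurv.survival import SurvivalData, screen_features


@dataclass
class PCAModel:
    loadings: np.ndarray               # d* x n_genes
    explained_variance_ratio: np.ndarray
    d_star: int

    def __post_init__(self) -> None:
        evr = self.explained_variance_ratio
        if np.any(evr < 0) or np.any(np.diff(evr) > 1e-12) or evr.sum() > 1 + 1e-9:
            raise ValueError("explained variance ratios must be non-negative, non-increasing, sum <= 1")


def pca_reduce(X: ExpressionMatrix, evr_threshold: float = 0.95) -> tuple[PCAModel, np.ndarray]:
    """Mean-centered PCA keeping the minimal d* with cumulative EVR >= threshold."""
    V = np.asarray(X.values, dtype=float)
    if V.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    if np.ptp(V) == 0:
        raise ValueError("constant matrix has no principal components")
    pca = PCA(n_components=min(V.shape), svd_solver="full", random_state=0)
    scores = pca.fit_transform(V)
    evr = pca.explained_variance_ratio_
    cum = np.cumsum(evr)
    d_star = int(np.searchsorted(cum, evr_threshold - 1e-12) + 1)
    model = PCAModel(
        loadings=pca.components_[:d_star],
        explained_variance_ratio=evr[:d_star],
        d_star=d_star,
    )
    return model, scores[:, :d_star]


def baseline_pca_subtype(
    expression: ExpressionMatrix,
    clinical: ClinicalTable,
    config: PipelineConfig,
    evr_threshold: float = 0.95,
    fixed_k: int | None = 2,
) -> tuple[SubgroupLabeling, dict]:
    """PCA (>=95% EVR) -> Cox screening of component scores -> K-means -> orient.

    ``fixed_k=None`` enables silhouette selection of K instead of the default
    two clusters.
    """
    clinical, expression = filter_cohort(clinical, expression)
    surv = SurvivalData(clinical.time, clinical.event)
    prepared, _ = prepare_encoder_input(expression, config.pseudocount)
    model, scores = pca_reduce(prepared, evr_threshold)
    screened = screen_features(scores, surv, alpha=config.screening_alpha)
    if len(screened) == 0:
        raise RuntimeError(
            f"Cox screening retained no principal components at alpha={config.screening_alpha}"
        )
    labeling, diag = _cluster_and_orient(scores[:, screened], surv, expression.sample_ids, config, fixed_k)
    diag |= {"d_star": model.d_star, "n_screened_components": int(len(screened)),
             "explained_variance_ratio_sum": float(model.explained_variance_ratio.sum())}
    return labeling, diag


def baseline_gene_cox_subtype(
    expression: ExpressionMatrix,
    clinical: ClinicalTable,
    config: PipelineConfig,
    fixed_k: int | None = 2,
) -> tuple[SubgroupLabeling, dict]:
    """Univariate Cox screen of prepared gene expression -> K-means on the
    retained, standardized genes -> orient."""
    clinical, expression = filter_cohort(clinical, expression)
    surv = SurvivalData(clinical.time, clinical.event)
    prepared, _ = prepare_encoder_input(expression, config.pseudocount)
    screened = screen_features(prepared.values, surv, alpha=config.screening_alpha)
    if len(screened) == 0:
        raise RuntimeError(f"Cox screening retained no genes at alpha={config.screening_alpha}")
    std = fit_standardizer(prepared.values[:, screened])
    Z = std.apply(prepared.values[:, screened])
    labeling, diag = _cluster_and_orient(Z, surv, expression.sample_ids, config, fixed_k)
    diag |= {"n_screened_genes": int(len(screened))}
    return labeling, diag


def _cluster_and_orient(
    values: np.ndarray, surv: SurvivalData, sample_ids: list[str], config: PipelineConfig, fixed_k: int | None
) -> tuple[SubgroupLabeling, dict]:
    """Shared clustering/orientation path (identical to the main pipeline's)."""
    seed = stage_seed(config.seed, "kmeans")
    if fixed_k is None:
        k, sil = select_k_silhouette(values, config.k_min, config.k_max, seed=seed, n_init=config.kmeans_n_init)
    else:
        k, sil = fixed_k, {}
    raw, _ = cluster_kmeans(values, k, seed=seed, n_init=config.kmeans_n_init)
    if k == 2:
        labeling = orient_labels(raw, surv, sample_ids=sample_ids)
    else:
        warnings.warn(f"K={k}: labels left in cluster order (orientation is binary-only)")
        labeling = SubgroupLabeling(sample_ids, raw, {"oriented": False})
    return labeling, {"k": int(k), "silhouette_by_k": {str(kk): v for kk, v in sil.items()}}
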