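"""End-to-end pipeline, repeated 60/40 evaluation and external validation.

The evaluation scheme partitions the cohort into 5 near-equal folds, takes 3
as training and 2 as test (a 60/40 split that plain K-fold cross-validation
cannot produce directly), and repeats this 10 times. Subgroup labels are
derived once from the full cohort (autoencoder -> Cox screening -> K-means ->
orientation) and held fixed; only the standardizer and the boosted-tree
classifier are refit inside each repetition, so no test sample influences any
fitted parameter within a repetition.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field

import numpy as np

from tallsurv.autoencoder import AutoencoderSpec, EncoderModel, LatentFeatures, encode, train_autoencoder
from tallsurv.classifier import (
    DEFAULT_GRID,
    BoostedClassifier,
    StandardizerParams,
    fit_standardizer,
    predict_risk,
    train_classifier,
)
from tallsurv.io_preprocess import ClinicalTable, EncoderInputTransform, ExpressionMatrix, filter_cohort, prepare_encoder_input
from tallsurv.subtyping import ClusterModel, SubgroupLabeling, cluster_kmeans, orient_labels, select_k_silhouette
from tallsurv.survival import SurvivalData, logrank_test, screen_features, time_dependent_auc

DAYS_PER_YEAR = 365.25

# per-stage seed derivation: child = SeedSequence([master, stage index])
_STAGE = {"autoencoder": 0, "kmeans": 1, "classifier": 2, "splits": 3}


def stage_seed(master_seed: int, stage: str) -> int:
    return int(np.random.SeedSequence([master_seed, _STAGE[stage]]).generate_state(1)[0] % 2**31)


@dataclass
class PipelineConfig:
    """Every tunable of the subtyping pipeline, validated up front."""

    pseudocount: float = 1.0
    autoencoder: AutoencoderSpec | None = None      # seed filled from master seed if None
    screening_alpha: float = 0.05
    k_min: int = 2
    k_max: int = 10
    kmeans_n_init: int = 10
    classifier_grid: dict = field(default_factory=lambda: dict(DEFAULT_GRID))
    cv_folds: int = 5
    n_reps: int = 10
    horizons_years: tuple[float, ...] = (3.0, 5.0)           # internal evaluation
    external_horizons_years: tuple[float, ...] = (1.0, 3.0)  # external validation
    min_gene_overlap: float = 0.95
    feature_space: str = "latent-screened"  # latent-screened | latent-all | genes
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.screening_alpha <= 1):
            raise ValueError("screening_alpha must be in (0, 1]")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("need 2 <= k_min <= k_max")
        if self.feature_space not in ("latent-screened", "latent-all", "genes"):
            raise ValueError(f"unknown feature_space {self.feature_space!r}")
        if self.n_reps < 1 or self.cv_folds < 2:
            raise ValueError("n_reps >= 1 and cv_folds >= 2 required")
        if not (0 < self.min_gene_overlap <= 1):
            raise ValueError("min_gene_overlap must be in (0, 1]")
        if self.autoencoder is None:
            self.autoencoder = AutoencoderSpec(seed=stage_seed(self.seed, "autoencoder"))

    def horizons_days(self, external: bool = False) -> list[float]:
        yrs = self.external_horizons_years if external else self.horizons_years
        return [y * DAYS_PER_YEAR for y in yrs]


@dataclass
class SplitPlan:
    """One repetition: 5 near-equal folds, 3 as training, 2 as test."""

    repetition: int
    fold_of: np.ndarray     # fold index per sample position
    train_folds: tuple[int, ...]
    seed: int

    def __post_init__(self) -> None:
        sizes = np.bincount(self.fold_of, minlength=5)
        if sizes.max() - sizes.min() > 1:
            raise ValueError("fold sizes must differ by at most 1")
        frac = np.isin(self.fold_of, self.train_folds).mean()
        if not (0.58 <= frac <= 0.62):
            raise ValueError(f"training fraction {frac:.3f} outside [0.58, 0.62]")

    @property
    def train_mask(self) -> np.ndarray:
        return np.isin(self.fold_of, self.train_folds)

    @property
    def test_mask(self) -> np.ndarray:
        return ~self.train_mask


def make_split_plans(sample_ids: list[str], n_reps: int = 10, seed: int = 0) -> list[SplitPlan]:
    """Independent repetitions of shuffle -> 5 folds -> draw 3 training folds."""
    n = len(sample_ids)
    if n < 10:
        raise ValueError("need at least 10 samples for 5-fold 60/40 partitioning")
    plans = []
    for rep in range(n_reps):
        rep_seed = int(np.random.SeedSequence([seed, _STAGE["splits"], rep]).generate_state(1)[0] % 2**31)
        rng = np.random.default_rng(rep_seed)
        order = rng.permutation(n)
        fold_of = np.empty(n, dtype=int)
        for f, chunk in enumerate(np.array_split(order, 5)):
            fold_of[chunk] = f
        train_folds = tuple(sorted(rng.choice(5, size=3, replace=False).tolist()))
        plans.append(SplitPlan(repetition=rep, fold_of=fold_of, train_folds=train_folds, seed=rep_seed))
    return plans


@dataclass
class PipelineBundle:
    """Everything needed to push a new cohort through the trained pipeline."""

    transform: EncoderInputTransform
    encoder: EncoderModel
    screened_idx: np.ndarray
    cluster: ClusterModel
    labeling: SubgroupLabeling
    standardizer: StandardizerParams
    classifier: BoostedClassifier
    config: PipelineConfig
    manifest: dict

    def features_for(self, latent: LatentFeatures, prepared: ExpressionMatrix) -> np.ndarray:
        if self.config.feature_space == "latent-screened":
            return latent.values[:, self.screened_idx]
        if self.config.feature_space == "latent-all":
            return latent.values
        return prepared.values


def _feature_matrix(config: PipelineConfig, latent: LatentFeatures, prepared: ExpressionMatrix, screened_idx: np.ndarray) -> np.ndarray:
    if config.feature_space == "latent-screened":
        return latent.values[:, screened_idx]
    if config.feature_space == "latent-all":
        return latent.values
    return prepared.values


def full_pipeline(
    expression: ExpressionMatrix, clinical: ClinicalTable, config: PipelineConfig
) -> tuple[PipelineBundle, SubgroupLabeling, dict]:
    """prepare -> autoencoder -> encode -> Cox screen -> silhouette K ->
    K-means -> orient -> boosted classifier; returns bundle, labels, manifest.

    Aborts with a clear error when screening selects zero features (rather
    than silently clustering on unscreened features).
    """
    clinical, expression = filter_cohort(clinical, expression)
    surv = SurvivalData(clinical.time, clinical.event)
    prepared, transform = prepare_encoder_input(expression, config.pseudocount)
    encoder = train_autoencoder(prepared, config.autoencoder, transform=transform)
    latent = encode(encoder, prepared)
    screened = screen_features(latent.values, surv, alpha=config.screening_alpha)
    if len(screened) == 0:
        raise RuntimeError(
            f"Cox screening selected no latent features at alpha={config.screening_alpha}; "
            "subtyping aborted"
        )
    km_seed = stage_seed(config.seed, "kmeans")
    best_k, sil_scores = select_k_silhouette(
        latent.values[:, screened], config.k_min, config.k_max, seed=km_seed, n_init=config.kmeans_n_init
    )
    raw_labels, cluster = cluster_kmeans(latent.values[:, screened], best_k, seed=km_seed, n_init=config.kmeans_n_init)
    if best_k == 2:
        labeling = orient_labels(raw_labels, surv, sample_ids=expression.sample_ids)
    else:
        warnings.warn(f"silhouette selected K={best_k}; labels left in cluster order (orientation is binary-only)")
        labeling = SubgroupLabeling(expression.sample_ids, raw_labels, {"oriented": False})
    cluster.silhouette_by_k = sil_scores

    feats = _feature_matrix(config, latent, prepared, screened)
    std = fit_standardizer(feats)
    clf = train_classifier(
        std.apply(feats), labeling.labels, grid=config.classifier_grid,
        cv_folds=config.cv_folds, seed=stage_seed(config.seed, "classifier"),
    )
    manifest = {
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGE},
        "n_samples": expression.n_samples,
        "n_genes": expression.n_genes,
        "autoencoder": asdict(config.autoencoder) | {"hidden_widths": list(config.autoencoder.hidden_widths)},
        "ae_loss_history": encoder.loss_history,
        "screening_alpha": config.screening_alpha,
        "n_screened_features": int(len(screened)),
        "screened_feature_indices": screened.tolist(),
        "selected_k": int(best_k),
        "silhouette_by_k": {str(k): v for k, v in sil_scores.items()},
        "subgroup_sizes": {f"K{g}": int((labeling.labels == g).sum()) for g in np.unique(labeling.labels)},
        "orientation": labeling.orientation,
        "feature_space": config.feature_space,
        "classifier_best_params": clf.best_params,
        "classifier_cv_accuracy": max(row["mean_accuracy"] for row in clf.cv_table),
    }
    bundle = PipelineBundle(
        transform=transform, encoder=encoder, screened_idx=screened, cluster=cluster,
        labeling=labeling, standardizer=std, classifier=clf, config=config, manifest=manifest,
    )
    return bundle, labeling, manifest


@dataclass
class EvaluationResult:
    per_repetition: list[dict]
    mean_logrank_p: float | None
    mean_auc: dict[float, float | None]
    n_untestable_logrank: int
    n_untestable_auc: dict[float, int]

    def to_dict(self) -> dict:
        return {
            "per_repetition": self.per_repetition,
            "mean_logrank_p": self.mean_logrank_p,
            "mean_auc": {str(k): v for k, v in self.mean_auc.items()},
            "n_untestable_logrank": self.n_untestable_logrank,
            "n_untestable_auc": {str(k): v for k, v in self.n_untestable_auc.items()},
        }


def run_repeated_evaluation(
    features: np.ndarray,
    surv: SurvivalData,
    labeling: SubgroupLabeling,
    plans: list[SplitPlan],
    horizons: list[float],
    grid: dict | None = None,
    cv_folds: int = 5,
) -> EvaluationResult:
    """Per repetition: refit standardizer + classifier on the training
    partition (labels fixed from the full cohort), evaluate the test
    partition by predicted-subgroup log-rank and risk-score AUC at each
    horizon. Untestable repetitions are excluded from means and counted.
    """
    features = np.asarray(features, dtype=float)
    rows: list[dict] = []
    for plan in plans:
        tr, te = plan.train_mask, plan.test_mask
        std = fit_standardizer(features[tr])
        clf = train_classifier(std.apply(features[tr]), labeling.labels[tr], grid=grid, cv_folds=cv_folds, seed=plan.seed)
        pred, risk = predict_risk(clf, std, features[te])
        surv_te = surv.subset(te)
        row: dict = {"repetition": plan.repetition, "n_train": int(tr.sum()), "n_test": int(te.sum())}
        if len(np.unique(pred)) < 2:
            warnings.warn(f"repetition {plan.repetition}: single-class test predictions; log-rank untestable")
            row["logrank_p"] = None
        else:
            _, p = logrank_test(surv_te, pred)
            row["logrank_p"] = p
        for h in horizons:
            try:
                row[f"auc@{h:g}"] = time_dependent_auc(risk, surv_te, h).auc
            except ValueError as exc:
                warnings.warn(f"repetition {plan.repetition}: AUC at {h:g} untestable ({exc})")
                row[f"auc@{h:g}"] = None
        rows.append(row)

    ps = [r["logrank_p"] for r in rows if r["logrank_p"] is not None]
    mean_auc: dict[float, float | None] = {}
    n_unt_auc: dict[float, int] = {}
    for h in horizons:
        vals = [r[f"auc@{h:g}"] for r in rows if r[f"auc@{h:g}"] is not None]
        mean_auc[h] = float(np.mean(vals)) if vals else None
        n_unt_auc[h] = len(rows) - len(vals)
    return EvaluationResult(
        per_repetition=rows,
        mean_logrank_p=float(np.mean(ps)) if ps else None,
        mean_auc=mean_auc,
        n_untestable_logrank=len(rows) - len(ps),
        n_untestable_auc=n_unt_auc,
    )


def validate_external(
    bundle: PipelineBundle,
    expression: ExpressionMatrix,
    clinical: ClinicalTable,
    horizons: list[float] | None = None,
) -> tuple[SubgroupLabeling, float | None, dict[float, float | None]]:
    """Push an external cohort through the stored transform -> encoder ->
    standardizer -> classifier and test predicted-subgroup survival.

    Requires the external cohort to share at least ``config.min_gene_overlap``
    of the training gene set; missing genes are imputed at the training
    per-gene minimum with a warning.
    """
    clinical, expression = filter_cohort(clinical, expression)
    genes_needed = bundle.transform.gene_ids
    missing = bundle.transform.missing_genes(expression)
    coverage = 1.0 - len(missing) / len(genes_needed)
    if coverage < bundle.config.min_gene_overlap:
        raise ValueError(
            f"external cohort covers {coverage:.1%} of the training gene set "
            f"(threshold {bundle.config.min_gene_overlap:.1%}); missing e.g. {missing[:5]}"
        )
    if missing:
        warnings.warn(f"{len(missing)} training gene(s) absent from external cohort; imputed at training minimum")
    prepared = bundle.transform.apply(expression)
    latent = encode(bundle.encoder, prepared)
    feats = bundle.features_for(latent, prepared)
    pred, risk = predict_risk(bundle.classifier, bundle.standardizer, feats)
    labeling = SubgroupLabeling(expression.sample_ids, pred, {"source": "classifier prediction"})
    surv = SurvivalData(clinical.time, clinical.event)
    if horizons is None:
        horizons = bundle.config.horizons_days(external=True)
    if len(np.unique(pred)) < 2:
        warnings.warn("external predictions are single-class; log-rank untestable")
        p = None
    else:
        _, p = logrank_test(surv, pred)
    aucs: dict[float, float | None] = {}
    for h in horizons:
        try:
            aucs[h] = time_dependent_auc(risk, surv, h).auc
        except ValueError as exc:
            warnings.warn(f"external AUC at {h:g} untestable ({exc})")
            aucs[h] = None
    return labeling, p, aucs
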