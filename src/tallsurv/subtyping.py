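"""K-means subtyping of Cox-screened latent features.

K is selected by mean silhouette coefficient over K = 2..10 (ties toward the
smaller K), and with K = 2 the labels are oriented so that "K1" names the
poor-survival subgroup: the group with the lower Kaplan-Meier survival at the
latest time both groups reach, with event rate as the tie-break.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from tallsurv.survival import SurvivalData, km_estimate, restricted_mean_survival


@dataclass
class ClusterModel:
    k: int
    centroids: np.ndarray
    seed: int
    silhouette_by_k: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("K must be at least 2")
        if self.centroids.shape[0] != self.k:
            raise ValueError("centroid count must equal K")

    def assign(self, values: np.ndarray) -> np.ndarray:
        d = ((values[:, None, :] - self.centroids[None, :, :]) ** 2).sum(axis=2)
        return d.argmin(axis=1)


@dataclass
class SubgroupLabeling:
    """Per-sample subgroup labels; with K = 2, label 1 ("K1") has worse survival."""

    sample_ids: list[str]
    labels: np.ndarray
    orientation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.sample_ids):
            raise ValueError("labels and sample ids differ in length")

    def name(self, label: int) -> str:
        return f"K{label}"


def cluster_kmeans(values: np.ndarray, k: int, seed: int = 0, n_init: int = 10) -> tuple[np.ndarray, ClusterModel]:
    """Best of ``n_init`` k-means++ restarts by within-cluster sum of squares."""
    values = np.asarray(values, dtype=float)
    if k < 2:
        raise ValueError("K must be at least 2")
    if k > values.shape[0]:
        raise ValueError(f"cannot form {k} clusters from {values.shape[0]} samples")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(values)
    if len(np.unique(labels)) < k:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed + 1)
        labels = km.fit_predict(values)
        if len(np.unique(labels)) < k:
            raise RuntimeError(f"k-means produced an empty cluster for K={k}")
    return labels, ClusterModel(k=k, centroids=km.cluster_centers_, seed=seed)


def select_k_silhouette(
    values: np.ndarray, k_min: int = 2, k_max: int = 10, seed: int = 0, n_init: int = 10
) -> tuple[int, dict[int, float]]:
    """Mean silhouette coefficient (Euclidean) for each K; best K maximises it.

    Ties break toward the smaller K. Requires more samples than ``k_max``.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] <= k_max:
        raise ValueError(f"need more than k_max={k_max} samples, got {values.shape[0]}")
    scores: dict[int, float] = {}
    for k in range(k_min, k_max + 1):
        labels, _ = cluster_kmeans(values, k, seed=seed, n_init=n_init)
        scores[k] = float(silhouette_score(values, labels, metric="euclidean"))
    best = max(sorted(scores), key=lambda k: scores[k])  # sorted -> ties pick smaller K
    return best, scores


def orient_labels(labels: np.ndarray, s: SurvivalData, sample_ids: list[str] | None = None) -> SubgroupLabeling:
    """Name the poor-survival cluster K1 (two-cluster case).

    The group with the smaller restricted mean survival time (area under the
    KM curve up to the latest time observed in both groups) becomes K1. A
    single KM tail point would hinge on a handful of long survivors, whereas
    the restricted mean integrates the whole follow-up window. Exact ties
    fall back to the higher event rate, then to the smaller group (with a
    warning).
    """
    labels = np.asarray(labels, dtype=int)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"orientation requires exactly 2 groups, got {len(uniq)}")
    if sample_ids is None:
        sample_ids = [str(i) for i in range(len(labels))]
    masks = {g: labels == g for g in uniq}
    t_common = min(s.time[m].max() for m in masks.values())
    kms = {g: km_estimate(s.subset(m)) for g, m in masks.items()}
    rmst = {g: restricted_mean_survival(kms[g], t_common) for g in uniq}
    surv_end = {g: float(kms[g].survival_at(t_common)) for g in uniq}
    ev_rate = {g: float(s.event[m].mean()) for g, m in masks.items()}
    g0, g1 = uniq
    if rmst[g0] != rmst[g1]:
        worse = g0 if rmst[g0] < rmst[g1] else g1
    elif surv_end[g0] != surv_end[g1]:  # a death step exactly at the horizon
        worse = g0 if surv_end[g0] < surv_end[g1] else g1
    elif ev_rate[g0] != ev_rate[g1]:
        worse = g0 if ev_rate[g0] > ev_rate[g1] else g1
    else:
        warnings.warn("subgroups have indistinguishable survival; naming the smaller group K1")
        worse = g0 if masks[g0].sum() <= masks[g1].sum() else g1
    out = (labels == worse).astype(int)
    return SubgroupLabeling(
        sample_ids=list(sample_ids),
        labels=out,
        orientation={
            "k1_source_cluster": int(worse),
            "restricted_mean_survival": {f"K{int(lab == worse)}": rmst[lab] for lab in uniq},
            "horizon": float(t_common),
            "event_rate": {f"K{int(lab == worse)}": ev_rate[lab] for lab in uniq},
        },
    )
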