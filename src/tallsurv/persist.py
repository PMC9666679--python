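"""Pipeline-bundle persistence: one directory holding the fitted transform,
encoder weights, cluster model, standardizer, boosted classifier and run
manifest, sufficient to re-apply the trained pipeline to an external cohort.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
from xgboost import XGBClassifier

from tallsurv.autoencoder import AutoencoderSpec, EncoderModel
from tallsurv.classifier import BoostedClassifier, StandardizerParams
from tallsurv.evaluation import PipelineBundle, PipelineConfig
from tallsurv.subtyping import ClusterModel, SubgroupLabeling


def save_bundle(bundle: PipelineBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.encoder.save(out / "encoder.npz")  # embeds the input transform
    np.savez(
        out / "arrays.npz",
        screened_idx=bundle.screened_idx,
        centroids=bundle.cluster.centroids,
        std_center=bundle.standardizer.center,
        std_scale=bundle.standardizer.scale,
        std_zero_variance=bundle.standardizer.zero_variance,
    )
    # persist the booster itself; the sklearn wrapper is rebuilt at load time
    bundle.classifier.model.get_booster().save_model(str(out / "classifier.ubj"))
    cfg = asdict(bundle.config)
    cfg["autoencoder"]["hidden_widths"] = list(bundle.config.autoencoder.hidden_widths)
    meta = {
        "config": cfg,
        "cluster": {"k": bundle.cluster.k, "seed": bundle.cluster.seed,
                    "silhouette_by_k": {str(k): v for k, v in bundle.cluster.silhouette_by_k.items()}},
        "classifier": {"best_params": bundle.classifier.best_params,
                       "cv_table": bundle.classifier.cv_table,
                       "n_features": bundle.classifier.n_features,
                       "seed": bundle.classifier.seed},
        "labeling": {"sample_ids": bundle.labeling.sample_ids,
                     "labels": bundle.labeling.labels.tolist(),
                     "orientation": bundle.labeling.orientation},
        "manifest": bundle.manifest,
    }
    (out / "bundle.json").write_text(json.dumps(meta, indent=1))


def load_bundle(in_dir: str | Path) -> PipelineBundle:
    src = Path(in_dir)
    meta = json.loads((src / "bundle.json").read_text())
    cfg_d = dict(meta["config"])
    ae = dict(cfg_d.pop("autoencoder"))
    ae["hidden_widths"] = tuple(ae["hidden_widths"])
    cfg_d["classifier_grid"] = dict(cfg_d["classifier_grid"])
    for key in ("horizons_years", "external_horizons_years"):
        cfg_d[key] = tuple(cfg_d[key])
    config = PipelineConfig(autoencoder=AutoencoderSpec(**ae), **cfg_d)
    encoder = EncoderModel.load(src / "encoder.npz")
    arrays = np.load(src / "arrays.npz")
    xgb = XGBClassifier()
    xgb.load_model(str(src / "classifier.ubj"))
    clf = BoostedClassifier(
        model=xgb,
        best_params=meta["classifier"]["best_params"],
        cv_table=meta["classifier"]["cv_table"],
        n_features=meta["classifier"]["n_features"],
        seed=meta["classifier"]["seed"],
    )
    cluster = ClusterModel(
        k=meta["cluster"]["k"],
        centroids=arrays["centroids"],
        seed=meta["cluster"]["seed"],
        silhouette_by_k={int(k): v for k, v in meta["cluster"]["silhouette_by_k"].items()},
    )
    labeling = SubgroupLabeling(
        sample_ids=meta["labeling"]["sample_ids"],
        labels=np.asarray(meta["labeling"]["labels"], dtype=int),
        orientation=meta["labeling"]["orientation"],
    )
    std = StandardizerParams(
        center=arrays["std_center"], scale=arrays["std_scale"], zero_variance=arrays["std_zero_variance"]
    )
    return PipelineBundle(
        transform=encoder.transform,
        encoder=encoder,
        screened_idx=arrays["screened_idx"],
        cluster=cluster,
        labeling=labeling,
        standardizer=std,
        classifier=clf,
        config=config,
        manifest=meta["manifest"],
    )
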