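"""The full training workflow.

fit per-system factors -> stack the (n, 4) parameter matrix -> center
columns -> Ward linkage -> cut at k groups -> stratified 10% holdout ->
refit one parameter set per group on the training portion -> build and
normalize descriptors -> train the classifier (validated on the holdout)
-> bundle everything and report mean absolute errors per subset and
evaluation mode.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .classify import ANNClassifier, TrainConfig, count_mistakes, train_ann
from .data_model import (
    AtomReferenceTable,
    ModelBundle,
    ScaleParams,
    SystemRecord,
)
from .featurize import FeatureSchema, build_features, default_schema, fit_normalizer, apply_normalizer
from .grouping import center_columns, cut_to_groups, stratified_holdout, ward_linkage, element_occurrence
from .predict import mae_report, predict_many
from .system_fit import DEFAULT_RIDGE, build_parameter_matrix, fit_group_params
from .classify import ANNModel

__all__ = ["TrainReport", "train_pipeline", "trivial_single_group_ann"]


@dataclass
class TrainReport:
    """Everything the training run measured."""

    k: int
    labels: np.ndarray
    train_ids: list[str]
    validation_ids: list[str]
    group_sizes: list[int]
    group_mae_at_fit: list[float]
    mae: dict[str, float]               # "<subset>/<mode>" -> kcal/mol
    classifier_history: dict
    element_occurrence: list[dict[str, float]]
    parameter_matrix: np.ndarray
    timings: dict[str, float] = field(default_factory=dict)


def trivial_single_group_ann(n_features: int) -> ANNModel:
    """A constant classifier for the degenerate one-group model."""
    z8 = np.zeros((n_features, 8))
    return ANNModel(W1=z8, b1=np.zeros(8), W2=np.zeros((8, 8)), b2=np.zeros(8),
                    W3=np.zeros((8, 1)), b3=np.zeros(1))


def train_pipeline(
    molecules: Sequence[SystemRecord],
    atoms: Sequence[SystemRecord],
    ref: AtomReferenceTable,
    k: int = 4,
    holdout_fraction: float = 0.10,
    ridge: float = DEFAULT_RIDGE,
    seed: int = 0,
    schema: FeatureSchema | None = None,
    train_config: TrainConfig | None = None,
) -> tuple[ModelBundle, TrainReport]:
    """Run the full workflow and return the model bundle plus its report.

    All molecules must carry a reference heat of formation.  Deterministic
    for fixed seeds: the holdout split uses ``seed`` and the classifier uses
    ``train_config.seed`` (defaulting to ``seed``).
    """
    t0 = time.perf_counter()
    schema = schema or default_schema()
    missing = [m.id for m in molecules if m.dhf_exp is None]
    if missing:
        raise ValueError(f"training requires dhf_exp for every molecule; missing: {missing[:5]}")
    systems = [(m, atoms, m.dhf_exp) for m in molecules]
    timings = {}

    matrix = build_parameter_matrix(systems, ref, ridge=ridge)
    timings["per_system_fit"] = time.perf_counter() - t0

    t1 = time.perf_counter()
    centered, _ = center_columns(matrix)
    if k == 1:
        labels = np.zeros(len(molecules), dtype=int)
    else:
        labels = cut_to_groups(ward_linkage(centered), k)
    timings["clustering"] = time.perf_counter() - t1

    train_idx, val_idx = stratified_holdout(labels, fraction=holdout_fraction, seed=seed)

    group_params: list[ScaleParams] = []
    group_mae = []
    for g in range(k):
        idx = [i for i in train_idx if labels[i] == g]
        fit = fit_group_params([systems[i] for i in idx], ref, ridge=0.0)
        group_params.append(fit.params)
        group_mae.append(fit.mae)

    feats = np.vstack([
        m.features if m.features is not None else build_features(m, schema)
        for m in molecules
    ])
    normalizer = fit_normalizer(feats[train_idx])
    Z = apply_normalizer(feats, normalizer)

    t2 = time.perf_counter()
    cfg = train_config or TrainConfig(seed=seed)
    if k == 1:
        ann = trivial_single_group_ann(Z.shape[1])
        history = {"loss": np.zeros(0), "r2_train": float("nan")}
    else:
        ann, history = train_ann(
            Z[train_idx], labels[train_idx], n_groups=k, config=cfg,
            validation=(Z[val_idx], labels[val_idx]) if len(val_idx) else None,
        )
        history["train_mistakes"] = count_mistakes(ANNClassifier(ann), Z[train_idx],
                                                   labels[train_idx])
    timings["classifier"] = time.perf_counter() - t2

    bundle = ModelBundle(
        group_params=group_params,
        ann=ann,
        normalizer=normalizer,
        schema_id=schema.schema_id,
        metadata={
            "seed": seed,
            "k": k,
            "holdout_fraction": holdout_fraction,
            "ridge": ridge,
            "group_sizes": [int(np.sum(labels == g)) for g in range(k)],
        },
    )
    bundle.validate()

    subsets = {
        "train": [molecules[i].id for i in train_idx],
        "validation": [molecules[i].id for i in val_idx],
        "all": [m.id for m in molecules],
    }
    if not subsets["validation"]:
        subsets.pop("validation")
    mae: dict[str, float] = {}
    for mode in ("max_prob", "average"):
        rows = predict_many(molecules, atoms, bundle, ref, mode=mode)
        for name, value in mae_report(rows, subsets).items():
            mae[f"{name}/{mode}"] = value

    report = TrainReport(
        k=k,
        labels=labels,
        train_ids=subsets["train"],
        validation_ids=[molecules[i].id for i in val_idx],
        group_sizes=bundle.metadata["group_sizes"],
        group_mae_at_fit=group_mae,
        mae=mae,
        classifier_history=history,
        element_occurrence=[
            element_occurrence([molecules[i] for i in np.flatnonzero(labels == g)])
            for g in range(k)
        ],
        parameter_matrix=matrix,
        timings=timings,
    )
    return bundle, report
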