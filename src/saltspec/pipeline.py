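"""End-to-end orchestration: raw bands -> correction -> features -> selection
-> cube PCA -> score images -> OB training -> validation metrics.

This is the glue the command-line interface and the synthetic surrogate study
run; every step is a call into the stage modules.  Because synthetic samples
are deterministic in their identifiers, the pipeline streams over the dataset
in multiple passes instead of holding every image in memory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation_metrics import ConfusionMatrix, SplitPlan, metrics, pot_level_split
from .imaging_io import FeatureTable
from .ob_network import (
    ObClassifierNet,
    StemAllocation,
    TrainConfig,
    TrainedClassifier,
    allocate_stem_kernels,
    train_classifier,
)
from .preprocessing import correct_sample, segment_plant
from .selection_reduction import (
    PCAModel,
    choose_retained,
    fit_cube_pca,
    relief_weights,
    select_union_top_k,
    transform_to_score_images,
)
from .spectral_features import (
    assemble_fused_stack,
    build_feature_table,
    sr_index,
)
from .synthetic_scenes import SyntheticDataset


def _corrected_with_mask(dataset: SyntheticDataset, row):
    sample = dataset.sample(row.pot_id, row.view_index, row.period_days)
    corrected = correct_sample(sample, dataset.references)
    mask = segment_plant(corrected.bands["F740"])
    return corrected, mask


def compute_feature_table(dataset: SyntheticDataset) -> FeatureTable:
    """Correct, mask and reduce every sample to its scalar feature row."""
    pairs = (
        _corrected_with_mask(dataset, row) for row in dataset.metadata.itertuples()
    )
    return build_feature_table(pairs)


def select_sr_subset(table: FeatureTable, train_pots, k_neighbors: int = 10,
                     top_k: int = 5, target_count: int | None = None) -> list[str]:
    """Per-period ReliefF on the 55 SR columns (training pots only), top-k union.

    With ``target_count`` the union is adjusted to exactly that many names by
    each feature's best weight across periods (dropped from the bottom or
    padded from the next-ranked features), since the fused stack needs a
    fixed channel count.
    """
    sr_cols = [c for c in table.feature_names if "/" in c and c.startswith("R")]
    train_rows = table.df["pot_id"].isin(set(train_pots))
    per_period = []
    for period in sorted(table.df["period_days"].unique()):
        sub = table.select(train_rows & (table.df["period_days"] == period))
        per_period.append(relief_weights(sub, k=k_neighbors, columns=sr_cols))
    union = select_union_top_k(per_period, k=top_k)
    if target_count is None or len(union) == target_count:
        return union
    best = {c: max(r.weights[c] for r in per_period) for c in sr_cols}
    ranked = sorted(sr_cols, key=lambda c: (-best[c], c))
    if len(union) > target_count:
        keep = sorted(union, key=lambda c: (-best[c], c))[:target_count]
    else:
        keep = list(union)
        for c in ranked:
            if len(keep) == target_count:
                break
            if c not in keep:
                keep.append(c)
    return sorted(keep)


def _iter_stacks(dataset: SyntheticDataset, rows, sr_defs):
    for row in rows.itertuples():
        corrected, mask = _corrected_with_mask(dataset, row)
        yield assemble_fused_stack(corrected, mask, sr_defs)


@dataclass
class PipelineResult:
    """Everything the end-to-end run produces."""

    feature_table: FeatureTable
    selected_sr: list[str]
    split: SplitPlan
    pca_model: PCAModel
    retained: int
    allocation: StemAllocation
    trained: TrainedClassifier
    val_metrics: dict
    confusion: ConfusionMatrix


def run_pipeline(dataset: SyntheticDataset, n_train_pots: int, seed: int = 0,
                 variance_threshold: float = 0.95, max_retained: int = 9,
                 relief_k: int = 10, top_k: int = 5,
                 train_config: TrainConfig | None = None,
                 desk_stem_width: int = 16) -> PipelineResult:
    """Run the whole screening pipeline on a (synthetic) dataset.

    Training uses the compact OB network: per-channel stem banks apportioned
    to the retained components' variance contributions, one 16-wide stage,
    global pooling and a 2-class head.
    """
    table = compute_feature_table(dataset)
    split = pot_level_split(dataset.pot_labels(), n_train=n_train_pots, seed=seed)
    selected_names = select_sr_subset(table, split.train_pots,
                                      k_neighbors=relief_k, top_k=top_k,
                                      target_count=11)
    sr_defs = [sr_index(*name.split("/")) for name in selected_names]

    meta = dataset.metadata
    train_rows = meta[meta.pot_id.isin(set(split.train_pots))]
    model = fit_cube_pca(_iter_stacks(dataset, train_rows, sr_defs))
    retained = min(choose_retained(model, variance_threshold), max_retained)
    allocation = allocate_stem_kernels(
        model.evr[:retained], total=max(desk_stem_width, retained)
    )

    config = train_config or TrainConfig(batch_size=32, max_epochs=20, seed=seed)
    X, y, pots = [], [], []
    for row in meta.itertuples():
        corrected, mask = _corrected_with_mask(dataset, row)
        stack = assemble_fused_stack(corrected, mask, sr_defs)
        scores = transform_to_score_images(stack, model, retain=retained)
        X.append(scores.images.astype(np.float32))
        y.append(1 if row.class_label == "salt" else 0)
        pots.append(row.pot_id)
    X = np.stack(X)
    y = np.asarray(y)
    pots = np.asarray(pots)
    in_train = np.isin(pots, list(split.train_pots))
    net = ObClassifierNet(
        input_channels=retained,
        stem_width=allocation.total,
        stage_widths=(16,),
        n_classes=2,
        allocation=allocation,
        seed=config.seed,
    )
    trained = train_classifier(
        (X[in_train], y[in_train], pots[in_train]),
        (X[~in_train], y[~in_train], pots[~in_train]),
        net, config,
    )
    pred = trained.predict(X[~in_train])
    yva = y[~in_train]
    cm = ConfusionMatrix(
        tp=int(((pred == 1) & (yva == 1)).sum()),
        fp=int(((pred == 1) & (yva == 0)).sum()),
        fn=int(((pred == 0) & (yva == 1)).sum()),
        tn=int(((pred == 0) & (yva == 0)).sum()),
    )
    return PipelineResult(
        feature_table=table,
        selected_sr=selected_names,
        split=split,
        pca_model=model,
        retained=retained,
        allocation=allocation,
        trained=trained,
        val_metrics=metrics(cm),
        confusion=cm,
    )
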