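"""End-to-end orchestration: subjects -> features -> fused inputs -> CV.

This is the thin glue the examples, CLI and acceptance checks share.  It
keeps the per-stage modules decoupled: projections are computed on raw
component stacks, each subject's mask comes from its own gray-matter map,
and the experiment construction decides how channels are assembled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fusion import FusionSpec, build_model_input
from .ivip import FeatureVolume, project
from .model import ModelConfig
from .synthetic import CohortSpec, SyntheticSubject, generate_cohort
from .training import (
    FoldMetrics,
    SplitPlan,
    TrainConfig,
    aggregate_folds,
    cross_validate,
    make_split_plan,
)
from .volumes import compute_mask

__all__ = ["build_inputs", "ExperimentResult", "run_experiment", "small_model_config"]


def build_inputs(
    subjects: Sequence[SyntheticSubject],
    spec: FusionSpec,
    unimodal_feature: str = "smri",
    mask_threshold: float = 0.03,
) -> tuple[np.ndarray, np.ndarray, list[str], list]:
    """Assemble (X, y, class_names, subject_ids) for a cohort.

    X is (N, n_channels, D, H, W); y holds class indices into the sorted
    list of labels present in the cohort (AD < CN < MCI alphabetically,
    reported as class_names).
    """
    class_names = sorted({s.label for s in subjects})
    xs, ys, ids = [], [], []
    for s in subjects:
        mask = compute_mask(s.smri, mask_threshold)
        smri_feat = FeatureVolume(s.smri.grid, s.smri.values, "smri", s.subject_id)
        ivip_feat = None
        if spec.experiment != "unimodal" or unimodal_feature != "smri":
            ivip_feat = project(s.icn_stack, spec.ivip_kind)
        mi = build_model_input(
            spec, smri_feat, ivip_feat, mask,
            subject_id=s.subject_id, label=s.label, unimodal_feature=unimodal_feature,
        )
        xs.append(mi.as_array())
        ys.append(class_names.index(s.label))
        ids.append(s.subject_id)
    return np.stack(xs), np.array(ys), class_names, ids


def small_model_config(n_channels: int, n_classes: int, init_seed: int = 0) -> ModelConfig:
    """A compact configuration for small grids and desk-scale cohorts.

    Three conv blocks (8, 16, 32 filters) with the 3-2-1
    kernel/stride/padding combination, no extra pooling (the stride-2
    convolutions already shrink a 24-voxel axis to 3), adaptive average
    pooling to 1x1x1, and a 64/32 FC head.
    """
    return ModelConfig(
        n_channels=n_channels,
        n_classes=n_classes,
        conv_filters=(8, 16, 32),
        kernel_size=3,
        stride=2,
        padding=1,
        pool_stages=(),
        dropout_rate=0.5,
        fc_widths=(64, 32),
        init_seed=init_seed,
    )


@dataclass
class ExperimentResult:
    experiment: str
    ivip_kind: str
    unimodal_feature: str
    fold_metrics: list[FoldMetrics]
    summary: pd.DataFrame
    histories: list[pd.DataFrame]

    @property
    def mean_test_accuracy(self) -> float:
        return float(self.summary.loc["test_accuracy", "mean"])

    @property
    def pooled_counts(self) -> tuple[int, int]:
        """(correct, total) pooled over folds, for chi-squared comparisons."""
        return (
            sum(f.n_correct for f in self.fold_metrics),
            sum(f.n_test for f in self.fold_metrics),
        )


def run_experiment(
    subjects: Sequence[SyntheticSubject],
    fusion: FusionSpec,
    plan: SplitPlan,
    model_config: Optional[ModelConfig] = None,
    train_config: Optional[TrainConfig] = None,
    unimodal_feature: str = "smri",
) -> ExperimentResult:
    """Train and evaluate one experiment arm over every fold of a plan."""
    x, y, class_names, ids = build_inputs(subjects, fusion, unimodal_feature)
    index = {sid: i for i, sid in enumerate(ids)}
    mcfg = model_config or small_model_config(fusion.n_channels, len(class_names))
    tcfg = train_config or TrainConfig()
    fold_metrics, histories = cross_validate(
        x, y, plan, mcfg, tcfg, class_names, subject_index=index
    )
    return ExperimentResult(
        experiment=fusion.experiment,
        ivip_kind=fusion.ivip_kind,
        unimodal_feature=unimodal_feature,
        fold_metrics=fold_metrics,
        summary=aggregate_folds(fold_metrics),
        histories=histories,
    )
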