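"""Reproducible simulation experiments exercising the whole pipeline.

These are the study-shaped computations used to validate the scorer on
synthetic data with known truth: training a classifier from simulated
annotated patches (the study trained on 30 patches from 10 cases), recovery
of true TPS on artifact-free patches, directional bias under artifact modes,
and end-to-end concordance of estimated vs true scores across a study.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .detect import CellObject
from .features import BACKGROUND, TUMOR, ClassifierModel, TrainingAnnotation
from .pipeline import PipelineConfig, score_image
from .simulate import (
    ArtifactFlags,
    PatchSpec,
    StudySpec,
    SyntheticPatch,
    generate_patch,
    generate_study,
)

__all__ = [
    "make_training_annotations",
    "build_training_table",
    "train_study_classifier",
    "truth_class_of_cells",
    "classification_accuracy",
    "tps_recovery_experiment",
    "bias_experiment",
    "study_pipeline_scores",
]


def make_training_annotations(patch: SyntheticPatch) -> list[TrainingAnnotation]:
    """Tumor/background region annotations derived from the patch's compartments.

    Each compartment polygon is pulled back from the boundary by the spec's
    annotation margin, the way an annotator avoids ambiguous border cells.
    """
    anns = []
    margin = patch.spec.boundary_margin
    if patch.tumor_region is not None and not patch.tumor_region.is_empty:
        poly = patch.tumor_region.buffer(-margin)
        if not poly.is_empty:
            anns.append(TrainingAnnotation(poly, TUMOR))
    if patch.background_region is not None and not patch.background_region.is_empty:
        poly = patch.background_region.buffer(-margin)
        if not poly.is_empty:
            anns.append(TrainingAnnotation(poly, BACKGROUND))
    return anns


def _training_specs(
    seed: int,
    n_cases: int,
    patches_per_case: int,
    base_spec: PatchSpec,
) -> list[PatchSpec]:
    rng = np.random.default_rng(seed)
    specs = []
    for _ in range(n_cases):
        case_tpf = rng.uniform(0.0, 0.9)
        for _ in range(patches_per_case):
            specs.append(
                replace(
                    base_spec,
                    true_positive_fraction=float(np.clip(case_tpf + rng.uniform(-0.1, 0.1), 0, 1)),
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
            )
    return specs


def build_training_table(
    config: PipelineConfig,
    seed: int = 0,
    n_cases: int = 10,
    patches_per_case: int = 3,
    base_spec: PatchSpec | None = None,
) -> pd.DataFrame:
    """Labelled per-cell feature table from simulated annotated patches.

    Defaults mirror the study's training budget: 3 patches from each of 10
    cases (30 annotated images), spanning a range of staining levels.
    """
    from .features import label_cells_from_annotations
    from .pipeline import process_patch

    base = base_spec or PatchSpec(height=256, width=256, n_tumor_cells=40, n_background_cells=30)
    tables = []
    for pspec in _training_specs(seed, n_cases, patches_per_case, base):
        patch = generate_patch(pspec)
        cells, _ = process_patch(patch.rgb, config)
        tables.append(label_cells_from_annotations(cells, make_training_annotations(patch)))
    return pd.concat(tables, ignore_index=True)


def train_study_classifier(
    config: PipelineConfig,
    seed: int = 0,
    n_cases: int = 10,
    patches_per_case: int = 3,
    base_spec: PatchSpec | None = None,
) -> ClassifierModel:
    """Train the classifier from the study-budget simulated training set."""
    from .features import train_classifier

    table = build_training_table(config, seed, n_cases, patches_per_case, base_spec)
    return train_classifier(table, config.forest)


def truth_class_of_cells(patch: SyntheticPatch, cells: list[CellObject]) -> list[str | None]:
    """Ground-truth class of each detected cell, matched via the truth mask.

    A detected nucleus inherits the simulated cell whose truth nucleus label
    sits at its centroid (falling back to the truth cell mask); None when
    the detection matches no simulated cell.
    """
    by_id = {c.id: c for c in patch.cells}
    out: list[str | None] = []
    for cell in cells:
        r = int(round(cell.nucleus.centroid[0]))
        c = int(round(cell.nucleus.centroid[1]))
        r = min(max(r, 0), patch.nucleus_mask.shape[0] - 1)
        c = min(max(c, 0), patch.nucleus_mask.shape[1] - 1)
        label = int(patch.nucleus_mask[r, c]) or int(patch.cell_mask[r, c])
        sim = by_id.get(label)
        out.append(sim.cls if sim is not None else None)
    return out


def classification_accuracy(
    patch: SyntheticPatch, cells: list[CellObject]
) -> tuple[float, float, pd.DataFrame]:
    """(accuracy, balanced accuracy, per-cell table) vs simulator truth."""
    truth = truth_class_of_cells(patch, cells)
    rows = [
        {"truth": t, "pred": cell.label}
        for t, cell in zip(truth, cells)
        if t is not None and cell.label is not None
    ]
    table = pd.DataFrame(rows)
    if table.empty:
        return float("nan"), float("nan"), table
    acc = float((table["truth"] == table["pred"]).mean())
    recalls = [
        float((sub["pred"] == cls).mean())
        for cls, sub in table.groupby("truth")
    ]
    return acc, float(np.mean(recalls)), table


def tps_recovery_experiment(
    model: ClassifierModel,
    config: PipelineConfig,
    seeds: list[int],
    base_spec: PatchSpec | None = None,
    positive_fractions: list[float] | None = None,
) -> pd.DataFrame:
    """Estimated vs true TPS on artifact-free patches, one row per seed."""
    base = base_spec or PatchSpec(
        height=576, width=576, n_tumor_cells=320, n_background_cells=100
    )
    rows = []
    for i, seed in enumerate(seeds):
        tpf = (
            positive_fractions[i % len(positive_fractions)]
            if positive_fractions
            else base.true_positive_fraction
        )
        patch = generate_patch(replace(base, seed=seed, true_positive_fraction=tpf))
        score, _cells = score_image(patch.rgb, model, config, patch_id=f"seed{seed}")
        rows.append(
            {
                "seed": seed,
                "true_tps": patch.true_tps,
                "estimated_tps": score.tps,
                "error": score.tps - patch.true_tps,
                "n_tumor_true": sum(c.cls == "tumor" for c in patch.cells),
                "n_tumor_detected": score.n_tumor_cells,
            }
        )
    return pd.DataFrame(rows)


def bias_experiment(
    model: ClassifierModel,
    config: PipelineConfig,
    flags: ArtifactFlags,
    true_positive_fraction: float,
    seeds: list[int],
    base_spec: PatchSpec | None = None,
) -> pd.DataFrame:
    """Estimated-minus-true TPS under an artifact mode, one row per seed."""
    base = base_spec or PatchSpec(
        height=448, width=448, n_tumor_cells=150, n_background_cells=60
    )
    base = replace(base, artifacts=flags, true_positive_fraction=true_positive_fraction)
    rows = []
    for seed in seeds:
        patch = generate_patch(replace(base, seed=seed))
        score, _cells = score_image(patch.rgb, model, config, patch_id=f"seed{seed}")
        rows.append(
            {
                "seed": seed,
                "true_tps": patch.true_tps,
                "estimated_tps": score.tps,
                "bias": score.tps - patch.true_tps,
            }
        )
    return pd.DataFrame(rows)


def study_pipeline_scores(
    model: ClassifierModel,
    config: PipelineConfig,
    study_spec: StudySpec,
) -> pd.DataFrame:
    """Run the scorer over every patch of a simulated study (streaming).

    Returns the study truth table joined with automated patch scores.
    """
    results: list[dict] = []

    def callback(patch: SyntheticPatch) -> None:
        score, _ = score_image(patch.rgb, model, config)
        results.append(
            {
                "estimated_tps": score.tps,
                "n_tumor_detected": score.n_tumor_cells,
                "n_positive_detected": score.n_positive_tumor_cells,
                "scorable": score.scorable,
            }
        )

    dataset = generate_study(study_spec, keep_images=False, patch_callback=callback)
    scores = pd.DataFrame(results)
    out = pd.concat([dataset.truth.reset_index(drop=True), scores], axis=1)
    out.attrs["raters"] = dataset.raters
    return out
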