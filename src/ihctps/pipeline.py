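"""End-to-end scoring pipeline: RGB patch in, TPS out.

Glues the stages together the way the study workflow does: color
deconvolution -> nucleus detection in the hematoxylin channel -> cell
expansion -> 67-feature computation -> random-forest classification ->
DAB-OD positivity calling -> patch TPS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detect import CellObject, DetectionParams, detect_nuclei, expand_cells
from .features import (
    ClassifierModel,
    ForestConfig,
    TrainingAnnotation,
    classify_cells,
    compute_features,
    label_cells_from_annotations,
    train_classifier,
)
from .scoring import DEFAULT_DAB_THRESHOLD, PatchScore, score_patch
from .stain import DEFAULT_WHITE_POINT, StainChannels, StainVectors, deconvolve, rgb_to_od

__all__ = ["PipelineConfig", "process_patch", "score_image", "train_from_annotations"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything that determines a scoring run (serialized beside outputs)."""

    stain_vectors: StainVectors = field(default_factory=StainVectors.hdab)
    detection: DetectionParams = field(default_factory=DetectionParams)
    forest: ForestConfig = field(default_factory=ForestConfig)
    dab_threshold: float = DEFAULT_DAB_THRESHOLD
    white_point: float = DEFAULT_WHITE_POINT

    def validate(self) -> None:
        self.detection.validate()
        if self.dab_threshold <= 0:
            raise ValueError("dab_threshold must be > 0")
        if self.white_point <= 0:
            raise ValueError("white_point must be > 0")


def process_patch(
    rgb: np.ndarray, config: PipelineConfig
) -> tuple[list[CellObject], StainChannels]:
    """Detect cells and compute their features from an RGB patch."""
    config.validate()
    od = rgb_to_od(rgb, config.white_point)
    channels = deconvolve(od, config.stain_vectors)
    nuclei = detect_nuclei(channels.hematoxylin, config.detection)
    cells = expand_cells(nuclei, channels.hematoxylin.shape, config.detection)
    compute_features(cells, channels)
    return cells, channels


def score_image(
    rgb: np.ndarray,
    model: ClassifierModel,
    config: PipelineConfig,
    patch_id: str = "patch",
) -> tuple[PatchScore, list[CellObject]]:
    """Full automated TPS for one patch; returns the cells for audit."""
    cells, channels = process_patch(rgb, config)
    classify_cells(model, cells)
    score = score_patch(cells, channels, config.dab_threshold, patch_id)
    return score, cells


def train_from_annotations(
    items: list[tuple[np.ndarray, list[TrainingAnnotation]]],
    config: PipelineConfig,
) -> ClassifierModel:
    """Train the tumor/background classifier from annotated RGB patches.

    ``items`` pairs each training image with its region annotations. The
    batch equivalent of the interactive annotate-train loop; calling it
    again with appended annotations reproduces iterative retraining.
    """
    import pandas as pd

    if not items:
        raise ValueError("no training annotations provided")
    tables = []
    for rgb, annotations in items:
        cells, _ = process_patch(rgb, config)
        tables.append(label_cells_from_annotations(cells, annotations))
    table = pd.concat(tables, ignore_index=True)
    return train_classifier(table, config.forest)
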