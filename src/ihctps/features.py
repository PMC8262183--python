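"""Per-cell morphometric features and the tumor-vs-background classifier.

Each detected cell is summarized by a frozen 67-entry feature vector:
nucleus/cell/cytoplasm geometry, per-compartment intensity statistics of the
hematoxylin and DAB OD channels, and local-context features (neighbor counts
and distances, plus neighborhood-smoothed versions of selected features over
a 25 px radius). A random-forest ("random trees") classifier trained from
polygon annotations of tumor vs background regions assigns each cell a class.

The manifest of 67 feature names is data: it ships with every trained model
(as a hash) and classification refuses to run against a mismatched manifest,
so retraining is always self-consistent.
"""

from __future__ import annotations

import hashlib
import pickle
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon
from skimage import measure
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .detect import CellObject
from .stain import StainChannels

__all__ = [
    "FEATURE_MANIFEST",
    "MANIFEST_HASH",
    "TUMOR",
    "BACKGROUND",
    "TrainingAnnotation",
    "ForestConfig",
    "ClassifierModel",
    "AnnotationConflictError",
    "ManifestMismatchError",
    "compute_features",
    "label_cells_from_annotations",
    "train_classifier",
    "classify_cells",
]

TUMOR = "tumor"
BACKGROUND = "background"

#: Radius (px) of the local-context neighborhood.
CONTEXT_RADIUS = 25.0

_GEOMETRY = (
    "nucleus_area",
    "nucleus_perimeter",
    "nucleus_circularity",
    "nucleus_eccentricity",
    "nucleus_max_caliper",
    "nucleus_min_caliper",
    "nucleus_solidity",
    "cell_area",
    "cell_perimeter",
    "cell_circularity",
    "cell_max_caliper",
    "cell_min_caliper",
    "cytoplasm_area",
    "nucleus_cell_area_ratio",
)
_STAINS = ("hematoxylin", "dab")
_COMPARTMENTS = ("nucleus", "cytoplasm", "cell")
_STATS = ("mean", "std", "min", "max", "range")
_INTENSITY = tuple(
    f"{comp}_{stain}_{stat}" for comp in _COMPARTMENTS for stain in _STAINS for stat in _STATS
)
_DENSITY = (
    "neighbor_count_25px",
    "mean_neighbor_distance_25px",
    "nearest_neighbor_distance",
)
_MEANS = tuple(f"{comp}_{stain}_mean" for comp in _COMPARTMENTS for stain in _STAINS)
_SMOOTHED = tuple(f"smoothed_25px_{name}" for name in _GEOMETRY + _MEANS)

#: The frozen 67-name feature manifest, in computation order.
FEATURE_MANIFEST: tuple[str, ...] = _GEOMETRY + _INTENSITY + _DENSITY + _SMOOTHED
assert len(FEATURE_MANIFEST) == 67

MANIFEST_HASH = hashlib.sha256(",".join(FEATURE_MANIFEST).encode()).hexdigest()


class AnnotationConflictError(ValueError):
    """A cell centroid falls inside polygons of different classes."""


class ManifestMismatchError(ValueError):
    """Model and feature vectors were built with different manifests."""


@dataclass(frozen=True)
class TrainingAnnotation:
    """A simple (non-self-intersecting) polygon labelling a training region.

    Polygon coordinates are (x=col, y=row) image coordinates.
    """

    polygon: Polygon
    label: str
    patch_id: str = "patch"

    def validate(self) -> None:
        if self.label not in (TUMOR, BACKGROUND):
            raise ValueError(f"annotation class must be tumor/background, got {self.label!r}")
        if not self.polygon.is_valid:
            raise ValueError("annotation polygon is not simple/valid")


def _region_geometry(rows: np.ndarray, cols: np.ndarray) -> dict[str, float]:
    r0, c0 = int(rows.min()), int(cols.min())
    local = np.zeros((int(rows.max()) - r0 + 3, int(cols.max()) - c0 + 3), dtype=np.uint8)
    local[rows - r0 + 1, cols - c0 + 1] = 1
    rp = measure.regionprops(local)[0]
    area = float(rp.area)
    perimeter = float(rp.perimeter)
    if perimeter > 0:
        circ = min(4.0 * np.pi * area / perimeter**2, 1.01)
    else:
        circ = 1.0
    return {
        "area": area,
        "perimeter": perimeter,
        "circularity": circ,
        "eccentricity": float(rp.eccentricity),
        "max_caliper": float(rp.feret_diameter_max),
        "min_caliper": float(rp.axis_minor_length),
        "solidity": float(rp.solidity),
    }


def _intensity_stats(values: np.ndarray) -> tuple[float, float, float, float, float]:
    mean = float(values.mean())
    std = float(values.std())
    lo = float(values.min())
    hi = float(values.max())
    return mean, std, lo, hi, hi - lo


def compute_features(
    cells: list[CellObject] | CellObject,
    channels: StainChannels,
) -> np.ndarray:
    """Compute the 67-entry feature vector for each cell (in manifest order).

    Accepts a single cell (context features then see no neighbors) or a list.
    Intensity statistics are taken over measurement-time-clamped OD channels.
    Zero-expansion cells have no cytoplasm pixels; their cytoplasm intensity
    statistics fall back to the nucleus values and ``cytoplasm_from_nucleus``
    is flagged on the cell. Results are attached to ``cell.features`` and
    returned as an (n, 67) array.
    """
    single = isinstance(cells, CellObject)
    cell_list = [cells] if single else list(cells)
    n = len(cell_list)
    if n == 0:
        return np.zeros((0, len(FEATURE_MANIFEST)))

    clamped = channels.clamp() if not channels.clamped else channels
    stain_fields = {"hematoxylin": clamped.hematoxylin, "dab": clamped.dab}

    table = np.zeros((n, len(FEATURE_MANIFEST)))
    col = {name: i for i, name in enumerate(FEATURE_MANIFEST)}
    centroids = np.zeros((n, 2))

    for i, cell in enumerate(cell_list):
        nuc = cell.nucleus
        centroids[i] = nuc.centroid
        g_nuc = _region_geometry(nuc.rows, nuc.cols)
        g_cell = _region_geometry(cell.cell_rows, cell.cell_cols)
        table[i, col["nucleus_area"]] = g_nuc["area"]
        table[i, col["nucleus_perimeter"]] = g_nuc["perimeter"]
        table[i, col["nucleus_circularity"]] = g_nuc["circularity"]
        table[i, col["nucleus_eccentricity"]] = g_nuc["eccentricity"]
        table[i, col["nucleus_max_caliper"]] = g_nuc["max_caliper"]
        table[i, col["nucleus_min_caliper"]] = g_nuc["min_caliper"]
        table[i, col["nucleus_solidity"]] = g_nuc["solidity"]
        table[i, col["cell_area"]] = g_cell["area"]
        table[i, col["cell_perimeter"]] = g_cell["perimeter"]
        table[i, col["cell_circularity"]] = g_cell["circularity"]
        table[i, col["cell_max_caliper"]] = g_cell["max_caliper"]
        table[i, col["cell_min_caliper"]] = g_cell["min_caliper"]
        table[i, col["cytoplasm_area"]] = float(cell.cytoplasm_rows.size)
        table[i, col["nucleus_cell_area_ratio"]] = g_nuc["area"] / g_cell["area"]

        compartments = {
            "nucleus": (nuc.rows, nuc.cols),
            "cytoplasm": (cell.cytoplasm_rows, cell.cytoplasm_cols),
            "cell": (cell.cell_rows, cell.cell_cols),
        }
        if cell.cytoplasm_rows.size == 0:
            compartments["cytoplasm"] = (nuc.rows, nuc.cols)
            cell.cytoplasm_from_nucleus = True
        for comp, (rr, cc) in compartments.items():
            for stain in _STAINS:
                vals = stain_fields[stain][rr, cc]
                stats = _intensity_stats(vals)
                for stat_name, value in zip(_STATS, stats):
                    table[i, col[f"{comp}_{stain}_{stat_name}"]] = value

    # Local-context features over a fixed-radius neighborhood of centroids.
    tree = cKDTree(centroids)
    neighbor_lists = tree.query_ball_point(centroids, r=CONTEXT_RADIUS)
    base_cols = [col[name] for name in _GEOMETRY + _MEANS]
    for i in range(n):
        idx = sorted(neighbor_lists[i])
        others = [j for j in idx if j != i]
        table[i, col["neighbor_count_25px"]] = float(len(others))
        if others:
            dists = np.linalg.norm(centroids[others] - centroids[i], axis=1)
            table[i, col["mean_neighbor_distance_25px"]] = float(dists.mean())
            table[i, col["nearest_neighbor_distance"]] = float(dists.min())
        else:
            table[i, col["mean_neighbor_distance_25px"]] = CONTEXT_RADIUS
            table[i, col["nearest_neighbor_distance"]] = CONTEXT_RADIUS
        smoothed = table[np.asarray(idx), :][:, base_cols].mean(axis=0)
        for k, name in enumerate(_GEOMETRY + _MEANS):
            table[i, col[f"smoothed_25px_{name}"]] = smoothed[k]

    for i, cell in enumerate(cell_list):
        cell.features = table[i].copy()

    return table[0] if single else table


def label_cells_from_annotations(
    cells: list[CellObject],
    annotations: list[TrainingAnnotation],
) -> pd.DataFrame:
    """Build a labelled training table from region annotations.

    A cell gets an annotation's class iff its nucleus centroid lies strictly
    inside the polygon (boundary excluded). Cells outside every polygon are
    excluded. Centroids claimed by polygons of both classes raise
    :class:`AnnotationConflictError` listing the offending cell ids.
    """
    for ann in annotations:
        ann.validate()
    rows = []
    labels = []
    conflicts = []
    for i, cell in enumerate(cells):
        if cell.features is None:
            raise ValueError("compute_features must run before labelling")
        r, c = cell.nucleus.centroid
        pt = Point(c, r)
        hits = {ann.label for ann in annotations if ann.polygon.contains(pt)}
        if len(hits) > 1:
            conflicts.append(cell.nucleus.id)
        elif len(hits) == 1:
            rows.append(cell.features)
            labels.append(next(iter(hits)))
    if conflicts:
        raise AnnotationConflictError(
            f"cells with conflicting annotation classes: {conflicts}"
        )
    table = pd.DataFrame(rows, columns=list(FEATURE_MANIFEST))
    table["label"] = labels
    return table


@dataclass(frozen=True)
class ForestConfig:
    """Random-forest hyperparameters (sqrt-features per split)."""

    n_trees: int = 100
    max_depth: int | None = None
    seed: int = 20210326


@dataclass
class ClassifierModel:
    """A fitted tumor-vs-background random forest plus its feature manifest."""

    forest: RandomForestClassifier
    config: ForestConfig
    manifest: tuple[str, ...]
    manifest_hash: str
    training_summary: dict = field(default_factory=dict)

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path) -> "ClassifierModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, cls):
            raise ManifestMismatchError("file does not contain a ClassifierModel")
        if model.manifest_hash != MANIFEST_HASH:
            raise ManifestMismatchError(
                "model was trained with a different feature manifest"
            )
        return model


def train_classifier(table: pd.DataFrame, config: ForestConfig | None = None) -> ClassifierModel:
    """Fit the random forest on a labelled training table.

    Requires both classes with >= 10 cells each and finite features. A
    stratified 25% held-out split provides the summary accuracy; the final
    forest is refit on all rows with the configured seed, so training is
    reproducible.
    """
    config = config or ForestConfig()
    if "label" not in table.columns:
        raise ValueError("training table must have a 'label' column")
    X = table[list(FEATURE_MANIFEST)].to_numpy(dtype=float)
    y = table["label"].to_numpy()
    bad = ~np.isfinite(X)
    if bad.any():
        names = [FEATURE_MANIFEST[j] for j in sorted(set(np.nonzero(bad)[1].tolist()))]
        raise ValueError(f"non-finite values in features: {names}")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training requires at least two classes")
    if counts.min() < 10:
        raise ValueError("training requires >= 10 cells per class")

    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=0.25, random_state=config.seed, stratify=y
    )
    probe = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_depth=config.max_depth,
        max_features="sqrt",
        random_state=config.seed,
    ).fit(X_tr, y_tr)
    heldout_accuracy = float((probe.predict(X_te) == y_te).mean())

    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_depth=config.max_depth,
        max_features="sqrt",
        random_state=config.seed,
    ).fit(X, y)
    summary = {
        "n_cells": int(len(y)),
        "class_counts": {str(c): int(k) for c, k in zip(classes, counts)},
        "heldout_accuracy": heldout_accuracy,
    }
    return ClassifierModel(forest, config, FEATURE_MANIFEST, MANIFEST_HASH, summary)


def classify_cells(model: ClassifierModel, cells: list[CellObject]) -> list[CellObject]:
    """Label every cell tumor/background; retain the tumor vote fraction."""
    if model.manifest_hash != MANIFEST_HASH:
        raise ManifestMismatchError("model manifest does not match this library version")
    if not cells:
        return cells
    X = []
    for cell in cells:
        if cell.features is None or len(cell.features) != len(FEATURE_MANIFEST):
            raise ManifestMismatchError("cells lack features in the model's manifest")
        X.append(cell.features)
    X = np.asarray(X, dtype=float)
    pred = model.forest.predict(X)
    proba = model.forest.predict_proba(X)
    tumor_col = list(model.forest.classes_).index(TUMOR) if TUMOR in model.forest.classes_ else None
    for i, cell in enumerate(cells):
        cell.label = str(pred[i])
        cell.tumor_vote = float(proba[i, tumor_col]) if tumor_col is not None else 0.0
    return cells
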