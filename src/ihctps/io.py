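"""File formats: TIFF rasters, GeoJSON annotations, CSV tables, manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import mapping, shape
from skimage import measure

from .detect import CellObject
from .features import TrainingAnnotation
from .scoring import CaseScore, PatchScore

__all__ = [
    "write_rgb_tiff",
    "read_rgb_image",
    "write_label_tiff",
    "annotations_to_geojson",
    "geojson_to_annotations",
    "cells_to_geojson",
    "patch_scores_to_frame",
    "case_scores_to_frame",
    "read_rater_table",
    "write_manifest",
    "file_sha256",
]


def write_rgb_tiff(path, rgb: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(rgb, dtype=np.uint8), photometric="rgb")


def read_rgb_image(path) -> np.ndarray:
    """Read an 8-bit RGB TIFF/PNG raster."""
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        arr = tifffile.imread(path)
    else:
        from PIL import Image

        arr = np.asarray(Image.open(path).convert("RGB"))
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError(f"{path}: expected an RGB raster, got shape {arr.shape}")
    return arr.astype(np.uint8)


def write_label_tiff(path, labels: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(labels, dtype=np.int32))


def annotations_to_geojson(annotations: list[TrainingAnnotation]) -> dict:
    features = []
    for ann in annotations:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(ann.polygon),
                "properties": {"classification": ann.label, "patch_id": ann.patch_id},
            }
        )
    return {"type": "FeatureCollection", "features": features}


def geojson_to_annotations(doc: dict) -> list[TrainingAnnotation]:
    anns = []
    for feat in doc.get("features", []):
        geom = shape(feat["geometry"])
        props = feat.get("properties", {})
        anns.append(
            TrainingAnnotation(
                polygon=geom,
                label=props.get("classification", ""),
                patch_id=props.get("patch_id", "patch"),
            )
        )
    return anns


def _region_polygon(rows: np.ndarray, cols: np.ndarray) -> list[list[float]]:
    """Outline a pixel set as a GeoJSON-style (x, y) ring via marching squares."""
    r0, c0 = int(rows.min()), int(cols.min())
    mask = np.zeros((int(rows.max()) - r0 + 3, int(cols.max()) - c0 + 3), dtype=float)
    mask[rows - r0 + 1, cols - c0 + 1] = 1.0
    contours = measure.find_contours(mask, 0.5)
    contour = max(contours, key=len)
    return [[float(c + c0 - 1), float(r + r0 - 1)] for r, c in contour]


def cells_to_geojson(cells: list[CellObject]) -> dict:
    """One feature per cell: cell outline with the nucleus as an inner ring."""
    features = []
    for cell in cells:
        outer = _region_polygon(cell.cell_rows, cell.cell_cols)
        inner = _region_polygon(cell.nucleus.rows, cell.nucleus.cols)
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [outer, inner]},
                "properties": {
                    "cell_id": cell.nucleus.id,
                    "classification": cell.label,
                    "tumor_vote": cell.tumor_vote,
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


def patch_scores_to_frame(scores: list[PatchScore], case_ids: dict[str, str] | None = None) -> pd.DataFrame:
    rows = []
    for s in scores:
        rows.append(
            {
                "patch_id": s.patch_id,
                "case_id": (case_ids or {}).get(s.patch_id, ""),
                "n_tumor": s.n_tumor_cells,
                "n_positive": s.n_positive_tumor_cells,
                "tps": s.tps,
                "category": s.category,
                "threshold": s.dab_threshold_used,
                "scorable": s.scorable,
            }
        )
    return pd.DataFrame(rows)


def case_scores_to_frame(scores: list[CaseScore]) -> pd.DataFrame:
    rows = []
    for s in scores:
        rows.append(
            {
                "case_id": s.case_id,
                "n_patches": len(s.patch_scores),
                "pooled_tps": s.pooled_tps,
                "category": s.category,
                "scorable": s.scorable,
            }
        )
    return pd.DataFrame(rows)


def read_rater_table(path) -> pd.DataFrame:
    tab = pd.read_csv(path)
    for col in ("patch_id", "rater_id", "score"):
        if col not in tab.columns:
            raise ValueError(f"rater CSV missing column {col!r}")
    return tab


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, config, inputs: list[Path] | None = None, extra: dict | None = None) -> dict:
    """Write the run manifest (tool version, config, input hashes) as JSON."""
    from . import __version__

    def _jsonable(obj):
        try:
            return asdict(obj)
        except TypeError:
            return str(obj)

    manifest = {
        "tool": "ihctps",
        "version": __version__,
        "config": _jsonable(config),
        "config_hash": hashlib.sha256(
            json.dumps(_jsonable(config), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "inputs": {str(p): file_sha256(p) for p in (inputs or [])},
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
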