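"""Nucleus detection and proximity-constrained cell expansion.

Nuclei are segmented from the hematoxylin OD channel (Gaussian smoothing,
fixed OD threshold, hole filling, optional watershed splitting of touching
objects, area gating). Cell areas are then estimated by assigning every
background pixel within a fixed expansion radius to its nearest nucleus
(Euclidean distance to the nucleus pixel set, ties to the lower nucleus id),
which partitions tissue into disjoint cell regions around each nucleus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import measure
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

__all__ = ["DetectionParams", "NucleusObject", "CellObject", "detect_nuclei", "expand_cells"]


@dataclass(frozen=True)
class DetectionParams:
    """User-specified morphological parameters for nucleus/cell detection.

    Units: ``smoothing_sigma`` and ``cell_expansion`` in pixels,
    ``nucleus_threshold`` in OD, areas in px^2.
    """

    smoothing_sigma: float = 1.5
    nucleus_threshold: float = 0.1
    min_nucleus_area: float = 30.0
    max_nucleus_area: float = 800.0
    cell_expansion: float = 5.0
    split_by_shape: bool = True
    watershed_min_separation: int = 4

    def validate(self) -> None:
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be >= 0")
        if not (0 < self.min_nucleus_area < self.max_nucleus_area):
            raise ValueError("need 0 < min_nucleus_area < max_nucleus_area")
        if self.cell_expansion < 0:
            raise ValueError("cell_expansion must be >= 0")
        if self.watershed_min_separation < 1:
            raise ValueError("watershed_min_separation must be >= 1")


@dataclass
class NucleusObject:
    """A detected nucleus: connected pixel set with summary measurements."""

    id: int
    rows: np.ndarray
    cols: np.ndarray
    centroid: tuple[float, float]
    area: int
    mean_hematoxylin_od: float

    @property
    def pixel_set(self) -> set[tuple[int, int]]:
        return set(zip(self.rows.tolist(), self.cols.tolist()))


@dataclass
class CellObject:
    """A nucleus plus its expanded cell region.

    ``cell_rows/cols`` always contain the nucleus pixels; the cytoplasm is the
    set difference. ``features`` and ``label`` are filled downstream by the
    feature/classification stage.
    """

    nucleus: NucleusObject
    cell_rows: np.ndarray
    cell_cols: np.ndarray
    cytoplasm_rows: np.ndarray
    cytoplasm_cols: np.ndarray
    features: np.ndarray | None = None
    label: str | None = None
    tumor_vote: float | None = None
    cytoplasm_from_nucleus: bool = field(default=False)

    @property
    def cell_area(self) -> int:
        return int(self.cell_rows.size)

    @property
    def cell_pixel_set(self) -> set[tuple[int, int]]:
        return set(zip(self.cell_rows.tolist(), self.cell_cols.tolist()))


def detect_nuclei(hema: np.ndarray, params: DetectionParams) -> list[NucleusObject]:
    """Segment nuclei from a hematoxylin OD field.

    Pipeline: Gaussian smoothing -> OD threshold -> fill holes -> watershed
    split of touching objects (seeds are distance-transform maxima at least
    ``watershed_min_separation`` px apart, when ``split_by_shape``) -> discard
    components outside the area bounds. Deterministic for fixed inputs.
    """
    params.validate()
    hema = np.asarray(hema, dtype=float)
    if hema.ndim != 2:
        raise ValueError("hematoxylin field must be 2-D")
    if hema.size == 0:
        return []
    if not np.all(np.isfinite(hema)):
        raise ValueError("hematoxylin field contains non-finite values")

    sm = ndi.gaussian_filter(hema, params.smoothing_sigma) if params.smoothing_sigma > 0 else hema
    mask = sm > params.nucleus_threshold
    if not mask.any():
        return []
    mask = ndi.binary_fill_holes(mask)

    if params.split_by_shape:
        dist = ndi.distance_transform_edt(mask)
        comp = measure.label(mask, connectivity=2)
        peaks = peak_local_max(
            dist,
            min_distance=params.watershed_min_separation,
            labels=comp,
            exclude_border=False,
        )
        markers = np.zeros(mask.shape, dtype=np.int32)
        if len(peaks):
            markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        lab = watershed(-dist, markers, mask=mask, connectivity=2)
    else:
        lab = measure.label(mask, connectivity=2)

    nuclei: list[NucleusObject] = []
    next_id = 1
    objects = ndi.find_objects(lab)
    for idx, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        local = lab[sl] == idx
        area = int(local.sum())
        if not (params.min_nucleus_area <= area <= params.max_nucleus_area):
            continue
        rr, cc = np.nonzero(local)
        rows = (rr + sl[0].start).astype(np.int64)
        cols = (cc + sl[1].start).astype(np.int64)
        centroid = (float(rows.mean()), float(cols.mean()))
        mean_od = float(hema[rows, cols].mean())
        nuclei.append(NucleusObject(next_id, rows, cols, centroid, area, mean_od))
        next_id += 1
    return nuclei


def expand_cells(
    nuclei: list[NucleusObject],
    shape: tuple[int, int],
    params: DetectionParams,
) -> list[CellObject]:
    """Assign each pixel within ``cell_expansion`` of a nucleus to its cell.

    A pixel joins the nucleus whose pixel set is nearest by Euclidean
    distance; exact ties go to the lower nucleus id. Zero expansion yields
    cell == nucleus. Cells are pairwise disjoint by construction.
    """
    params.validate()
    h, w = shape
    radius = params.cell_expansion
    dist_best = np.full(shape, np.inf)
    label_best = np.zeros(shape, dtype=np.int32)
    pad = int(np.ceil(radius)) + 1

    for nuc in sorted(nuclei, key=lambda n: n.id):
        if nuc.rows.min() < 0 or nuc.cols.min() < 0 or nuc.rows.max() >= h or nuc.cols.max() >= w:
            raise ValueError(f"nucleus {nuc.id} lies outside the image bounds")
        r0 = max(int(nuc.rows.min()) - pad, 0)
        r1 = min(int(nuc.rows.max()) + pad + 1, h)
        c0 = max(int(nuc.cols.min()) - pad, 0)
        c1 = min(int(nuc.cols.max()) + pad + 1, w)
        local = np.zeros((r1 - r0, c1 - c0), dtype=bool)
        local[nuc.rows - r0, nuc.cols - c0] = True
        d = ndi.distance_transform_edt(~local)
        view = dist_best[r0:r1, c0:c1]
        sel = (d <= radius) & (d < view)
        view[sel] = d[sel]
        label_best[r0:r1, c0:c1][sel] = nuc.id

    cells: list[CellObject] = []
    for nuc in sorted(nuclei, key=lambda n: n.id):
        rr, cc = np.nonzero(label_best == nuc.id)
        is_nucleus = dist_best[rr, cc] == 0.0
        cyto_rows = rr[~is_nucleus].astype(np.int64)
        cyto_cols = cc[~is_nucleus].astype(np.int64)
        cells.append(
            CellObject(
                nucleus=nuc,
                cell_rows=rr.astype(np.int64),
                cell_cols=cc.astype(np.int64),
                cytoplasm_rows=cyto_rows,
                cytoplasm_cols=cyto_cols,
            )
        )
    return cells
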