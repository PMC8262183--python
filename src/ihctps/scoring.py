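"""Tumor proportion score (TPS) computation at cell, patch and case level.

A classified tumor cell is PD-L1 positive when the mean DAB optical density
over its whole cell region strictly exceeds a fixed threshold ("exceeded", so
equality is negative). A patch's TPS is the percentage of tumor cells called
positive; a case pools the raw counts of its patches, which is algebraically
the tumor-cell-count-weighted mean of the patch TPS values. Continuous scores
are binned into the clinical categories <1, 1-49 and >=50 percent only after
any averaging. The module also builds the multi-rater gold standard (average
the pathologists' continuous scores first, then categorize).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detect import CellObject
from .features import TUMOR
from .stain import StainChannels

__all__ = [
    "CATEGORY_LOW",
    "CATEGORY_MID",
    "CATEGORY_HIGH",
    "PatchScore",
    "CaseScore",
    "UnlabelledCellError",
    "call_positivity",
    "categorize",
    "score_patch",
    "score_case",
    "gold_standard",
    "rater_case_score",
    "calibrate_dab_threshold",
    "DEFAULT_DAB_THRESHOLD",
]

logger = logging.getLogger(__name__)

CATEGORY_LOW = "<1"
CATEGORY_MID = "1-49"
CATEGORY_HIGH = ">=50"

#: Default positivity threshold on mean cell DAB OD (configuration, not a
#: claim about the study's unstated empirical value).
DEFAULT_DAB_THRESHOLD = 0.2


class UnlabelledCellError(RuntimeError):
    """Positivity was requested for a cell that has not been classified."""


@dataclass
class PatchScore:
    patch_id: str
    n_tumor_cells: int
    n_positive_tumor_cells: int
    tps: float  # percent; NaN when unscorable
    category: str | None
    dab_threshold_used: float
    scorable: bool = True


@dataclass
class CaseScore:
    case_id: str
    patch_scores: list[PatchScore] = field(default_factory=list)
    pooled_tps: float = float("nan")
    category: str | None = None
    scorable: bool = True


def categorize(tps: float) -> str:
    """Clinical TPS category: <1 | 1-49 | >=50, boundaries at 1 and 50."""
    if not np.isfinite(tps) or tps < 0 or tps > 100:
        raise ValueError(f"TPS must lie in [0, 100], got {tps}")
    if tps < 1.0:
        return CATEGORY_LOW
    if tps < 50.0:
        return CATEGORY_MID
    return CATEGORY_HIGH


def mean_cell_dab(cell: CellObject, channels: StainChannels) -> float:
    """Mean DAB OD over the whole cell region (clamped at 0 for measurement)."""
    dab = channels.dab if channels.clamped else np.maximum(channels.dab, 0.0)
    return float(dab[cell.cell_rows, cell.cell_cols].mean())


def call_positivity(cell: CellObject, channels: StainChannels, threshold: float) -> bool:
    """True iff the cell's mean DAB OD strictly exceeds the threshold."""
    if cell.label is None:
        raise UnlabelledCellError("cell must be classified before positivity calling")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    return mean_cell_dab(cell, channels) > threshold


def score_patch(
    cells: list[CellObject],
    channels: StainChannels,
    threshold: float = DEFAULT_DAB_THRESHOLD,
    patch_id: str = "patch",
) -> PatchScore:
    """TPS for one patch: percent of tumor cells called DAB-positive.

    Background cells are ignored entirely. A patch with zero tumor cells is
    flagged unscorable (distinct from TPS 0) and logged.
    """
    tumor_cells = [c for c in cells if _require_label(c) == TUMOR]
    n_tumor = len(tumor_cells)
    if n_tumor == 0:
        logger.warning("patch %s has no tumor cells: unscorable", patch_id)
        return PatchScore(patch_id, 0, 0, float("nan"), None, threshold, scorable=False)
    n_pos = sum(call_positivity(c, channels, threshold) for c in tumor_cells)
    tps = 100.0 * n_pos / n_tumor
    return PatchScore(patch_id, n_tumor, int(n_pos), tps, categorize(tps), threshold)


def _require_label(cell: CellObject) -> str:
    if cell.label is None:
        raise UnlabelledCellError("cells must be classified before scoring")
    return cell.label


def score_case(patch_scores: list[PatchScore], case_id: str = "case") -> CaseScore:
    """Pool patch counts into a case-level TPS.

    pooled = 100 * (sum positives) / (sum tumor cells), identical to the
    tumor-count-weighted mean of patch TPS. Unscorable patches are excluded
    (not treated as 0%); a case with no scorable patch is itself unscorable.
    """
    scorable = [p for p in patch_scores if p.scorable]
    if not scorable:
        logger.warning("case %s has no scorable patches", case_id)
        return CaseScore(case_id, list(patch_scores), scorable=False)
    total = sum(p.n_tumor_cells for p in scorable)
    positive = sum(p.n_positive_tumor_cells for p in scorable)
    pooled = 100.0 * positive / total
    return CaseScore(case_id, list(patch_scores), pooled, categorize(pooled))


def gold_standard(raters: pd.DataFrame) -> pd.DataFrame:
    """Per-patch gold standard from a rater score table.

    ``raters`` has columns patch_id, rater_id, score (continuous percent).
    The gold standard averages the continuous scores first, then categorizes
    (never averages categories). Missing scores are dropped with a log entry;
    every patch must retain >= 2 raters.
    """
    _check_rater_table(raters)
    tab = raters.copy()
    missing = tab["score"].isna()
    if missing.any():
        logger.warning("dropping %d missing rater scores", int(missing.sum()))
        tab = tab[~missing]
    grouped = tab.groupby("patch_id")["score"]
    counts = grouped.count()
    if (counts < 2).any():
        short = counts[counts < 2].index.tolist()
        raise ValueError(f"patches with fewer than 2 rater scores: {short}")
    out = grouped.mean().to_frame("mean_score")
    out["category"] = out["mean_score"].map(categorize)
    out["n_raters"] = counts
    return out


def rater_case_score(raters: pd.DataFrame, tumor_counts: pd.DataFrame) -> pd.DataFrame:
    """Case-level rater scores weighted by automated tumor counts.

    ``tumor_counts`` has columns patch_id, case_id, n_tumor (from automated
    detection). Each rater's case score is the tumor-count-weighted mean of
    their continuous patch scores, then categorized.
    """
    _check_rater_table(raters)
    for col in ("patch_id", "case_id", "n_tumor"):
        if col not in tumor_counts.columns:
            raise ValueError(f"tumor_counts missing column {col!r}")
    merged = raters.merge(tumor_counts, on="patch_id", how="left", validate="many_to_one")
    if merged["n_tumor"].isna().any():
        orphans = merged.loc[merged["n_tumor"].isna(), "patch_id"].unique().tolist()
        raise ValueError(f"missing tumor counts for patches: {orphans}")
    def _weighted(group: pd.DataFrame) -> float:
        w = group["n_tumor"].to_numpy(dtype=float)
        s = group["score"].to_numpy(dtype=float)
        return float((w * s).sum() / w.sum())
    out = (
        merged.groupby(["case_id", "rater_id"])[["score", "n_tumor"]]
        .apply(_weighted)
        .to_frame("case_score")
        .reset_index()
    )
    out["category"] = out["case_score"].map(categorize)
    return out


def _check_rater_table(raters: pd.DataFrame) -> None:
    for col in ("patch_id", "rater_id", "score"):
        if col not in raters.columns:
            raise ValueError(f"rater table missing column {col!r}")
    valid = raters["score"].dropna()
    if ((valid < 0) | (valid > 100)).any():
        raise ValueError("rater scores must lie in [0, 100]")


def calibrate_dab_threshold(
    mean_ods: np.ndarray,
    is_positive: np.ndarray,
    grid: np.ndarray | None = None,
) -> tuple[float, pd.DataFrame]:
    """Sweep candidate thresholds against annotated positive/negative cells.

    Returns the accuracy-maximizing threshold (lowest such value on ties) and
    the full sweep table. This is the batch analogue of the interactive
    intensity-threshold tuning an operator would perform.
    """
    mean_ods = np.asarray(mean_ods, dtype=float)
    is_positive = np.asarray(is_positive, dtype=bool)
    if mean_ods.shape != is_positive.shape or mean_ods.size == 0:
        raise ValueError("mean_ods and is_positive must be equal-length, non-empty")
    if grid is None:
        grid = np.round(np.arange(0.02, 1.0, 0.02), 4)
    rows = []
    for t in grid:
        pred = mean_ods > t
        rows.append({"threshold": float(t), "accuracy": float((pred == is_positive).mean())})
    sweep = pd.DataFrame(rows)
    best = sweep.loc[sweep["accuracy"].idxmax(), "threshold"]
    return float(best), sweep
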