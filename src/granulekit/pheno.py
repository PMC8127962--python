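"""Cell-level phenotype statistics.

Percent of granule-positive cells per condition (>= 6 granules by default),
granule persistence across a paired treatment, and granule number/size
distribution summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import sem

log = logging.getLogger(__name__)

DEFAULT_POSITIVE_THRESHOLD = 6


@dataclass
class CellRecord:
    image_id: str
    cell_id: int
    condition: str
    granule_diameters: list[float] = field(default_factory=list)
    replicate: int = 1

    @property
    def granule_count(self) -> int:
        return len(self.granule_diameters)


def records_from_granule_frame(
    df: pd.DataFrame, condition: str = "default", replicate: int = 1
) -> list[CellRecord]:
    """Build cell records from a detect-module granule table (one row per
    granule).  Cells present in the image but without granules must be added
    by the caller; the table alone cannot know about them."""
    records = []
    for (image_id, cell_id), sub in df.groupby(["image_id", "cell_id"]):
        records.append(
            CellRecord(
                image_id=str(image_id),
                cell_id=int(cell_id),
                condition=condition,
                granule_diameters=sub["eq_diam_um"].tolist(),
                replicate=replicate,
            )
        )
    return records


def granule_positive_fraction(
    cells: list[CellRecord], threshold: int = DEFAULT_POSITIVE_THRESHOLD
) -> pd.DataFrame:
    """Percent of cells with >= threshold granules, per condition.

    Computed per replicate, then averaged across replicates with SEM
    (replicates are independent experiments, matching the error-bar
    convention).  Raises on an empty condition.
    """
    if not cells:
        raise ValueError("no cell records")
    df = pd.DataFrame(
        {
            "condition": [c.condition for c in cells],
            "replicate": [c.replicate for c in cells],
            "positive": [c.granule_count >= threshold for c in cells],
        }
    )
    out = []
    for cond, sub in df.groupby("condition"):
        per_rep = sub.groupby("replicate")["positive"].mean() * 100.0
        out.append(
            {
                "condition": cond,
                "percent_positive": float(per_rep.mean()),
                "sem": sem(per_rep.to_numpy()) if per_rep.size >= 2 else np.nan,
                "n_replicates": int(per_rep.size),
                "n_cells": int(len(sub)),
                "threshold": threshold,
            }
        )
    return pd.DataFrame(out)


def persistence_ratio(
    pre: list[CellRecord], post: list[CellRecord]
) -> tuple[pd.DataFrame, float, float | None]:
    """Granule persistence after a treatment: count(after)/count(before).

    Fields (images) are paired by ``image_id``; counts are summed over the
    cells of a field.  Fields with zero pre-treatment granules are excluded
    and logged.  Ratios above 1 are kept but flagged.  Returns the per-field
    table, the pooled mean, and its SEM.
    """
    def field_counts(records: list[CellRecord]) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in records:
            counts[c.image_id] = counts.get(c.image_id, 0) + c.granule_count
        return counts

    pre_counts = field_counts(pre)
    post_counts = field_counts(post)
    unmatched = set(pre_counts) ^ set(post_counts)
    if unmatched:
        raise ValueError(f"unpaired field(s): {sorted(unmatched)}")
    rows = []
    for image_id in sorted(pre_counts):
        n_pre = pre_counts[image_id]
        if n_pre == 0:
            log.warning("field %s: zero pre-treatment granules, excluded", image_id)
            continue
        ratio = post_counts[image_id] / n_pre
        if ratio > 1:
            log.warning("field %s: persistence %.3f > 1", image_id, ratio)
        rows.append(
            {
                "image_id": image_id,
                "pre_count": n_pre,
                "post_count": post_counts[image_id],
                "persistence": ratio,
                "flagged_gt1": ratio > 1,
            }
        )
    if not rows:
        raise ValueError("no fields with pre-treatment granules")
    table = pd.DataFrame(rows)
    vals = table["persistence"].to_numpy()
    return table, float(vals.mean()), (sem(vals) if vals.size >= 2 else None)


def granule_size_stats(cells: list[CellRecord]) -> pd.DataFrame:
    """Per-condition median diameter and per-cell count distribution."""
    if not any(c.granule_count for c in cells):
        raise ValueError("no granules in any cell")
    rows = []
    by_cond: dict[str, list[CellRecord]] = {}
    for c in cells:
        by_cond.setdefault(c.condition, []).append(c)
    for cond, recs in sorted(by_cond.items()):
        diams = np.concatenate(
            [np.asarray(c.granule_diameters, dtype=float) for c in recs]
        ) if any(c.granule_count for c in recs) else np.array([])
        counts = np.array([c.granule_count for c in recs], dtype=float)
        rows.append(
            {
                "condition": cond,
                "median_diameter_um": float(np.median(diams)) if diams.size else np.nan,
                "n_granules": int(diams.size),
                "count_median": float(np.median(counts)),
                "count_q1": float(np.percentile(counts, 25)),
                "count_q3": float(np.percentile(counts, 75)),
                "n_cells": int(counts.size),
            }
        )
    return pd.DataFrame(rows)
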