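"""Object-based colocalization and per-granule fold enrichment.

Granules from two channels of the same image are matched one-to-one within
each cell by greedily accepting the globally smallest remaining centroid
distance under a cutoff (0.5 um by default).  Fold enrichment of a signal
channel at a granule is the mean signal intensity over the granule's pixels
divided by the mean over the whole area of its cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import GranuleSet
from .stats import sem

log = logging.getLogger(__name__)

DEFAULT_CUTOFF_UM = 0.5


@dataclass
class Match:
    cell_id: int
    granule_a: int
    granule_b: int
    distance_um: float


@dataclass
class ColocResult:
    image_id: str
    cutoff_um: float
    matches: list[Match]
    n_reference: dict[int, int]  # cell -> granule count in set A
    n_other: dict[int, int]  # cell -> granule count in set B

    def matches_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "image_id": self.image_id,
                    "cell_id": m.cell_id,
                    "A_id": m.granule_a,
                    "B_id": m.granule_b,
                    "distance_um": m.distance_um,
                }
                for m in self.matches
            ],
            columns=["image_id", "cell_id", "A_id", "B_id", "distance_um"],
        )


def match_granules(
    set_a: GranuleSet, set_b: GranuleSet, cutoff_um: float = DEFAULT_CUTOFF_UM
) -> ColocResult:
    """Greedy one-to-one matching on within-cell centroid distances.

    All pairwise distances within a cell are pooled across the image, sorted,
    and accepted smallest-first while both granules are unmatched and the
    distance is <= cutoff.  Ties break deterministically on
    (cell_id, A_id, B_id).
    """
    if set_a.image_id != set_b.image_id:
        raise ValueError(
            f"image id mismatch: {set_a.image_id!r} vs {set_b.image_id!r}"
        )
    if set_a.pixel_size != set_b.pixel_size:
        raise ValueError("granule sets disagree on pixel size")
    px = set_a.pixel_size
    by_cell_a = set_a.by_cell()
    by_cell_b = set_b.by_cell()

    candidates: list[tuple[float, int, int, int]] = []
    for cell_id, gas in by_cell_a.items():
        gbs = by_cell_b.get(cell_id, [])
        for ga in gas:
            for gb in gbs:
                d = (
                    np.hypot(
                        ga.centroid[0] - gb.centroid[0],
                        ga.centroid[1] - gb.centroid[1],
                    )
                    * px
                )
                if d <= cutoff_um:
                    candidates.append((float(d), cell_id, ga.granule_id, gb.granule_id))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches = []
    for d, cell_id, a_id, b_id in candidates:
        if a_id in used_a or b_id in used_b:
            continue
        used_a.add(a_id)
        used_b.add(b_id)
        matches.append(Match(cell_id, a_id, b_id, d))
    cells = sorted(set(by_cell_a) | set(by_cell_b))
    return ColocResult(
        image_id=set_a.image_id,
        cutoff_um=cutoff_um,
        matches=matches,
        n_reference={c: len(by_cell_a.get(c, [])) for c in cells},
        n_other={c: len(by_cell_b.get(c, [])) for c in cells},
    )


def colocalization_fraction(
    result: ColocResult, reference: str = "A"
) -> tuple[dict[int, float], float]:
    """Percent of reference-set granules matched, per cell and pooled.

    Cells with zero reference granules are excluded from per-cell values and
    logged.  Raises if every cell is empty.
    """
    if reference not in ("A", "B"):
        raise ValueError("reference must be 'A' or 'B'")
    totals = result.n_reference if reference == "A" else result.n_other
    matched: dict[int, int] = {c: 0 for c in totals}
    for m in result.matches:
        matched[m.cell_id] += 1
    per_cell: dict[int, float] = {}
    skipped = 0
    for cell_id, n in totals.items():
        if n == 0:
            skipped += 1
            continue
        per_cell[cell_id] = 100.0 * matched[cell_id] / n
    if skipped:
        log.info(
            "image %s: %d cell(s) with zero reference granules excluded",
            result.image_id,
            skipped,
        )
    if not per_cell:
        raise ValueError(f"image {result.image_id}: no cells with reference granules")
    total_ref = sum(totals.values())
    pooled = 100.0 * len(result.matches) / total_ref
    return per_cell, pooled


@dataclass
class EnrichmentResult:
    per_granule: pd.DataFrame  # image_id, cell_id, granule_id, fold
    per_cell: pd.DataFrame  # cell_id, mean_fold, sem_fold, n

    @property
    def mean_fold(self) -> float:
        return float(self.per_granule["fold"].mean())

    @property
    def sem_fold(self) -> float | None:
        folds = self.per_granule["fold"].to_numpy()
        return sem(folds) if folds.size >= 2 else None


def fold_enrichment(
    granules: GranuleSet,
    signal_channel: np.ndarray,
    cell_mask: np.ndarray,
    exclude_granule_pixels: bool = False,
    excess: bool = False,
) -> EnrichmentResult:
    """Mean signal over each granule's pixels / mean over its whole cell area.

    ``exclude_granule_pixels`` removes all detected granule pixels from the
    cell mean (off by default: the denominator is the whole cell area);
    ``excess`` reports fold - 1.
    """
    signal = np.asarray(signal_channel, dtype=float)
    mask = np.asarray(cell_mask)
    if signal.shape != mask.shape:
        raise ValueError("signal channel and cell mask shapes differ")

    granule_pixels_by_cell: dict[int, np.ndarray] = {}
    if exclude_granule_pixels:
        gmask = np.zeros(mask.shape, dtype=bool)
        for g in granules.granules:
            gmask[g.pixel_set[:, 0], g.pixel_set[:, 1]] = True

    cell_means: dict[int, float] = {}
    for cid in sorted({g.cell_id for g in granules.granules}):
        sel = mask == cid
        if exclude_granule_pixels:
            sel = sel & ~gmask
        vals = signal[sel]
        if vals.size == 0 or vals.mean() == 0:
            raise ValueError(f"cell {cid}: zero whole-cell mean intensity")
        cell_means[cid] = float(vals.mean())

    rows = []
    for g in granules.granules:
        gvals = signal[g.pixel_set[:, 0], g.pixel_set[:, 1]]
        fold = float(gvals.mean() / cell_means[g.cell_id])
        rows.append(
            {
                "image_id": granules.image_id,
                "cell_id": g.cell_id,
                "granule_id": g.granule_id,
                "fold": fold - 1.0 if excess else fold,
            }
        )
    per_granule = pd.DataFrame(
        rows, columns=["image_id", "cell_id", "granule_id", "fold"]
    )
    agg = []
    for cid, sub in per_granule.groupby("cell_id"):
        folds = sub["fold"].to_numpy()
        agg.append(
            {
                "cell_id": cid,
                "mean_fold": float(folds.mean()),
                "sem_fold": sem(folds) if folds.size >= 2 else np.nan,
                "n": int(folds.size),
            }
        )
    per_cell = pd.DataFrame(agg, columns=["cell_id", "mean_fold", "sem_fold", "n"])
    return EnrichmentResult(per_granule=per_granule, per_cell=per_cell)
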