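"""Granule detection: Otsu thresholding and size-gated connected components.

The threshold maximizes the between-class variance ``w0 * w1 * (mu0 - mu1)^2``
over observed intensity levels with classes ``{x <= t}`` and ``{x > t}``; ties
resolve to the lowest maximizing level.  Foreground is split into 8-connected
components, components touching the image border or spanning more than one
cell are discarded, and the survivors are gated by equivalent diameter
(inclusive bounds, 0.4-2.0 um by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .imgproc import FieldImage

log = logging.getLogger(__name__)

DEFAULT_GATE = (0.4, 2.0)  # um, equivalent diameter


def otsu_threshold(intensities: np.ndarray) -> float:
    """Otsu threshold over the observed intensity levels.

    Returns the level t maximizing between-class variance with classes
    {x <= t} (background) and {x > t} (foreground); the lowest maximizing
    level wins ties.  Raises on a constant input.
    """
    x = np.asarray(intensities, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("degenerate histogram: empty input")
    levels, counts = np.unique(x, return_counts=True)
    if levels.size < 2:
        raise ValueError("degenerate histogram: fewer than 2 distinct levels")
    n = x.size
    # cumulative statistics of the lower class for every candidate level
    w0 = np.cumsum(counts)[:-1]  # last level cannot be a threshold
    s0 = np.cumsum(counts * levels)[:-1]
    total = float((counts * levels).sum())
    w1 = n - w0
    mu0 = s0 / w0
    mu1 = (total - s0) / w1
    bcv = (w0 / n) * (w1 / n) * (mu0 - mu1) ** 2
    best = int(np.argmax(bcv))  # argmax returns the first (lowest) maximizer
    return float(levels[best])


@dataclass
class Granule:
    """One detected granule and its per-object features."""

    granule_id: int
    cell_id: int
    centroid: tuple[float, float]  # (row, col), 0-based px
    area_px: int
    equivalent_diameter_um: float
    mean_intensity: float
    pixel_set: np.ndarray  # (n, 2) int array of (row, col)


@dataclass
class GranuleSet:
    image_id: str
    channel: str
    pixel_size: float
    granules: list[Granule]
    gate: tuple[float, float]
    threshold_used: float | dict[int, float]
    cell_ids: list[int] = field(default_factory=list)

    def by_cell(self) -> dict[int, list[Granule]]:
        out: dict[int, list[Granule]] = {c: [] for c in self.cell_ids}
        for g in self.granules:
            out.setdefault(g.cell_id, []).append(g)
        return out

    def __len__(self) -> int:
        return len(self.granules)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "image_id": self.image_id,
                    "channel": self.channel,
                    "cell_id": g.cell_id,
                    "granule_id": g.granule_id,
                    "row_px": g.centroid[0],
                    "col_px": g.centroid[1],
                    "area_px2": g.area_px,
                    "eq_diam_um": g.equivalent_diameter_um,
                    "mean_intensity": g.mean_intensity,
                }
                for g in self.granules
            ],
            columns=[
                "image_id",
                "channel",
                "cell_id",
                "granule_id",
                "row_px",
                "col_px",
                "area_px2",
                "eq_diam_um",
                "mean_intensity",
            ],
        )


_EIGHT = np.ones((3, 3), dtype=int)


def equivalent_diameter_um(area_px: int, pixel_size: float) -> float:
    """Diameter of the circle with the object's area, in micrometres."""
    return 2.0 * np.sqrt(area_px / np.pi) * pixel_size


def segment_granules(
    field_image: FieldImage,
    channel: str,
    gate: tuple[float, float] = DEFAULT_GATE,
    per_cell: bool = False,
) -> GranuleSet:
    """Detect granules in one channel of a (corrected) field image.

    The Otsu threshold is computed on within-cell pixels, per image by default
    or per cell with ``per_cell``.  A cell whose histogram is degenerate
    contributes zero granules (logged), rather than failing the image.
    """
    if channel not in field_image.channels:
        raise ValueError(f"no channel {channel!r} in image {field_image.image_id}")
    img = field_image.channels[channel]
    mask = field_image.cell_mask
    cell_ids = field_image.cell_ids()
    if not cell_ids:
        raise ValueError(f"empty cell mask in image {field_image.image_id}")

    foreground = np.zeros(img.shape, dtype=bool)
    if per_cell:
        thresholds: dict[int, float] = {}
        for cid in cell_ids:
            sel = mask == cid
            try:
                t = otsu_threshold(img[sel])
            except ValueError:
                log.warning(
                    "image %s cell %d: degenerate histogram, zero granules",
                    field_image.image_id,
                    cid,
                )
                continue
            thresholds[cid] = t
            foreground |= sel & (img > t)
        threshold_used: float | dict[int, float] = thresholds
    else:
        inside = mask > 0
        try:
            t = otsu_threshold(img[inside])
        except ValueError:
            log.warning(
                "image %s: degenerate histogram, zero granules", field_image.image_id
            )
            return GranuleSet(
                field_image.image_id, channel, field_image.pixel_size, [],
                gate, float("nan"), cell_ids,
            )
        foreground = inside & (img > t)
        threshold_used = t

    labels, n_comp = ndimage.label(foreground, structure=_EIGHT)
    granules: list[Granule] = []
    gid = 0
    h, w = img.shape
    for comp in range(1, n_comp + 1):
        rows, cols = np.nonzero(labels == comp)
        if (
            rows.min() == 0
            or cols.min() == 0
            or rows.max() == h - 1
            or cols.max() == w - 1
        ):
            continue  # truncated by the image border
        cells = np.unique(mask[rows, cols])
        if cells.size != 1 or cells[0] == 0:
            continue  # spans cells or leaks into background
        area = rows.size
        eq_d = equivalent_diameter_um(area, field_image.pixel_size)
        if not (gate[0] <= eq_d <= gate[1]):
            continue
        granules.append(
            Granule(
                granule_id=gid,
                cell_id=int(cells[0]),
                centroid=(float(rows.mean()), float(cols.mean())),
                area_px=int(area),
                equivalent_diameter_um=float(eq_d),
                mean_intensity=float(img[rows, cols].mean()),
                pixel_set=np.column_stack([rows, cols]),
            )
        )
        gid += 1
    return GranuleSet(
        image_id=field_image.image_id,
        channel=channel,
        pixel_size=field_image.pixel_size,
        granules=granules,
        gate=gate,
        threshold_used=threshold_used,
        cell_ids=cell_ids,
    )
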