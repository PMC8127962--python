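"""Field images, illumination-field estimation, and image correction.

The correction model is multiplicative shading times additive background:
``raw = illumination * signal + autofluorescence``.  The illumination field is
estimated as an exponentiated low-order 2D polynomial fitted robustly (granules
and other bright outliers are iteratively downweighted) on cytosol/background
pixels, then applied as ``corrected = max(raw / field - autofluorescence, 0)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class FieldImage:
    """One multi-channel 2D field with its physical scale and cell labeling.

    channels    name -> 2D float array (arbitrary units, >= 0)
    pixel_size  micrometres per pixel
    cell_mask   integer label image; 0 = background, k = cell k
    """

    channels: dict[str, np.ndarray]
    pixel_size: float
    cell_mask: np.ndarray
    image_id: str = "image"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        self.cell_mask = np.asarray(self.cell_mask)
        if self.cell_mask.ndim != 2:
            raise ValueError("cell_mask must be 2D")
        for name in list(self.channels):
            arr = np.asarray(self.channels[name], dtype=float)
            if arr.shape != self.cell_mask.shape:
                raise ValueError(
                    f"channel {name!r} shape {arr.shape} != mask shape "
                    f"{self.cell_mask.shape}"
                )
            if np.any(arr < 0):
                raise ValueError(f"channel {name!r} has negative intensities")
            self.channels[name] = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.cell_mask.shape

    def cell_ids(self) -> list[int]:
        ids = np.unique(self.cell_mask)
        return [int(i) for i in ids if i != 0]


def _poly_terms(order: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(order + 1) for j in range(order + 1 - i)]


def _design_matrix(rows: np.ndarray, cols: np.ndarray, shape, order: int) -> np.ndarray:
    # coordinates scaled to [-1, 1] for conditioning
    y = 2.0 * rows / max(shape[0] - 1, 1) - 1.0
    x = 2.0 * cols / max(shape[1] - 1, 1) - 1.0
    return np.column_stack([(y**i) * (x**j) for i, j in _poly_terms(order)])


def estimate_illumination_field(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    poly_order: int = 2,
    n_iter: int = 5,
    clip_sigma: float = 2.5,
) -> np.ndarray:
    """Estimate a smooth multiplicative illumination field, mean 1 over the mask.

    Fits a 2D polynomial to log intensity on ``mask`` pixels with iterative
    sigma-clipping (Tukey-style downweighting of outliers such as granules),
    and exponentiates, guaranteeing strict positivity.

    Parameters
    ----------
    image : 2D intensities (a.u.).
    mask : boolean array of pixels to use; defaults to all positive pixels.
    poly_order : polynomial order of the log-field surface.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2D")
    if mask is None:
        use = img > 0
    else:
        use = np.asarray(mask, dtype=bool) & (img > 0)
    rows, cols = np.nonzero(use)
    n_terms = len(_poly_terms(poly_order))
    if rows.size < n_terms:
        raise ValueError(
            f"degenerate fit: order {poly_order} needs >= {n_terms} pixels, "
            f"got {rows.size}"
        )
    A = _design_matrix(rows, cols, img.shape, poly_order)
    b = np.log(img[rows, cols])

    w = np.ones_like(b)
    coef = None
    for _ in range(max(n_iter, 1)):
        Aw = A * w[:, None]
        coef, _, rank, _ = np.linalg.lstsq(Aw, b * w, rcond=None)
        if rank < n_terms:
            raise ValueError(
                f"degenerate fit: rank {rank} < {n_terms} terms at order "
                f"{poly_order} on {rows.size} pixels"
            )
        resid = b - A @ coef
        scale = 1.4826 * np.median(np.abs(resid - np.median(resid)))
        if scale <= 0:
            break
        w = (np.abs(resid) <= clip_sigma * scale).astype(float)
        if w.sum() < n_terms:  # keep enough support
            break

    rr, cc = np.indices(img.shape)
    full = _design_matrix(rr.ravel(), cc.ravel(), img.shape, poly_order) @ coef
    logf = full.reshape(img.shape)
    field = np.exp(logf)
    norm_mask = use if mask is None else np.asarray(mask, dtype=bool)
    field /= field[norm_mask].mean()
    return field


def correct_image(
    field_image: FieldImage,
    illumination: dict[str, np.ndarray] | np.ndarray | None = None,
    autofluorescence: dict[str, float] | float = 0.0,
) -> FieldImage:
    """Apply ``corrected = max(raw / illumination - autofluorescence, 0)``.

    ``illumination`` may be a single field shared by all channels, a per-channel
    dict, or None (no shading correction).  ``autofluorescence`` is a scalar or
    per-channel dict of scalars (or maps).
    """
    corrected = {}
    for name, raw in field_image.channels.items():
        if illumination is None:
            fld = None
        elif isinstance(illumination, dict):
            if name not in illumination:
                raise ValueError(f"no illumination field for channel {name!r}")
            fld = illumination[name]
        else:
            fld = illumination
        if fld is not None:
            fld = np.asarray(fld, dtype=float)
            if np.any(fld <= 0):
                raise ValueError("illumination field must be strictly positive")
            out = raw / fld
        else:
            out = raw.copy()
        if isinstance(autofluorescence, dict):
            if name not in autofluorescence:
                raise ValueError(f"no autofluorescence value for channel {name!r}")
            af = autofluorescence[name]
        else:
            af = autofluorescence
        out = np.maximum(out - af, 0.0)
        corrected[name] = out
    return FieldImage(
        channels=corrected,
        pixel_size=field_image.pixel_size,
        cell_mask=field_image.cell_mask,
        image_id=field_image.image_id,
        metadata={**field_image.metadata, "corrected": True},
    )


def estimate_autofluorescence(
    image: np.ndarray, cell_mask: np.ndarray, granule_mask: np.ndarray | None = None
) -> float:
    """Median intensity of non-granule pixels inside cells (background proxy)."""
    inside = np.asarray(cell_mask) > 0
    if granule_mask is not None:
        inside &= ~np.asarray(granule_mask, dtype=bool)
    if not inside.any():
        raise ValueError("no usable pixels for autofluorescence estimate")
    return float(np.median(np.asarray(image, dtype=float)[inside]))
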