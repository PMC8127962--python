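"""Densitometry-derived quantities.

Fraction-in-pellet from solubility fractionation bands, and double-normalized
signaling ratios (active-GTPase pulldown or phospho/total pairs, standardized
to a control condition and optionally corrected for construct expression).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .stats import sem

#: canonical column names for a tidy densitometry table
TABLE_COLUMNS = ("analyte", "condition", "replicate", "band_intensity")


@dataclass
class FractionSummary:
    per_replicate: np.ndarray
    mean: float
    sem: float | None


def validate_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"densitometry table missing columns: {sorted(missing)}")
    if (df["band_intensity"] < 0).any():
        raise ValueError("band intensities must be >= 0")
    keys = df[["analyte", "condition", "replicate"]]
    if keys.duplicated().any():
        dup = keys[keys.duplicated()].iloc[0].tolist()
        raise ValueError(f"duplicate (analyte, condition, replicate) row: {dup}")
    return df


def fraction_in_pellet(
    pellet: Sequence[float], supernatant: Sequence[float]
) -> FractionSummary:
    """Per-replicate pellet/(pellet + supernatant), with mean +/- SEM.

    Raises for any replicate where both bands are zero (undefined ratio).
    """
    p = np.asarray(pellet, dtype=float)
    s = np.asarray(supernatant, dtype=float)
    if p.shape != s.shape:
        raise ValueError("pellet and supernatant must have equal length")
    if np.any(p < 0) or np.any(s < 0):
        raise ValueError("band intensities must be >= 0")
    total = p + s
    zero = total == 0
    if zero.any():
        raise ValueError(
            f"replicate(s) {np.nonzero(zero)[0].tolist()} have zero total band intensity"
        )
    frac = p / total
    return FractionSummary(
        per_replicate=frac,
        mean=float(frac.mean()),
        sem=sem(frac) if frac.size >= 2 else None,
    )


def fraction_in_supernatant(
    pellet: Sequence[float], supernatant: Sequence[float]
) -> FractionSummary:
    res = fraction_in_pellet(supernatant, pellet)
    return res


def _ratio(num: float, den: float, band: str) -> float:
    if den <= 0:
        raise ValueError(f"zero or negative denominator band: {band}")
    return num / den


def normalize_ras_gtp(
    gtp: float,
    total: float,
    expression: float,
    control: tuple[float, float, float],
    expression_normalize: bool = True,
) -> float:
    """Double-normalized active-GTPase level, control = 1.

    ``((gtp/total) / (gtp_ctrl/total_ctrl)) / (expression/expression_ctrl)``;
    the expression factor is skipped when ``expression_normalize`` is False
    (conditions within one construct, e.g. drug vs vehicle).
    """
    gtp_c, total_c, expr_c = control
    level = _ratio(gtp, total, "total") / _ratio(gtp_c, total_c, "control total")
    if expression_normalize:
        level /= _ratio(expression, expr_c, "control expression")
    return float(level)


def normalize_band_ratio(
    signal: float,
    loading: float,
    control_pair: tuple[float, float],
    expression_pair: tuple[float, float] | None = None,
) -> float:
    """Generic phospho/total style normalization (covers pERK/ERK etc.)."""
    sig_c, load_c = control_pair
    level = _ratio(signal, loading, "loading") / _ratio(sig_c, load_c, "control loading")
    if expression_pair is not None:
        expr, expr_c = expression_pair
        level /= _ratio(expr, expr_c, "control expression")
    return float(level)


def aggregate_ratios(
    ratios: Sequence[float], geometric: bool = False
) -> tuple[float, float | None]:
    """Replicate aggregation: arithmetic mean +/- SEM (default) or geometric mean.

    The geometric option suits multiplicative (lognormal) band noise; its
    second element is the SEM of the log-ratios mapped through exp.
    """
    r = np.asarray(ratios, dtype=float)
    if r.size == 0:
        raise ValueError("no ratios to aggregate")
    if geometric:
        if np.any(r <= 0):
            raise ValueError("geometric mean requires positive ratios")
        logs = np.log(r)
        gm = float(np.exp(logs.mean()))
        return gm, (float(np.exp(sem(logs)) - 1.0) * gm if r.size >= 2 else None)
    return float(r.mean()), (sem(r) if r.size >= 2 else None)
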