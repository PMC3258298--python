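"""Two-library miRNA count normalization and differential-expression screening.

A small-RNA experiment with one library per condition (here NC = normal
control, WC = cold-acclimated) yields one raw read count per miRNA per
library. Because the two libraries are sequenced to different depths the
WC counts must be rescaled by a library scaling factor *f* before fold
changes are comparable: the normalized WC count is ``count_wc / f``.

The screen calls a miRNA differentially expressed when its normalized fold
change exceeds a fold threshold (default 2) and its mean expression exceeds
an abundance threshold (default 64); the abundance cut guards against the
high relative noise of low-count miRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "estimate_norm_factor",
    "calibrate_norm_factor",
    "normalized_fold_change",
    "screen_differential",
]


@dataclass(frozen=True)
class NormalizationResult:
    """Library scaling factor of WC relative to NC (normalized WC = WC / f)."""

    factor_f: float
    method: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.factor_f) or self.factor_f <= 0:
            raise ValueError(f"scaling factor must be positive, got {self.factor_f}")


def _validate_counts(table: pd.DataFrame) -> pd.DataFrame:
    for col in ("mirna_id", "count_nc", "count_wc"):
        if col not in table.columns:
            raise ValueError(f"count table lacks required column {col!r}")
    if table["mirna_id"].duplicated().any():
        dups = table.loc[table["mirna_id"].duplicated(), "mirna_id"].tolist()
        raise ValueError(f"duplicate miRNA ids: {dups}")
    if (table[["count_nc", "count_wc"]] < 0).any().any():
        raise ValueError("negative counts are not allowed")
    return table


def estimate_norm_factor(
    table: pd.DataFrame,
    method: Literal["total", "median_ratio"] = "total",
) -> NormalizationResult:
    """Estimate the WC:NC library scaling factor from a count table.

    Parameters
    ----------
    table
        Count table with columns ``mirna_id``, ``count_nc``, ``count_wc``.
    method
        ``"total"``: ratio of library totals, f = Σ WC / Σ NC.
        ``"median_ratio"``: median of per-miRNA WC/NC ratios over rows with
        both counts positive; robust to a few strongly changed miRNAs.
    """
    _validate_counts(table)
    if len(table) == 0:
        raise ValueError("empty count table")
    if method == "total":
        tot_nc = float(table["count_nc"].sum())
        tot_wc = float(table["count_wc"].sum())
        if tot_nc == 0 or tot_wc == 0:
            raise ValueError("zero total counts in one of the libraries")
        return NormalizationResult(tot_wc / tot_nc, "total")
    if method == "median_ratio":
        both = table[(table["count_nc"] > 0) & (table["count_wc"] > 0)]
        if len(both) == 0:
            raise ValueError("no rows with positive counts in both libraries")
        ratios = both["count_wc"].to_numpy(float) / both["count_nc"].to_numpy(float)
        return NormalizationResult(float(np.median(ratios)), "median_ratio")
    raise ValueError(f"unknown normalization method {method!r}")


def calibrate_norm_factor(
    table: pd.DataFrame,
    exclude: str | None = None,
) -> float:
    """Recover the library scaling factor from reported normalized folds.

    Given a table that also carries ``reported_fold`` and
    ``reported_direction`` columns, each row implies a scaling factor:
    for up-regulated rows f = (WC/NC) / fold and for down-regulated rows
    f = (WC/NC) × fold. The calibrated estimate is the median of the
    per-row implied factors, optionally leaving one miRNA out so that the
    factor used for a miRNA is independent of its own reported fold.

    Parameters
    ----------
    table
        Count table with ``reported_fold`` (≥ 1) and ``reported_direction``
        (``"up"``/``"down"``) columns.
    exclude
        ``mirna_id`` of a row to leave out of the median.
    """
    _validate_counts(table)
    for col in ("reported_fold", "reported_direction"):
        if col not in table.columns:
            raise ValueError(f"calibration requires column {col!r}")
    rows = table if exclude is None else table[table["mirna_id"] != exclude]
    if len(rows) == 0:
        raise ValueError("no rows left to calibrate on")
    ratio = rows["count_wc"].to_numpy(float) / rows["count_nc"].to_numpy(float)
    fold = rows["reported_fold"].to_numpy(float)
    up = (rows["reported_direction"] == "up").to_numpy()
    implied = np.where(up, ratio / fold, ratio * fold)
    return float(np.median(implied))


def normalized_fold_change(
    count_nc: float,
    count_wc: float,
    f: float,
    pseudocount: float = 1.0,
) -> tuple[float, str | None]:
    """Normalized fold change and direction for one miRNA.

    The WC count is rescaled to the NC library depth (``count_wc / f``);
    the fold is the larger of the two normalized ratios so it is always
    ≥ 1, with ``direction`` "up" when the miRNA is higher in WC, "down"
    when higher in NC, and ``None`` at exact equality. Zero counts are
    replaced by ``pseudocount`` before the ratio is formed.
    """
    if count_nc < 0 or count_wc < 0:
        raise ValueError("counts must be non-negative")
    if f <= 0:
        raise ValueError("scaling factor must be positive")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    nc = count_nc if count_nc > 0 else pseudocount
    wc = count_wc if count_wc > 0 else pseudocount
    if nc == 0 or wc == 0:
        raise ValueError("zero count with zero pseudocount gives undefined fold")
    wc_norm = wc / f
    if wc_norm > nc:
        return wc_norm / nc, "up"
    if wc_norm < nc:
        return nc / wc_norm, "down"
    return 1.0, None


def screen_differential(
    table: pd.DataFrame,
    f: float,
    fold_threshold: float = 2.0,
    mean_threshold: float = 64.0,
    pseudocount: float = 1.0,
    mean_on: Literal["raw", "normalized"] = "raw",
) -> pd.DataFrame:
    """Apply the fold-change + abundance screen to a count table.

    A miRNA passes when ``normalized_fold > fold_threshold`` (strict) and
    its mean expression exceeds ``mean_threshold`` (strict). With
    ``mean_on="raw"`` the mean is over the raw library counts; with
    ``"normalized"`` both libraries are put on the deeper-library scale
    (NC is multiplied by f) before averaging, so the abundance cut is
    depth-adjusted without discarding reads.

    Returns the full table with ``normalized_fold``, ``direction``,
    ``mean_expression`` and ``passes_screen`` columns, sorted by
    descending fold.
    """
    _validate_counts(table)
    if fold_threshold <= 0 or mean_threshold <= 0:
        raise ValueError("thresholds must be positive")
    folds: list[float] = []
    dirs: list[str | None] = []
    for nc, wc in zip(table["count_nc"], table["count_wc"]):
        fold, direction = normalized_fold_change(nc, wc, f, pseudocount)
        folds.append(fold)
        dirs.append(direction)
    out = table.copy()
    out["normalized_fold"] = folds
    out["direction"] = dirs
    if mean_on == "raw":
        out["mean_expression"] = (out["count_nc"] + out["count_wc"]) / 2.0
    elif mean_on == "normalized":
        out["mean_expression"] = (out["count_nc"] * f + out["count_wc"]) / 2.0
    else:
        raise ValueError(f"unknown mean_on {mean_on!r}")
    out["passes_screen"] = (out["normalized_fold"] > fold_threshold) & (
        out["mean_expression"] > mean_threshold
    )
    return out.sort_values("normalized_fold", ascending=False).reset_index(drop=True)
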