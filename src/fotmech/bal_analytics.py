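"""Bronchoalveolar-lavage quantifications.

Covers the four BAL-derived read-outs of the study: relative qPCR
quantification by the ddCT method (amplification efficiency fixed at 2,
fold = 2^-ddCT, normalised to the control group), manual cell-differential
proportions, the SP-D/SP-B densitometry ratio normalised to the control
mean, and the capillary-surfactometer percent-open metric over the 2-min
recording window.  All operations start from tabulated numbers; image and
signal acquisition are upstream of this package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_data import CELL_TYPES

__all__ = [
    "SurfTrace",
    "ddct_fold_expression",
    "differential_fractions",
    "normalize_ratio",
    "percent_open",
]

SURF_WINDOW_S = 120.0


@dataclass(frozen=True)
class SurfTrace:
    """Capillary surfactometer recording: patency flag over a 2-min window."""

    time: np.ndarray  # seconds, uniform, spanning [0, 120)
    open_flag: np.ndarray  # 1 = capillary patent, 0 = blocked
    initial_pressure: float = float("nan")

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        flags = np.asarray(self.open_flag)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("time must be 1-D with >= 2 samples")
        if flags.shape != t.shape:
            raise ValueError("open_flag must match time in length")
        dt = float(np.median(np.diff(t)))
        duration = t.size * dt
        if abs(duration - SURF_WINDOW_S) > dt / 2:
            raise ValueError(
                f"trace must span exactly {SURF_WINDOW_S:.0f} s; got {duration:.3f} s"
            )
        if not np.isin(flags, (0, 1)).all():
            raise ValueError("open_flag must be 0/1")


def ddct_fold_expression(
    ct: pd.DataFrame,
    control_label: str,
    group_col: str = "group",
    gene_col: str = "gene",
    target_col: str = "ct_target",
    reference_col: str = "ct_reference",
) -> pd.DataFrame:
    """Relative fold expression by the ddCT method.

    dCT = CT_target - CT_reference per row; ddCT = dCT_group - dCT_control
    per gene; fold = 2^-ddCT.  The control group's fold is 1 for every gene
    by construction.  Raises if any gene lacks a control row.
    """
    ct = ct.copy()
    ct["dct"] = ct[target_col] - ct[reference_col]
    control = ct[ct[group_col] == control_label].set_index(gene_col)["dct"]
    missing = sorted(set(ct[gene_col]) - set(control.index))
    if missing:
        raise ValueError(f"no control ({control_label!r}) row for gene(s): {missing}")
    ct["ddct"] = ct["dct"] - ct[gene_col].map(control).to_numpy()
    ct["fold"] = np.power(2.0, -ct["ddct"])
    return ct[[group_col, gene_col, "dct", "ddct", "fold"]]


def differential_fractions(
    counts: pd.DataFrame,
    cell_types = CELL_TYPES,
    group_cols = ("treatment", "dose_label", "day"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-animal differential proportions plus group mean and SD.

    Each row's counts are divided by its own total (which must be positive);
    proportions therefore sum to 1 per animal.
    """
    cell_types = [c for c in cell_types if c in counts.columns]
    if not cell_types:
        raise ValueError("no cell-type columns found in the counts table")
    mat = counts[cell_types].to_numpy(dtype=float)
    if np.any(mat < 0):
        raise ValueError("negative cell counts")
    totals = mat.sum(axis=1)
    if np.any(totals <= 0):
        bad = counts.index[totals <= 0].tolist()
        raise ValueError(f"rows with zero total cells: {bad}")
    fractions = counts.copy()
    fractions[cell_types] = mat / totals[:, None]
    group_cols = [c for c in group_cols if c in counts.columns]
    if group_cols:
        summary = fractions.groupby(group_cols, observed=True)[cell_types].agg(["mean", "std"])
    else:
        summary = fractions[cell_types].agg(["mean", "std"])
    return fractions, summary


def normalize_ratio(spd: float, spb: float, control_mean_ratio: float) -> float:
    """SP-D/SP-B densitometry ratio normalised to the control-group mean ratio."""
    if spb <= 0:
        raise ValueError(f"SP-B densitometry must be positive; got {spb}")
    if control_mean_ratio <= 0:
        raise ValueError(f"control mean ratio must be positive; got {control_mean_ratio}")
    return (spd / spb) / control_mean_ratio


def percent_open(trace: SurfTrace) -> float:
    """Percent of the 2-min recording during which the capillary was patent."""
    flags = np.asarray(trace.open_flag, dtype=float)
    return float(100.0 * flags.mean())
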