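"""Sensitivity analyses: leave-one-out, single-SNP scans, pleiotropy screen.

Leave-one-out repeats IVW, weighted-median, and MR-Egger estimation with each
instrument excluded in turn.  The pleiotropy screen applies a Bonferroni
threshold over a SNP x trait p-value matrix of confounder lookups.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .harmonize import HarmonizedInstrument
from .mr_estimators import MrEstimate, egger, ivw, wald_ratio, weighted_median

__all__ = [
    "LeaveOneOutRow",
    "PleiotropyScreen",
    "leave_one_out",
    "loo_to_frame",
    "single_snp_scan",
    "bonferroni_threshold",
    "screen_pleiotropy",
    "write_screen_report",
]


@dataclass
class LeaveOneOutRow:
    excluded_snp: str
    ivw_beta: float
    ivw_p: float
    wmr_beta: float
    wmr_p: float
    egger_beta: float
    egger_p: float
    intercept_beta: float
    intercept_p: float


def leave_one_out(
    instruments: Sequence[HarmonizedInstrument],
    variance_model: str = "default",
    n_boot: int = 1000,
    seed: int | None = None,
    wm_weighting: str = "simple",
    egger_use_t: bool = False,
) -> list[LeaveOneOutRow]:
    """Re-estimate with each instrument excluded in turn (input order).

    Requires at least four instruments so that every reduced set still
    supports MR-Egger.  Per-row bootstrap seeds are spawned deterministically
    from ``seed``, so the whole table is reproducible bit-for-bit.
    """
    if len(instruments) < 4:
        raise ValueError("leave-one-out requires at least 4 instruments")
    children = np.random.SeedSequence(seed).spawn(len(instruments))
    rows: list[LeaveOneOutRow] = []
    for j, excluded in enumerate(instruments):
        subset = [inst for k, inst in enumerate(instruments) if k != j]
        est_ivw, _ = ivw(subset, variance_model=variance_model)
        est_wmr = weighted_median(subset, n_boot=n_boot, seed=children[j], weighting=wm_weighting)
        slope, intercept, _ = egger(subset, use_t=egger_use_t)
        rows.append(
            LeaveOneOutRow(
                excluded_snp=excluded.snp_id,
                ivw_beta=est_ivw.beta,
                ivw_p=est_ivw.pvalue,
                wmr_beta=est_wmr.beta,
                wmr_p=est_wmr.pvalue,
                egger_beta=slope.beta,
                egger_p=slope.pvalue,
                intercept_beta=intercept.beta,
                intercept_p=intercept.pvalue,
            )
        )
    return rows


def loo_to_frame(rows: Sequence[LeaveOneOutRow]) -> pd.DataFrame:
    return pd.DataFrame([row.__dict__ for row in rows])


def single_snp_scan(instruments: Sequence[HarmonizedInstrument]) -> list[MrEstimate]:
    """One Wald-ratio estimate per instrument, in input order."""
    if len(instruments) < 1:
        raise ValueError("single-SNP scan requires at least 1 instrument")
    return [wald_ratio(inst) for inst in instruments]


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise p-value cutoff ``alpha / n_tests``."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha!r}")
    if not n_tests >= 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests!r}")
    return alpha / n_tests


@dataclass
class PleiotropyScreen:
    threshold: float
    matrix: pd.DataFrame
    flags: list[tuple[str, str, float]]

    @property
    def n_flags(self) -> int:
        return len(self.flags)


def screen_pleiotropy(
    matrix: pd.DataFrame,
    alpha: float = 0.05,
    n_instruments: int | None = None,
) -> PleiotropyScreen:
    """Flag (SNP, trait) pairs below the Bonferroni-corrected threshold.

    ``matrix`` holds association p-values with rsIDs as the index and traits
    as columns; absent (NaN) entries are never flagged.
    """
    if n_instruments is None:
        n_instruments = matrix.shape[0]
    threshold = bonferroni_threshold(alpha, n_instruments) if matrix.size else alpha
    flags: list[tuple[str, str, float]] = []
    for snp, row in matrix.iterrows():
        for trait, p in row.items():
            if pd.notna(p) and float(p) < threshold:
                flags.append((str(snp), str(trait), float(p)))
    return PleiotropyScreen(threshold=threshold, matrix=matrix, flags=flags)


def write_screen_report(screen: PleiotropyScreen, path) -> None:
    lines = ["snp\ttrait\tpvalue\tflagged"]
    flagged = {(s, t) for s, t, _ in screen.flags}
    for snp, row in screen.matrix.iterrows():
        for trait, p in row.items():
            if pd.isna(p):
                continue
            lines.append(f"{snp}\t{trait}\t{p:g}\t{(str(snp), str(trait)) in flagged}")
    Path(path).write_text("\n".join(lines) + "\n")
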