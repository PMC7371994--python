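"""Directionality assessment for instruments (Steiger-style filtering).

Per SNP, the variance explained in exposure and outcome is recovered from the
association p-value and the study sample size; a Z-test on the difference of
Fisher-transformed implied correlations decides whether the instrument acts
in the assumed exposure-to-outcome direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

from scipy import stats

from .harmonize import HarmonizedInstrument

__all__ = [
    "SteigerResult",
    "SteigerFilterResult",
    "r2_from_pn",
    "steiger_test",
    "steiger_filter",
    "effective_n",
    "write_steiger_log",
]


def effective_n(n_cases: int, n_controls: int) -> float:
    """Effective sample size of a case-control study, ``4/(1/cases + 1/controls)``.

    Provided as an option; the filter itself defaults to total n.
    """
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)


def r2_from_pn(pvalue: float, n: float) -> float:
    """Variance explained implied by an association p-value at sample size n.

    ``t2`` is the upper-tail chi-square(1) quantile at ``pvalue``;
    ``r2 = t2 / (t2 + n - 2)``.
    """
    if not 0 < pvalue <= 1:
        raise ValueError(f"pvalue must be in (0, 1], got {pvalue!r}")
    if not n > 2:
        raise ValueError(f"sample size must exceed 2, got {n!r}")
    t2 = float(stats.chi2.isf(pvalue, 1))
    return t2 / (t2 + n - 2.0)


def steiger_test(r2_exp: float, n_exp: float, r2_out: float, n_out: float) -> tuple[float, float]:
    """Z-test comparing variance explained in exposure vs outcome.

    Both r2 values are converted to correlations (positive root), Fisher
    z-transformed, and differenced with variance ``1/(n_exp-3) + 1/(n_out-3)``.
    Positive z supports the exposure-to-outcome direction.
    """
    for label, n in (("n_exp", n_exp), ("n_out", n_out)):
        if not n > 3:
            raise ValueError(f"{label} must exceed 3, got {n!r}")
    for label, r2 in (("r2_exp", r2_exp), ("r2_out", r2_out)):
        if not 0 <= r2 < 1:
            raise ValueError(f"{label} must be in [0, 1), got {r2!r}")
    z_exp = math.atanh(math.sqrt(r2_exp))
    z_out = math.atanh(math.sqrt(r2_out))
    z = (z_exp - z_out) / math.sqrt(1.0 / (n_exp - 3.0) + 1.0 / (n_out - 3.0))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return z, p


@dataclass
class SteigerResult:
    snp_id: str
    r2_exp: float
    r2_out: float
    z: float
    pvalue: float

    @property
    def correct_direction(self) -> bool:
        return self.r2_exp > self.r2_out


class SteigerFilterResult(NamedTuple):
    kept: list[HarmonizedInstrument]
    flagged: list[SteigerResult]
    log: list[SteigerResult]


def steiger_filter(
    instruments: Sequence[HarmonizedInstrument],
    n_exp: float,
    n_out: float,
) -> SteigerFilterResult:
    """Keep instruments explaining more variance in exposure than outcome.

    Requires per-SNP exposure/outcome p-values on each instrument.  Returns
    the kept instruments, the flagged (wrong-direction) results, and the full
    per-SNP log.
    """
    kept: list[HarmonizedInstrument] = []
    flagged: list[SteigerResult] = []
    log: list[SteigerResult] = []
    for inst in instruments:
        if inst.pval_exp is None or inst.pval_out is None:
            raise ValueError(f"{inst.snp_id}: exposure/outcome p-values required for Steiger filtering")
        r2_exp = r2_from_pn(inst.pval_exp, n_exp)
        r2_out = r2_from_pn(inst.pval_out, n_out)
        z, p = steiger_test(r2_exp, n_exp, r2_out, n_out)
        result = SteigerResult(inst.snp_id, r2_exp, r2_out, z, p)
        log.append(result)
        if result.correct_direction:
            kept.append(inst)
        else:
            flagged.append(result)
    return SteigerFilterResult(kept, flagged, log)


def write_steiger_log(log: Sequence[SteigerResult], path) -> None:
    lines = ["snp_id\tr2_exp\tr2_out\tz\tpvalue\tkept"]
    for res in log:
        lines.append(
            f"{res.snp_id}\t{res.r2_exp:.6g}\t{res.r2_out:.6g}\t"
            f"{res.z:.6g}\t{res.pvalue:.6g}\t{res.correct_direction}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
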