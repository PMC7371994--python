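"""Core two-sample MR estimators.

Implements per-SNP Wald ratios, the inverse-variance weighted (IVW) pooled
estimate under fixed and multiplicative random-effects variance models,
the weighted-median estimator with a seeded parametric-bootstrap standard
error, MR-Egger regression with its pleiotropy intercept, and Cochran's Q.

Variance-model conventions
--------------------------
``variance_model="default"`` resolves to fixed effects when fewer than four
instruments are available and to multiplicative random effects otherwise;
the random model multiplies the fixed-effects SE by ``max(1, sqrt(Q/df))``
(underdispersion floored at 1).  P-values are two-sided normal by default;
MR-Egger offers a t-distribution alternative (``use_t``) matching software
that reports t-based Egger p-values.

The weighted median supports two weighting conventions for the Wald ratios:
``"simple"`` inverse-variance weights ``(beta_exp/se_out)^2`` and ``"delta"``
weights from the full first-order delta-method ratio variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .harmonize import HarmonizedInstrument

__all__ = [
    "MrEstimate",
    "HeterogeneityResult",
    "EggerResult",
    "wald_ratio",
    "ivw",
    "weighted_median",
    "egger",
    "estimates_to_frame",
    "write_results",
]

_Z95 = 1.96


def _norm_p(beta: float, se: float) -> float:
    if se == 0:
        return 1.0 if beta == 0 else 0.0
    return float(2.0 * stats.norm.sf(abs(beta) / se))


@dataclass
class MrEstimate:
    """A causal estimate on the log-odds scale with its OR-scale summary."""

    method: str
    beta: float
    se: float
    pvalue: float
    n_snps: int
    variance_model: str = "fixed"
    scale_factor: float = 1.0

    @property
    def or_value(self) -> float:
        return math.exp(self.beta)

    @property
    def ci_lower(self) -> float:
        return math.exp(self.beta - _Z95 * self.se)

    @property
    def ci_upper(self) -> float:
        return math.exp(self.beta + _Z95 * self.se)


@dataclass
class HeterogeneityResult:
    """Cochran's Q with its degrees of freedom and upper-tail chi-square p."""

    q: float
    df: int
    pvalue: float


class EggerResult(NamedTuple):
    slope: MrEstimate
    intercept: MrEstimate
    heterogeneity: HeterogeneityResult


def _arrays(instruments: Sequence[HarmonizedInstrument]):
    bx = np.array([i.beta_exp for i in instruments], dtype=float)
    sx = np.array([i.se_exp for i in instruments], dtype=float)
    by = np.array([i.beta_out for i in instruments], dtype=float)
    sy = np.array([i.se_out for i in instruments], dtype=float)
    return bx, sx, by, sy


def wald_ratio(inst: HarmonizedInstrument) -> MrEstimate:
    """Single-SNP causal estimate ``beta_out / beta_exp``.

    The SE uses the first-order delta method, ``se_out / |beta_exp|``.
    """
    if inst.beta_exp == 0:
        raise ValueError(f"{inst.snp_id}: zero exposure effect")
    beta = inst.beta_out / inst.beta_exp
    se = inst.se_out / abs(inst.beta_exp)
    return MrEstimate("wald_ratio", beta, se, _norm_p(beta, se), n_snps=1)


def _resolve_model(variance_model: str, n: int) -> str:
    if variance_model == "default":
        return "fixed" if n < 4 else "random"
    if variance_model not in ("fixed", "random"):
        raise ValueError(f"unknown variance model {variance_model!r}")
    return variance_model


def ivw(
    instruments: Sequence[HarmonizedInstrument],
    variance_model: str = "default",
) -> tuple[MrEstimate, HeterogeneityResult]:
    """Inverse-variance weighted pooled estimate with Cochran's Q.

    Ratios ``theta_j = beta_out_j / beta_exp_j`` are pooled with weights
    ``w_j = (beta_exp_j / se_out_j)^2``; this is algebraically the
    zero-intercept weighted least-squares slope of ``beta_out`` on
    ``beta_exp`` with weights ``se_out^-2``.
    """
    if len(instruments) == 0:
        raise ValueError("ivw requires at least one instrument")
    bx, _, by, sy = _arrays(instruments)
    if np.any(bx == 0):
        raise ValueError("zero exposure effect among instruments")
    theta = by / bx
    w = (bx / sy) ** 2
    est = float(np.sum(w * theta) / np.sum(w))
    se_fixed = float(np.sum(w)) ** -0.5
    q = float(np.sum(w * (theta - est) ** 2))
    df = len(instruments) - 1
    q_p = float(stats.chi2.sf(q, df)) if df >= 1 else 1.0
    model = _resolve_model(variance_model, len(instruments))
    scale = max(1.0, math.sqrt(q / df)) if (model == "random" and df >= 1) else 1.0
    se = se_fixed * scale
    estimate = MrEstimate(
        "ivw", est, se, _norm_p(est, se),
        n_snps=len(instruments), variance_model=model, scale_factor=scale,
    )
    return estimate, HeterogeneityResult(q, df, q_p)


def _ratio_weights(bx, sx, by, sy, weighting: str):
    if weighting == "simple":
        return (bx / sy) ** 2
    if weighting == "delta":
        return 1.0 / (sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    raise ValueError(f"unknown weighting {weighting!r}")


def _percentile_weighted_median(theta: np.ndarray, w: np.ndarray, order=None) -> float:
    # Cumulative percentile of the j-th sorted ratio: (S_j - w_j/2) / S_J.
    if order is None:
        order = np.argsort(theta, kind="stable")
    theta, w = theta[order], w[order]
    w = w / np.sum(w)
    perc = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, perc, theta))


def weighted_median(
    instruments: Sequence[HarmonizedInstrument],
    n_boot: int = 1000,
    seed: int | None = None,
    weighting: str = "simple",
) -> MrEstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    The point estimate interpolates the sorted Wald ratios at the weighted
    50th percentile and is deterministic (ties in the ratio are broken by a
    stable sort on rsID).  The SE is the standard deviation of the estimate
    over ``n_boot`` resamples drawing both betas from normal distributions
    centred on their observed values, so it depends on ``seed``.
    """
    if len(instruments) < 3:
        raise ValueError("weighted median requires at least 3 instruments")
    bx, sx, by, sy = _arrays(instruments)
    if np.any(bx == 0):
        raise ValueError("zero exposure effect among instruments")
    theta = by / bx
    w = _ratio_weights(bx, sx, by, sy, weighting)
    snp_ids = [i.snp_id for i in instruments]
    order = np.array(sorted(range(len(theta)), key=lambda j: (theta[j], snp_ids[j])))
    est = _percentile_weighted_median(theta, w, order=order)

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    bxs = rng.normal(bx, sx, size=(n_boot, len(bx)))
    bys = rng.normal(by, sy, size=(n_boot, len(by)))
    for b in range(n_boot):
        tb = bys[b] / bxs[b]
        wb = _ratio_weights(bxs[b], sx, bys[b], sy, weighting)
        boot[b] = _percentile_weighted_median(tb, wb)
    se = float(np.std(boot, ddof=1))
    return MrEstimate(
        "weighted_median", est, se, _norm_p(est, se),
        n_snps=len(instruments), variance_model="default",
    )


def egger(
    instruments: Sequence[HarmonizedInstrument],
    use_t: bool = False,
) -> EggerResult:
    """MR-Egger: weighted regression of outcome on exposure betas with intercept.

    Instruments are first reoriented so every exposure beta is non-negative
    (Egger is not orientation-invariant).  Coefficient SEs carry the
    multiplicative residual-heterogeneity scale ``max(1, sqrt(Q'/(J-2)))``.
    ``use_t`` switches the coefficient p-values from the normal to a
    t-distribution on ``J - 2`` degrees of freedom.
    """
    if len(instruments) < 3:
        raise ValueError("MR-Egger requires at least 3 instruments")
    bx, _, by, sy = _arrays(instruments)
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    if np.allclose(bx, bx[0]):
        raise ValueError("exposure betas are all equal: Egger design matrix is rank-deficient")
    w = 1.0 / sy**2
    X = np.column_stack([np.ones_like(bx), bx])
    xtwx = X.T @ (X * w[:, None])
    coef = np.linalg.solve(xtwx, (X * w[:, None]).T @ by)
    resid = by - X @ coef
    df = len(instruments) - 2
    q = float(np.sum(w * resid**2))
    scale = max(1.0, math.sqrt(q / df))
    se = np.sqrt(np.diag(np.linalg.inv(xtwx))) * scale
    if use_t:
        pvals = [float(2.0 * stats.t.sf(abs(c) / s, df)) for c, s in zip(coef, se)]
    else:
        pvals = [_norm_p(c, s) for c, s in zip(coef, se)]
    intercept = MrEstimate(
        "egger_intercept", float(coef[0]), float(se[0]), pvals[0],
        n_snps=len(instruments), variance_model="random", scale_factor=scale,
    )
    slope = MrEstimate(
        "egger_slope", float(coef[1]), float(se[1]), pvals[1],
        n_snps=len(instruments), variance_model="random", scale_factor=scale,
    )
    het = HeterogeneityResult(q, df, float(stats.chi2.sf(q, df)))
    return EggerResult(slope, intercept, het)


def estimates_to_frame(
    estimates: Iterable[MrEstimate],
    analysis: str = "",
    heterogeneity: HeterogeneityResult | None = None,
) -> pd.DataFrame:
    """Tidy results table: one row per estimate, OR scale included."""
    rows = []
    for est in estimates:
        rows.append(
            {
                "analysis": analysis,
                "method": est.method,
                "n_snps": est.n_snps,
                "beta": est.beta,
                "se": est.se,
                "pvalue": est.pvalue,
                "or": est.or_value,
                "ci_lower": est.ci_lower,
                "ci_upper": est.ci_upper,
                "q": heterogeneity.q if heterogeneity else None,
                "q_df": heterogeneity.df if heterogeneity else None,
                "q_pvalue": heterogeneity.pvalue if heterogeneity else None,
            }
        )
    return pd.DataFrame(rows)


def write_results(frame: pd.DataFrame, path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        frame.to_json(path, orient="records", indent=2)
    else:
        frame.to_csv(path, sep="\t", index=False)
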