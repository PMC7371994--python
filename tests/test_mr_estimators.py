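import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tsmr.harmonize import HarmonizedInstrument
from tsmr.mr_estimators import (
    egger,
    estimates_to_frame,
    ivw,
    wald_ratio,
    weighted_median,
)


def inst(snp_id="rs1", bx=0.05, sx=0.01, by=0.01, sy=0.02):
    return HarmonizedInstrument(snp_id=snp_id, beta_exp=bx, se_exp=sx, beta_out=by, se_out=sy)


@st.composite
def instrument_lists(draw, min_size=3, max_size=6):
    n = draw(st.integers(min_size, max_size))
    items = []
    for j in range(n):
        bx = draw(st.floats(0.02, 1.0))
        sign = draw(st.sampled_from([-1.0, 1.0]))
        items.append(
            inst(
                snp_id=f"rs{j}",
                bx=sign * bx,
                sx=draw(st.floats(0.001, 0.1)),
                by=draw(st.floats(-0.5, 0.5)),
                sy=draw(st.floats(0.001, 0.1)),
            )
        )
    return items


def _oracle_ivw(instruments):
    # Explicit zero-intercept normal equations: slope = sum(w x y) / sum(w x^2).
    sw_xy = sum(i.beta_exp * i.beta_out / i.se_out**2 for i in instruments)
    sw_xx = sum(i.beta_exp**2 / i.se_out**2 for i in instruments)
    return sw_xy / sw_xx


def _oracle_egger(instruments):
    # 2x2 normal equations assembled from explicit sums.
    sw = sum(1 / i.se_out**2 for i in instruments)
    swx = sum(abs(i.beta_exp) / i.se_out**2 for i in instruments)
    swxx = sum(i.beta_exp**2 / i.se_out**2 for i in instruments)
    sgn = [1.0 if i.beta_exp >= 0 else -1.0 for i in instruments]
    swy = sum(s * i.beta_out / i.se_out**2 for s, i in zip(sgn, instruments))
    swxy = sum(abs(i.beta_exp) * s * i.beta_out / i.se_out**2 for s, i in zip(sgn, instruments))
    det = sw * swxx - swx**2
    intercept = (swxx * swy - swx * swxy) / det
    slope = (sw * swxy - swx * swy) / det
    return slope, intercept


class TestWaldRatio:
    def test_las_single_snp(self, las_instruments):
        rs10820405 = {i.snp_id: i for i in las_instruments}["rs10820405"]
        est = wald_ratio(rs10820405)
        assert round(est.beta, 3) == -0.047
        assert round(est.pvalue, 3) == 0.664

    def test_zero_outcome_effect(self):
        est = wald_ratio(inst(by=0.0))
        assert est.beta == 0.0
        assert est.pvalue == 1.0

    def test_delta_method_formula(self):
        est = wald_ratio(inst(bx=0.5, by=0.1, sy=0.05))
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.1)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(inst(bx=0.0))


class TestIvw:
    def test_as_published_values(self, as_instruments):
        est, het = ivw(as_instruments)
        assert round(est.beta, 3) == -0.039
        assert round(est.pvalue, 3) == 0.750
        assert round(het.q, 4) == 15.8637
        assert het.df == 10
        assert round(het.pvalue, 4) == 0.1036
        assert est.variance_model == "random"

    def test_las_fixed_effects_below_four(self, las_instruments):
        est, _ = ivw(las_instruments)
        assert est.variance_model == "fixed"
        assert round(est.beta, 3) == 0.037
        assert round(est.pvalue, 3) == 0.568

    def test_single_instrument_reduces_to_wald(self):
        one = inst(bx=0.1823, sx=0.0341, by=-0.0086, sy=0.0198)
        est, het = ivw([one])
        wald = wald_ratio(one)
        assert est.beta == pytest.approx(wald.beta, abs=1e-15)
        assert est.se == pytest.approx(wald.se, abs=1e-15)
        assert het.q == pytest.approx(0.0, abs=1e-25)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ivw([])

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(ValueError):
            ivw([inst(), inst(snp_id="rs2", bx=0.0)])

    def test_orientation_invariance_exact(self, as_instruments):
        est, het = ivw(as_instruments)
        flipped = list(as_instruments)
        orig = flipped[3]
        flipped[3] = HarmonizedInstrument(
            snp_id=orig.snp_id, beta_exp=-orig.beta_exp, se_exp=orig.se_exp,
            beta_out=-orig.beta_out, se_out=orig.se_out,
        )
        est2, het2 = ivw(flipped)
        assert est2.beta == est.beta
        assert het2.q == het.q

    def test_q_scale_free_exact(self, as_instruments):
        # Doubling every outcome SE divides Q by exactly 4 (power-of-two scale).
        _, het = ivw(as_instruments)
        scaled = [
            HarmonizedInstrument(
                snp_id=i.snp_id, beta_exp=i.beta_exp, se_exp=i.se_exp,
                beta_out=i.beta_out, se_out=2.0 * i.se_out,
            )
            for i in as_instruments
        ]
        _, het_scaled = ivw(scaled)
        assert het_scaled.q == het.q / 4.0

    def test_q_zero_iff_ratios_equal(self):
        same = [inst(snp_id=f"rs{j}", bx=0.1 * (j + 1), by=0.02 * (j + 1)) for j in range(4)]
        _, het = ivw(same)
        assert het.q == pytest.approx(0.0, abs=1e-25)

    def test_random_se_at_least_fixed(self, as_instruments, ais_instruments):
        for instruments in (as_instruments, ais_instruments):
            fixed, het = ivw(instruments, variance_model="fixed")
            rand, _ = ivw(instruments, variance_model="random")
            assert rand.se >= fixed.se
            if het.q <= het.df:
                assert rand.se == fixed.se
            else:
                assert rand.se > fixed.se

    @settings(max_examples=50, deadline=None)
    @given(instrument_lists())
    def test_oracle_equivalence(self, instruments):
        est, _ = ivw(instruments, variance_model="fixed")
        assert est.beta == pytest.approx(_oracle_ivw(instruments), rel=1e-10, abs=1e-10)

    def test_or_and_ci_consistency(self, as_instruments):
        est, _ = ivw(as_instruments)
        assert est.or_value == pytest.approx(math.exp(est.beta), abs=1e-12)
        assert est.ci_lower < est.or_value < est.ci_upper


class TestWeightedMedian:
    def test_as_point_estimate(self, as_instruments):
        est = weighted_median(as_instruments, n_boot=10, seed=0)
        assert round(est.beta, 3) == -0.156

    def test_equal_weights_hit_middle_ratio(self):
        instruments = [
            inst(snp_id="rs1", bx=0.1, by=0.1, sy=0.1),
            inst(snp_id="rs2", bx=0.1, by=0.2, sy=0.1),
            inst(snp_id="rs3", bx=0.1, by=1.0, sy=0.1),
        ]
        est = weighted_median(instruments, n_boot=10, seed=0)
        assert est.beta == pytest.approx(2.0)

    def test_degenerate_identical_ratios(self):
        c = 0.3
        instruments = [
            inst(snp_id=f"rs{j}", bx=0.1, sx=1e-7, by=c * 0.1, sy=1e-7) for j in range(3)
        ]
        est = weighted_median(instruments, n_boot=100, seed=0)
        assert est.beta == pytest.approx(c)
        assert est.se < 1e-4

    def test_too_few_instruments(self):
        with pytest.raises(ValueError):
            weighted_median([inst(), inst(snp_id="rs2")], n_boot=10, seed=0)

    def test_bootstrap_p_tolerance(self, as_instruments):
        for seed in (0, 1, 2):
            est = weighted_median(as_instruments, n_boot=1000, seed=seed)
            assert abs(est.pvalue - 0.274) <= 0.1

    def test_seed_reproducibility(self, as_instruments):
        a = weighted_median(as_instruments, n_boot=200, seed=7)
        b = weighted_median(as_instruments, n_boot=200, seed=7)
        assert a.se == b.se and a.pvalue == b.pvalue

    @settings(max_examples=50, deadline=None)
    @given(instrument_lists())
    def test_bracketing(self, instruments):
        est = weighted_median(instruments, n_boot=2, seed=0)
        ratios = [i.beta_out / i.beta_exp for i in instruments]
        assert min(ratios) - 1e-12 <= est.beta <= max(ratios) + 1e-12

    def test_delta_weighting_option(self, as_steiger_instruments):
        est = weighted_median(as_steiger_instruments, n_boot=10, seed=0, weighting="delta")
        assert round(est.beta, 3) == -0.129


class TestEgger:
    def test_as_published_values(self, as_instruments):
        slope, intercept, het = egger(as_instruments)
        assert round(slope.beta, 3) == -1.312
        assert round(slope.pvalue, 3) == 0.098
        assert round(intercept.beta, 3) == 0.071
        assert round(intercept.pvalue, 3) == 0.105
        assert het.df == 9

    def test_ces_published_values(self, ces_instruments):
        slope, intercept, _ = egger(ces_instruments)
        assert round(slope.beta, 3) == -0.062
        assert round(intercept.beta, 3) == -0.001

    def test_exact_line_recovered(self):
        a, b = 0.01, 0.4
        instruments = [
            inst(snp_id=f"rs{j}", bx=x, by=a + b * x, sy=0.01 * (j + 1))
            for j, x in enumerate([0.05, 0.1, 0.2, 0.4])
        ]
        slope, intercept, het = egger(instruments)
        assert slope.beta == pytest.approx(b, abs=1e-12)
        assert intercept.beta == pytest.approx(a, abs=1e-12)
        assert het.q == pytest.approx(0.0, abs=1e-20)

    def test_too_few_instruments(self):
        with pytest.raises(ValueError):
            egger([inst(), inst(snp_id="rs2")])

    def test_rank_deficiency_rejected(self):
        instruments = [inst(snp_id=f"rs{j}", bx=0.1) for j in range(4)]
        with pytest.raises(ValueError):
            egger(instruments)

    def test_t_option_changes_p_only(self, ces_instruments):
        slope_n, _, _ = egger(ces_instruments, use_t=False)
        slope_t, _, _ = egger(ces_instruments, use_t=True)
        assert slope_t.beta == slope_n.beta
        assert slope_t.se == slope_n.se
        assert slope_t.pvalue > slope_n.pvalue  # heavier tails at df=1

    @settings(max_examples=50, deadline=None)
    @given(instrument_lists(min_size=4))
    def test_oracle_equivalence(self, instruments):
        # after orientation Egger regresses on |beta_exp|; require conditioning
        bx = np.abs([i.beta_exp for i in instruments])
        if bx.max() - bx.min() <= 0.05 * bx.max():
            return
        slope, intercept, _ = egger(instruments)
        oracle_slope, oracle_intercept = _oracle_egger(instruments)
        assert slope.beta == pytest.approx(oracle_slope, rel=1e-10, abs=1e-10)
        assert intercept.beta == pytest.approx(oracle_intercept, rel=1e-10, abs=1e-10)


def test_estimates_to_frame_layout(as_instruments):
    est, het = ivw(as_instruments)
    frame = estimates_to_frame([est], analysis="AS", heterogeneity=het)
    assert list(frame.columns) == [
        "analysis", "method", "n_snps", "beta", "se", "pvalue",
        "or", "ci_lower", "ci_upper", "q", "q_df", "q_pvalue",
    ]
    assert frame.loc[0, "method"] == "ivw"
    assert frame.loc[0, "n_snps"] == 11
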