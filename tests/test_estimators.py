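"""Wald ratio, IVW, MR-Egger, weighted median, Cochran's Q."""

import dataclasses

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

from hcymr.estimators import (cochran_q, egger, first_order_weights, ivw,
                              wald_ratio, wald_ratios, weighted_median)

from conftest import make_set


def instrument_arrays(min_j=3, max_j=12):
    """Strategy: (bx, by, sy) arrays for a random instrument set."""
    j = st.integers(min_j, max_j)
    return j.flatmap(lambda n: st.tuples(
        st.lists(st.floats(0.02, 0.3).map(float), min_size=n, max_size=n),
        st.lists(st.booleans(), min_size=n, max_size=n),
        st.lists(st.floats(-0.15, 0.15), min_size=n, max_size=n),
        st.lists(st.floats(0.01, 0.08), min_size=n, max_size=n),
    )).map(lambda t: (np.array(t[0]) * np.where(t[1], 1.0, -1.0),
                      np.array(t[2]), np.array(t[3])))


class TestWaldRatio:
    def test_strongest_instrument_against_finngen(self, finngen_set):
        inst = next(i for i in finngen_set if i.variant_id == "rs1801133")
        est = wald_ratio(inst)
        assert est.estimate == pytest.approx(0.7556, abs=1e-4)
        assert est.se == pytest.approx(0.3386, abs=1e-4)

    def test_null_outcome_effect_gives_zero(self):
        iset = make_set([0.2], [0.0], [0.05])
        assert wald_ratio(iset.instruments[0]).estimate == 0.0

    def test_scale_invariance(self):
        a = make_set([0.1], [0.05], [0.02]).instruments[0]
        b = make_set([0.2], [0.10], [0.02]).instruments[0]
        assert wald_ratio(a).estimate == pytest.approx(wald_ratio(b).estimate)

    def test_second_order_se_exceeds_first_order(self):
        inst = make_set([0.1], [0.05], [0.02], sx=[0.02]).instruments[0]
        assert wald_ratio(inst, second_order=True).se > wald_ratio(inst).se

    def test_zero_exposure_beta_raises(self):
        inst = make_set([0.0], [0.05], [0.02]).instruments[0]
        with pytest.raises(ZeroDivisionError):
            wald_ratio(inst)


class TestIVW:
    def test_single_instrument_equals_wald_ratio(self):
        iset = make_set([0.12], [0.05], [0.03])
        est = ivw(iset)
        wald = wald_ratio(iset.instruments[0])
        assert est.estimate == pytest.approx(wald.estimate)
        assert est.se == pytest.approx(wald.se)

    def test_two_equal_weight_instruments_average_the_ratios(self):
        # same |bx| and sy -> equal weights, so IVW = mean of the two ratios
        iset = make_set([0.1, 0.1], [0.02, 0.06], [0.03, 0.03])
        assert ivw(iset, model="fixed").estimate == pytest.approx(
            (0.2 + 0.6) / 2)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(instrument_arrays())
    def test_fixed_equals_weighted_mean_of_wald_ratios(self, arrays):
        bx, by, sy = arrays
        iset = make_set(bx, by, sy)
        ratios = wald_ratios(iset)
        w = first_order_weights(iset)
        assert ivw(iset, model="fixed").estimate == pytest.approx(
            float(np.sum(w * ratios) / np.sum(w)), rel=1e-9)

    def test_auto_selects_random_effects_at_four_instruments(self):
        small = make_set([0.1, 0.2, 0.15], [0.05, 0.1, 0.02], [0.03] * 3)
        large = make_set([0.1, 0.2, 0.15, 0.12], [0.05, 0.1, 0.02, 0.0],
                         [0.03] * 4)
        assert ivw(small).method == "ivw_fe"
        assert ivw(large).method == "ivw_mre"

    def test_random_effects_se_never_below_fixed(self):
        iset = make_set([0.1, 0.2, 0.15, 0.12], [0.05, 0.1, 0.02, 0.0],
                        [0.03] * 4)
        assert ivw(iset, model="multiplicative_random").se >= \
            ivw(iset, model="fixed").se

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(instrument_arrays())
    def test_allele_and_outcome_recoding_symmetries(self, arrays):
        # joint (bx, by) flip re-codes effect alleles: Wald ratios unchanged;
        # flipping the outcome trait coding (by only) negates the estimate
        bx, by, sy = arrays
        a = ivw(make_set(bx, by, sy))
        joint = ivw(make_set(-bx, -by, sy))
        outcome_flip = ivw(make_set(bx, -by, sy))
        assert joint.estimate == pytest.approx(a.estimate, rel=1e-9, abs=1e-15)
        assert outcome_flip.estimate == pytest.approx(-a.estimate,
                                                      rel=1e-9, abs=1e-15)
        assert outcome_flip.se == pytest.approx(a.se, rel=1e-9)

    def test_empty_set_impossible(self):
        from hcymr.data_model import HarmonizationError, InstrumentSet
        with pytest.raises(HarmonizationError):
            InstrumentSet(label="x", instruments=())


class TestEgger:
    def test_exact_linear_relationship_recovered(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2])
        by = 0.7 * bx + 0.02
        res = egger(make_set(bx, by, [0.03] * 4))
        assert res.slope.estimate == pytest.approx(0.7, abs=1e-10)
        assert res.intercept.estimate == pytest.approx(0.02, abs=1e-10)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(instrument_arrays())
    def test_matches_generic_weighted_least_squares(self, arrays):
        import statsmodels.api as sm
        bx, by, sy = arrays
        assume(float(np.ptp(np.abs(bx))) > 1e-6)
        res = egger(make_set(bx, by, sy))
        sign = np.where(bx < 0, -1.0, 1.0)
        fit = sm.WLS(by * sign, sm.add_constant(bx * sign),
                     weights=1.0 / sy ** 2).fit()
        assert res.intercept.estimate == pytest.approx(fit.params[0], abs=1e-8)
        assert res.slope.estimate == pytest.approx(fit.params[1], abs=1e-8)
        # same covariance up to the no-deflation rule for underdispersion
        assume(fit.scale > 1e-10)  # exact fits make the WLS scale collapse
        inflate = 1.0 if fit.scale >= 1.0 else 1.0 / np.sqrt(fit.scale)
        assert res.slope.se == pytest.approx(fit.bse[1] * inflate, rel=1e-6)

    def test_intercept_constrained_to_zero_reproduces_fixed_ivw(self, day_set):
        # weighted through-origin regression is algebraically the FE IVW slope
        bx, by = day_set.beta_exposure, day_set.beta_outcome
        w = 1.0 / day_set.se_outcome ** 2
        origin_slope = float(np.sum(w * bx * by) / np.sum(w * bx * bx))
        assert origin_slope == pytest.approx(ivw(day_set, model="fixed").estimate,
                                             rel=1e-12)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(instrument_arrays())
    def test_recoding_symmetries(self, arrays):
        # the non-negative orientation makes a joint flip a no-op, while an
        # outcome-coding flip negates both slope and intercept, SEs unchanged
        bx, by, sy = arrays
        assume(float(np.ptp(np.abs(bx))) > 1e-6)
        a = egger(make_set(bx, by, sy))
        joint = egger(make_set(-bx, -by, sy))
        outcome_flip = egger(make_set(bx, -by, sy))
        assert joint.slope.estimate == pytest.approx(a.slope.estimate,
                                                     rel=1e-9, abs=1e-15)
        assert joint.intercept.estimate == pytest.approx(
            a.intercept.estimate, rel=1e-9, abs=1e-15)
        assert outcome_flip.slope.estimate == pytest.approx(
            -a.slope.estimate, rel=1e-9, abs=1e-15)
        assert outcome_flip.intercept.estimate == pytest.approx(
            -a.intercept.estimate, rel=1e-9, abs=1e-15)
        assert outcome_flip.slope.se == pytest.approx(a.slope.se, rel=1e-9)

    def test_t_reference_widens_interval(self, day_set):
        n = egger(day_set, p_reference="normal")
        t = egger(day_set, p_reference="t")
        assert t.slope.ci_high - t.slope.ci_low > n.slope.ci_high - n.slope.ci_low

    def test_too_few_or_degenerate(self):
        with pytest.raises(ValueError, match=">= 3"):
            egger(make_set([0.1, 0.2], [0.1, 0.1], [0.03, 0.03]))
        with pytest.raises(ValueError, match="degenerate"):
            egger(make_set([0.1, 0.1, 0.1], [0.1, 0.2, 0.1], [0.03] * 3))


def brute_force_weighted_median(theta, w):
    """Independent oracle: walk the sorted cumulative-weight step function
    and linearly interpolate the 50% crossing."""
    order = np.argsort(theta)
    theta, w = np.asarray(theta)[order], np.asarray(w)[order]
    total = w.sum()
    s = []
    cum = 0.0
    for wi in w:
        s.append((cum + wi / 2) / total)
        cum += wi
    s = np.array(s)
    if 0.5 <= s[0]:
        return theta[0]
    if 0.5 >= s[-1]:
        return theta[-1]
    k = int(np.searchsorted(s, 0.5)) - 1
    frac = (0.5 - s[k]) / (s[k + 1] - s[k])
    return theta[k] + frac * (theta[k + 1] - theta[k])


class TestWeightedMedian:
    def test_equal_weights_odd_count_is_middle_order_statistic(self):
        iset = make_set([0.1, 0.1, 0.1], [0.03, 0.01, 0.05], [0.02] * 3)
        est = weighted_median(iset, n_boot=200, seed=1)
        assert est.estimate == pytest.approx(0.3)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(instrument_arrays(min_j=7, max_j=7))
    def test_agrees_with_step_function_oracle(self, arrays):
        bx, by, sy = arrays
        iset = make_set(bx, by, sy)
        est = weighted_median(iset, n_boot=50, seed=1)
        expected = brute_force_weighted_median(wald_ratios(iset),
                                               first_order_weights(iset))
        assert est.estimate == pytest.approx(expected, rel=1e-9, abs=1e-12)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(instrument_arrays())
    def test_lies_between_extreme_ratios_and_ignores_order(self, arrays):
        bx, by, sy = arrays
        iset = make_set(bx, by, sy)
        est = weighted_median(iset, n_boot=50, seed=1)
        ratios = wald_ratios(iset)
        assert ratios.min() - 1e-12 <= est.estimate <= ratios.max() + 1e-12
        perm = np.random.default_rng(0).permutation(len(bx))
        shuffled = weighted_median(make_set(bx[perm], by[perm], sy[perm]),
                                   n_boot=50, seed=1)
        assert shuffled.estimate == pytest.approx(est.estimate, rel=1e-12)

    def test_bootstrap_se_reproducible_and_seed_sensitive(self, tyrmi_set):
        a = weighted_median(tyrmi_set, n_boot=500, seed=7)
        b = weighted_median(tyrmi_set, n_boot=500, seed=7)
        c = weighted_median(tyrmi_set, n_boot=500, seed=8)
        assert a.se == b.se
        assert a.se != c.se
        assert a.estimate == c.estimate  # point estimate is not resampled

    def test_invalid_boot_count(self, tyrmi_set):
        with pytest.raises(ValueError, match="n_boot"):
            weighted_median(tyrmi_set, n_boot=0)


class TestCochranQ:
    def test_identical_ratios_give_zero_q(self):
        bx = np.array([0.1, 0.2, 0.05])
        iset = make_set(bx, 0.4 * bx, [0.03] * 3)
        het = cochran_q(iset)
        assert het.q_statistic == pytest.approx(0.0, abs=1e-20)
        assert het.p_value == pytest.approx(1.0)
        assert het.i_squared == 0.0

    def test_term_by_term_summation_oracle(self, day_set):
        het = cochran_q(day_set)
        ratios = wald_ratios(day_set)
        w = first_order_weights(day_set)
        theta = float(np.sum(w * ratios) / np.sum(w))
        q = sum(wi * (ti - theta) ** 2 for wi, ti in zip(w, ratios))
        assert het.q_statistic == pytest.approx(q, rel=1e-12)
        assert het.df == 13

    def test_duplicated_instrument_never_decreases_q(self, day_set):
        het = cochran_q(day_set)
        dup = dataclasses.replace(day_set.instruments[0], variant_id="dup")
        bigger = dataclasses.replace(
            day_set, instruments=day_set.instruments + (dup,))
        assert cochran_q(bigger).q_statistic >= het.q_statistic - 1e-12
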