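"""Estimator battery: Wald, IVW, Egger, median, mode, Q, reporting helpers."""
import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from duomr.mr import (
    MRModel,
    ci_and_p,
    cochran_q,
    egger,
    ivw,
    leave_one_out,
    mode_estimate,
    sd_to_grams,
    wald_ratio,
    weighted_median,
)
from duomr.simulate import simulate_summary_instruments

from conftest import make_instrument, make_instruments


class TestWaldRatio:
    def test_hand_arithmetic(self):
        r = wald_ratio(make_instrument("rs1", 0.4, 0.02, 0.2, 0.05))
        assert r.estimate == pytest.approx(0.5)
        assert r.se == pytest.approx(0.125)

    def test_null_and_identity(self):
        assert wald_ratio(make_instrument("rs1", 0.1, 0.01, 0.0, 0.05)).estimate == 0.0
        assert wald_ratio(make_instrument("rs1", 0.1, 0.01, 0.1, 0.05)).estimate == pytest.approx(1.0)

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(ValueError, match="zero exposure"):
            wald_ratio(make_instrument("rs1", 0.0, 0.01, 0.1, 0.05))


class TestIvw:
    def test_single_instrument_equals_wald(self):
        inst = make_instrument("rs1", 0.4, 0.02, 0.2, 0.05)
        with pytest.warns(UserWarning, match="single instrument"):
            res, het = ivw([inst])
        w = wald_ratio(inst)
        assert (res.estimate, res.se, res.pvalue) == (w.estimate, w.se, w.pvalue)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_slope_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 12)
        bx = rng.uniform(-0.3, 0.3, n)
        bx[np.abs(bx) < 1e-3] = 0.05
        sy = rng.uniform(0.005, 0.05, n)
        by = 0.2 * bx + rng.normal(0, sy)
        inst = make_instruments(bx, np.full(n, 0.01), by, sy)
        res, _ = ivw(inst)
        w = 1 / sy**2
        oracle = np.sum(w * bx * by) / np.sum(w * bx**2)
        assert res.estimate == pytest.approx(oracle, abs=1e-10)

    def test_se_never_below_fixed_effect(self, random_instruments):
        for seed in range(5):
            inst = random_instruments(seed)
            res, _ = ivw(inst)
            sy = np.array([i.se_outcome for i in inst])
            bx = np.array([i.beta_exposure for i in inst])
            se_fixed = math.sqrt(1 / np.sum(bx**2 / sy**2))
            assert res.se >= se_fixed - 1e-15

    def test_outcome_scale_equivariance(self, random_instruments):
        inst = random_instruments(3)
        c = 2.5
        scaled = [
            make_instrument(i.rsid, i.beta_exposure, i.se_exposure, c * i.beta_outcome, c * i.se_outcome)
            for i in inst
        ]
        r1, _ = ivw(inst)
        r2, _ = ivw(scaled)
        assert r2.estimate == pytest.approx(c * r1.estimate, rel=1e-12)
        assert r2.se == pytest.approx(c * r1.se, rel=1e-12)

    def test_exposure_unit_equivariance(self, random_instruments):
        inst = random_instruments(4)
        c = 3.0
        scaled = [
            make_instrument(i.rsid, c * i.beta_exposure, c * i.se_exposure, i.beta_outcome, i.se_outcome)
            for i in inst
        ]
        r1, _ = ivw(inst)
        r2, _ = ivw(scaled)
        assert r2.estimate == pytest.approx(r1.estimate / c, rel=1e-12)

    def test_coverage_under_valid_instruments(self):
        """95% CI covers the true effect ~95% of the time (1000 reps)."""
        theta = 0.15
        hits = 0
        reps = 1000
        for seed in range(reps):
            inst = simulate_summary_instruments(8, theta, seed=seed)
            res, _ = ivw(inst)
            hits += res.ci_low <= theta <= res.ci_high
        # binomial 3-sigma band around 0.95; random-effects floor makes
        # coverage conservative, so allow up-side slack
        assert 0.95 - 3 * math.sqrt(0.95 * 0.05 / reps) <= hits / reps <= 1.0


class TestEgger:
    def test_requires_three_instruments(self):
        inst = make_instruments([0.1, 0.2], [0.01, 0.01], [0.01, 0.02], [0.01, 0.01])
        with pytest.raises(ValueError, match="at least 3"):
            egger(inst)

    def test_exact_fit_recovers_slope_and_intercept(self):
        # by = delta + theta*bx exactly: perfect weighted fit, zero residual Q
        bx = np.array([0.1, 0.2, 0.3, 0.15])
        delta, theta = 0.01, 0.4
        inst = make_instruments(bx, np.full(4, 0.01), delta + theta * bx, np.full(4, 0.02))
        slope, intercept, het = egger(inst)
        assert slope.estimate == pytest.approx(theta, abs=1e-12)
        assert intercept.estimate == pytest.approx(delta, abs=1e-12)
        assert het.q == pytest.approx(0.0, abs=1e-18)

    def test_orientation_invariance(self):
        """Flipping an instrument's alleles (bx, by jointly negated) changes nothing."""
        inst = simulate_summary_instruments(6, 0.2, seed=5)
        flipped = [
            make_instrument(i.rsid, -i.beta_exposure, i.se_exposure, -i.beta_outcome, i.se_outcome)
            for i in inst
        ]
        s1, i1, _ = egger(inst)
        s2, i2, _ = egger(flipped)
        assert s2.estimate == pytest.approx(s1.estimate, rel=1e-12)
        assert i2.estimate == pytest.approx(i1.estimate, rel=1e-12)

    def test_directional_pleiotropy_recovered(self):
        """Mean Egger intercept over replicates recovers the injected offset,
        and the slope stays unbiased, while IVW absorbs the pleiotropy."""
        delta, theta, reps = 0.02, 0.1, 200
        intercepts, slopes, ivws = [], [], []
        for seed in range(reps):
            inst = simulate_summary_instruments(
                12, theta, seed=10_000 + seed, pleiotropy_mean=delta, pleiotropy_sd=0.002
            )
            s, i, _ = egger(inst)
            r, _ = ivw(inst)
            intercepts.append(i.estimate)
            slopes.append(s.estimate)
            ivws.append(r.estimate)
        mc_se = np.std(intercepts, ddof=1) / math.sqrt(reps)
        assert np.mean(intercepts) == pytest.approx(delta, abs=3 * mc_se)
        slope_se = np.std(slopes, ddof=1) / math.sqrt(reps)
        assert np.mean(slopes) == pytest.approx(theta, abs=3 * slope_se)
        assert abs(np.mean(ivws) - theta) > abs(np.mean(slopes) - theta)

    def test_balanced_pleiotropy_intercept_centred_on_zero(self):
        reps = 200
        intercepts = []
        for seed in range(reps):
            inst = simulate_summary_instruments(
                12, 0.1, seed=20_000 + seed, pleiotropy_mean=0.0, pleiotropy_sd=0.01
            )
            _, i, _ = egger(inst)
            intercepts.append(i.estimate)
        mc_se = np.std(intercepts, ddof=1) / math.sqrt(reps)
        assert abs(np.mean(intercepts)) < 3 * mc_se


class TestWeightedMedian:
    def test_middle_order_statistic(self):
        inst = make_instruments([1, 1, 1], [0.01] * 3, [0.0, 1.0, 2.0], [1.0] * 3)
        res = weighted_median(inst, seed=1)
        assert res.estimate == pytest.approx(1.0)

    def test_identical_ratios_degenerate(self):
        inst = make_instruments([0.1, 0.2, 0.3], [0.001] * 3, [0.05, 0.10, 0.15], [0.001] * 3)
        res = weighted_median(inst, seed=2)
        assert res.estimate == pytest.approx(0.5, abs=1e-9)
        assert res.se < 0.05

    def test_guards(self):
        inst = make_instruments([0.1, 0.2], [0.01] * 2, [0.01, 0.02], [0.01] * 2)
        with pytest.raises(ValueError, match="at least 3"):
            weighted_median(inst, seed=1)
        three = make_instruments([0.1, 0.2, 0.3], [0.01] * 3, [0.01, 0.02, 0.03], [0.01] * 3)
        with pytest.raises(ValueError, match="seed"):
            weighted_median(three)
        with pytest.warns(UserWarning, match="n_boot"):
            weighted_median(three, n_boot=50, seed=1)

    def test_bootstrap_reproducible(self):
        inst = simulate_summary_instruments(6, 0.2, seed=3)
        a = weighted_median(inst, seed=42)
        b = weighted_median(inst, seed=42)
        assert a == b


class TestMode:
    def test_point_mass(self):
        inst = make_instruments([0.1, 0.2, 0.4], [0.001] * 3, [0.07, 0.14, 0.28], [0.001] * 3)
        for weighted in (False, True):
            res = mode_estimate(inst, weighted=weighted, seed=1)
            assert res.estimate == pytest.approx(0.7, abs=1e-6)

    def test_consensus_cluster_beats_ivw_against_outliers(self):
        # 7 ratios at 0.5, 3 outliers at 3.0, equal precision
        bx = np.full(10, 0.2)
        by = np.concatenate([np.full(7, 0.1), np.full(3, 0.6)])
        by += np.linspace(-0.004, 0.004, 10)  # break exact ties
        inst = make_instruments(bx, np.full(10, 0.01), by, np.full(10, 0.02))
        res = mode_estimate(inst, weighted=False, seed=7)
        res_ivw, _ = ivw(inst)
        assert abs(res.estimate - 0.5) < 0.1
        assert abs(res.estimate - 0.5) < abs(res_ivw.estimate - 0.5)

    def test_matches_grid_search_density_oracle(self):
        inst = simulate_summary_instruments(9, 0.15, seed=11)
        res = mode_estimate(inst, weighted=True, seed=1)
        bx = np.array([i.beta_exposure for i in inst])
        sy = np.array([i.se_outcome for i in inst])
        ratios = np.array([i.beta_outcome / i.beta_exposure for i in inst])
        w = (np.abs(bx) / sy) ** 2
        w = w / w.sum()
        s = 0.9 * min(np.std(ratios, ddof=1), stats.median_abs_deviation(ratios, scale="normal")) / len(ratios) ** 0.2
        fine = np.linspace(ratios.min() - 3 * s, ratios.max() + 3 * s, 20001)
        dens = np.zeros_like(fine)
        for r, wi in zip(ratios, w):
            dens += wi * stats.norm.pdf(fine, r, s)
        oracle = fine[np.argmax(dens)]
        # agreement up to the 512-point grid resolution
        grid_step = (ratios.max() - ratios.min() + 6 * s) / 511
        assert abs(res.estimate - oracle) <= grid_step

    def test_guards(self):
        inst = simulate_summary_instruments(5, 0.1, seed=2)
        with pytest.raises(ValueError, match="phi"):
            mode_estimate(inst, phi=0.0, seed=1)
        with pytest.raises(ValueError, match="at least 3"):
            mode_estimate(inst[:2], seed=1)


class TestHeterogeneityAndLoo:
    def test_identical_ratios_give_zero_q(self):
        inst = make_instruments([0.1, 0.2, 0.4], [0.01] * 3, [0.05, 0.10, 0.20], [0.02] * 3)
        het = cochran_q(inst)
        assert het.q == pytest.approx(0.0, abs=1e-20)
        assert het.pvalue == pytest.approx(1.0)
        assert het.df == 2

    def test_q_matches_wald_ratio_formula(self, random_instruments):
        inst = random_instruments(8)
        het = cochran_q(inst)
        bx = np.array([i.beta_exposure for i in inst])
        sy = np.array([i.se_outcome for i in inst])
        ratios = np.array([i.beta_outcome / i.beta_exposure for i in inst])
        w = (bx / sy) ** 2
        theta_ivw = np.sum(w * ratios) / np.sum(w)
        q = np.sum(w * (ratios - theta_ivw) ** 2)
        assert het.q == pytest.approx(q, rel=1e-10)
        assert het.pvalue == pytest.approx(stats.chi2.sf(q, len(inst) - 1), rel=1e-10)

    def test_leave_one_out_homogeneous_within_one_se(self):
        inst = simulate_summary_instruments(10, 0.2, seed=21)
        full, _ = ivw(inst)
        for rsid, res in leave_one_out(inst)[:-1]:
            assert abs(res.estimate - full.estimate) < full.se

    def test_leave_one_out_dominant_snp_moves_estimate_most(self):
        # one deviant, very high-precision SNP dominates the fit
        bx = np.array([0.2, 0.2, 0.2, 0.2, 0.2])
        by = np.array([0.02, 0.021, 0.019, 0.02, 0.12])
        sy = np.array([0.02, 0.02, 0.02, 0.02, 0.002])
        inst = make_instruments(bx, np.full(5, 0.01), by, sy)
        full, _ = ivw(inst)
        rows = leave_one_out(inst)[:-1]
        shifts = {rsid: abs(r.estimate - full.estimate) for rsid, r in rows}
        assert max(shifts, key=shifts.get) == "rs4"
        assert [rsid for rsid, _ in rows] == [i.rsid for i in inst]

    def test_q_type_one_error_calibrated(self):
        """Under homogeneity Q ~ chi2(L-1): rejection rate at 0.05 within
        binomial error over 1000 replicates."""
        reps, rejections = 1000, 0
        for seed in range(reps):
            inst = simulate_summary_instruments(6, 0.1, seed=30_000 + seed, se_exposure=1e-8)
            het = cochran_q(inst)
            rejections += het.pvalue < 0.05
        rate = rejections / reps
        assert abs(rate - 0.05) <= 3 * math.sqrt(0.05 * 0.95 / reps)


class TestReporting:
    def test_ci_and_p_null(self):
        lo, hi, p = ci_and_p(0.0, 0.1)
        assert p == pytest.approx(1.0)
        assert lo == -hi

    def test_ci_and_p_guards(self):
        with pytest.raises(ValueError):
            ci_and_p(0.1, 0.0)
        with pytest.raises(ValueError):
            ci_and_p(float("nan"), 0.1)

    def test_sd_to_grams_rounding(self):
        assert sd_to_grams(0.0, 484) == 0
        assert sd_to_grams(0.146, 484) == 71
        assert sd_to_grams(-0.0514, 484) == -25
        with pytest.raises(ValueError):
            sd_to_grams(0.1, -1.0)


class TestModelInterface:
    def test_fit_all_matches_individual_estimators(self):
        inst = simulate_summary_instruments(8, 0.2, seed=13)
        model = MRModel(inst, sd_grams=484)
        battery = model.fit_all(seed=99, n_boot=200)
        assert battery.results["ivw"].estimate == ivw(inst)[0].estimate
        assert battery.results["egger"].estimate == egger(inst)[0].estimate
        assert battery.heterogeneity.q == cochran_q(inst).q
        assert "ivw" in battery.summary().lower() or "ivw" in battery.summary()
        frame = battery.to_frame()
        assert set(frame["method"]) >= {"ivw", "egger", "weighted_median", "simple_mode", "weighted_mode"}
        assert "grams" in frame.columns

    def test_insufficient_instruments_marked_not_run(self):
        inst = simulate_summary_instruments(2, 0.2, seed=14)
        battery = MRModel(inst).fit_all(seed=1)
        assert "ivw" in battery.results and "egger" not in battery.results
        assert all("not run" in reason for reason in battery.skipped.values())
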