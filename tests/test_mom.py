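"""Method-of-moments estimators against brute-force moment oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dietcalib import (ErrorModelSpec, combine_estimates,
                       estimate_alpha_differential,
                       estimate_alpha_nondifferential,
                       estimate_error_variances, estimate_theta_bio,
                       estimate_theta_sr, fit_mom, mask_calibration,
                       simulate_full_trial, ScenarioConfig)
from dietcalib.data import ValidationError
from dietcalib.mom import (_ee_system_differential, _ee_system_nondifferential,
                           _g_differential, _g_nondifferential)
from dietcalib.simulate import replicate_rng

from conftest import make_dataset


# -- brute-force oracles: plain python loops, no shared code paths ----------

def o_mean(xs):
    return sum(xs) / len(xs)


def o_cov(xs, ys):
    mx, my = o_mean(xs), o_mean(ys)
    return sum((x - mx) * (y - my) for x, y in zip(xs, ys)) / (len(xs) - 1)


def split(d, g, sub_only=True):
    rows = [(q, m1, m2) for grp, q, m1, m2, s in
            zip(d.group, d.q, d.m[:, 0], d.m[:, 1], d.in_substudy)
            if grp == g and (s or not sub_only)]
    return ([r[0] for r in rows], [r[1] for r in rows], [r[2] for r in rows])


class TestThetaBio:
    def test_identical_groups_give_zero(self):
        d = make_dataset([1, 1, 1, 2, 2, 2], [1] * 6, [2] * 6, [2] * 6)
        est, _ = estimate_theta_bio(d)
        assert est == 0.0

    def test_simple_arithmetic(self):
        # per-individual means {1,2,3} vs {2,3,4}: effect 1, var 1/3 + 1/3
        d = make_dataset([1, 1, 1, 2, 2, 2], [0] * 6,
                         [1, 2, 3, 2, 3, 4], [1, 2, 3, 2, 3, 4])
        est, var = estimate_theta_bio(d)
        assert est == pytest.approx(1.0, abs=1e-12)
        assert var == pytest.approx(2 / 3, abs=1e-12)

    def test_matches_moment_oracle(self, toy_dataset):
        est, var = estimate_theta_bio(toy_dataset)
        mbars = {}
        for g in (1, 2):
            _, m1, m2 = split(toy_dataset, g)
            mbars[g] = [(a + b) / 2 for a, b in zip(m1, m2)]
        exp = o_mean(mbars[2]) - o_mean(mbars[1])
        exp_var = sum(o_cov(mbars[g], mbars[g]) / len(mbars[g]) for g in (1, 2))
        assert est == pytest.approx(exp, abs=1e-12)
        assert var == pytest.approx(exp_var, abs=1e-12)

    def test_unbiased_under_reference_settings(self):
        # the biomarker classical error model makes the estimator unbiased
        cfg = ScenarioConfig.differential(seed=13)
        ests = []
        for r in range(300):
            rng = replicate_rng(13, r)
            d = mask_calibration(simulate_full_trial(cfg, rng), 0.25, rng)
            ests.append(estimate_theta_bio(d)[0])
        ests = np.asarray(ests)
        mc_se = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean() - (-0.5)) < 3 * mc_se


class TestAlphaEstimates:
    def test_noise_free_exact_recovery(self, noise_free_dataset):
        al = estimate_alpha_differential(noise_free_dataset)
        np.testing.assert_allclose(al.alpha1, [0.8, 0.5], atol=1e-12)
        np.testing.assert_allclose(al.alpha0, [0.3, 1.5], atol=1e-10)

    def test_noise_free_pooled_recovery(self):
        rng = np.random.default_rng(8)
        t = rng.normal(4.3, 0.4, 40)
        d = make_dataset(group=np.r_[np.ones(20), 2 * np.ones(20)],
                         q=0.9 + 0.65 * t, m1=t, m2=t)
        al = estimate_alpha_nondifferential(d)
        assert al.alpha1[0] == pytest.approx(0.65, abs=1e-12)
        assert al.alpha0[0] == pytest.approx(0.9, abs=1e-10)

    def test_matches_covariance_oracle(self, toy_dataset):
        al = estimate_alpha_differential(toy_dataset)
        for i, g in enumerate((1, 2)):
            q, m1, m2 = split(toy_dataset, g)
            mbar = [(a + b) / 2 for a, b in zip(m1, m2)]
            slope = o_cov(q, mbar) / o_cov(m1, m2)
            assert al.alpha1[i] == pytest.approx(slope, abs=1e-12)
            assert al.alpha0[i] == pytest.approx(o_mean(q) - slope * o_mean(mbar),
                                                 abs=1e-12)

    def test_pooled_matches_oracle(self, toy_dataset):
        al = estimate_alpha_nondifferential(toy_dataset)
        q1, m11, m21 = split(toy_dataset, 1)
        q2, m12, m22 = split(toy_dataset, 2)
        q, m1, m2 = q1 + q2, m11 + m12, m21 + m22
        mbar = [(a + b) / 2 for a, b in zip(m1, m2)]
        slope = o_cov(q, mbar) / o_cov(m1, m2)
        assert al.alpha1[0] == pytest.approx(slope, abs=1e-12)

    def test_slope_consistency_large_n(self):
        cfg = ScenarioConfig.differential(n_per_group=40000, seed=21)
        d = simulate_full_trial(cfg, replicate_rng(21, 0))
        al = estimate_alpha_differential(d)
        np.testing.assert_allclose(al.alpha1, [0.8, 0.5], atol=0.03)

    def test_negative_replicate_covariance_flagged(self):
        # anti-correlated replicates: slope denominator <= 0
        m1 = [1.0, 2.0, 3.0, 4.0]
        m2 = [4.0, 3.0, 2.0, 1.0]
        d = make_dataset([1] * 4 + [2] * 4, [1, 2, 3, 4] * 2,
                         m1 + [1.0, 2.0, 3.0, 4.0], m2 + [1.0, 2.0, 3.0, 4.0])
        al = estimate_alpha_differential(d)
        assert not al.valid
        fit = fit_mom(d, ErrorModelSpec("differential"))
        assert not fit.valid
        assert any("covariance" in m for m in fit.messages)


class TestThetaSr:
    def test_formula_against_oracle(self, toy_dataset, spec_diff):
        al = estimate_alpha_differential(toy_dataset)
        est = estimate_theta_sr(toy_dataset, spec_diff, al)
        parts = []
        for i, g in enumerate((1, 2)):
            q_all, _, _ = split(toy_dataset, g, sub_only=False)
            q_sub, m1, m2 = split(toy_dataset, g)
            mbar = [(a + b) / 2 for a, b in zip(m1, m2)]
            parts.append(((o_mean(q_all) - o_mean(q_sub)) / al.alpha1[i],
                          o_mean(mbar)))
        expected = parts[1][0] - parts[0][0] + parts[1][1] - parts[0][1]
        assert est == pytest.approx(expected, abs=1e-12)

    def test_nondifferential_ratio_form(self, toy_dataset, spec_nondiff):
        al = estimate_alpha_nondifferential(toy_dataset)
        est = estimate_theta_sr(toy_dataset, spec_nondiff, al)
        q1, _, _ = split(toy_dataset, 1, sub_only=False)
        q2, _, _ = split(toy_dataset, 2, sub_only=False)
        assert est == pytest.approx((o_mean(q2) - o_mean(q1)) / al.alpha1[0],
                                    abs=1e-12)

    def test_full_calibration_reduces_to_biomarker_estimate(self, toy_dataset,
                                                            spec_diff):
        al = estimate_alpha_differential(toy_dataset)
        est = estimate_theta_sr(toy_dataset, spec_diff, al)
        assert est == pytest.approx(estimate_theta_bio(toy_dataset)[0], abs=1e-12)


class TestErrorVariances:
    def test_zero_biomarker_error_when_replicates_identical(self, spec_diff):
        t = np.array([4.0, 4.5, 5.0, 4.2, 3.0, 3.5, 3.2, 3.8])
        d = make_dataset([1] * 4 + [2] * 4, t * 0.8, t, t)
        al = estimate_alpha_differential(d)
        s2m, _ = estimate_error_variances(d, spec_diff, al)
        np.testing.assert_allclose(s2m, [0.0, 0.0], atol=1e-12)

    @pytest.mark.parametrize("structure", ["differential", "nondifferential"])
    def test_matches_moment_oracle(self, toy_dataset, structure):
        spec = ErrorModelSpec(structure)
        al = (estimate_alpha_differential(toy_dataset) if spec.is_differential
              else estimate_alpha_nondifferential(toy_dataset))
        s2m, s2q = estimate_error_variances(toy_dataset, spec, al)
        groups = (1, 2) if spec.is_differential else (None,)
        for i, g in enumerate(groups):
            if g is None:
                q1, m11, m21 = split(toy_dataset, 1)
                q2, m12, m22 = split(toy_dataset, 2)
                q, m1, m2 = q1 + q2, m11 + m12, m21 + m22
            else:
                q, m1, m2 = split(toy_dataset, g)
            c_mm = o_cov(m1, m2)
            a1 = al.alpha1[i]
            var_m = (o_cov(m1, m1) + o_cov(m2, m2)) / 2
            assert s2m[i] == pytest.approx(var_m - c_mm, abs=1e-12)
            assert s2q[i] == pytest.approx(o_cov(q, q) - a1**2 * c_mm, abs=1e-12)

    def test_large_n_recovery(self):
        cfg = ScenarioConfig.differential(n_per_group=40000, sigma2_q=(0.3, 0.3),
                                          seed=31)
        d = simulate_full_trial(cfg, replicate_rng(31, 0))
        al = estimate_alpha_differential(d)
        s2m, s2q = estimate_error_variances(d, ErrorModelSpec("differential"), al)
        np.testing.assert_allclose(s2m, [0.2, 0.2], atol=0.02)
        np.testing.assert_allclose(s2q, [0.3, 0.3], atol=0.02)


class TestCombination:
    def test_closed_form_example(self):
        c = combine_estimates(1.0, 2.0, var_bio=1.0, var_sr=2.0, cov_bio_sr=0.5)
        assert c.weight_bio == pytest.approx(0.75)
        assert c.var == pytest.approx((2.0 - 0.25) / 2.0)

    def test_symmetric_case_halves_variance(self):
        c = combine_estimates(0.0, 1.0, 1.0, 1.0, 0.0)
        assert c.weight_bio == pytest.approx(0.5)
        assert c.var == pytest.approx(0.5)

    def test_huge_self_report_variance_gives_biomarker_estimate(self):
        c = combine_estimates(-0.5, 3.0, 1.0, 1e12, 0.0)
        assert c.weight_bio == pytest.approx(1.0, abs=1e-9)
        assert c.theta == pytest.approx(-0.5, abs=1e-9)

    def test_non_positive_definite_flagged(self):
        c = combine_estimates(0.0, 1.0, 1.0, 1.0, 1.5)
        assert not c.valid

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.floats(0.1, 10), st.floats(0.1, 10), st.floats(-0.99, 0.99),
           st.floats(-2, 2), st.floats(-2, 2))
    def test_optimal_weights_beat_both_components(self, v1, v2, rho, t1, t2):
        cov = rho * np.sqrt(v1 * v2)
        c = combine_estimates(t1, t2, v1, v2, cov)
        if c.valid and not c.degenerate:
            assert c.var <= min(v1, v2) + 1e-12
            # weights sum to one by construction
            recon = c.weight_bio * t1 + (1 - c.weight_bio) * t2
            assert recon == pytest.approx(c.theta, rel=1e-9, abs=1e-9)


class TestEstimatingEquationSystem:
    @pytest.mark.parametrize("builder,g_fun", [
        (_ee_system_differential, _g_differential),
        (_ee_system_nondifferential, _g_nondifferential),
    ])
    def test_bread_is_diagonal_at_solution(self, sim_dataset_25pct, builder, g_fun):
        """The averaged Jacobian of the estimating functions is diagonal at
        the moment solution (all cross-terms are centered means)."""
        _, masked = sim_dataset_25pct
        beta, diag, psi = builder(masked)
        # solution check: equations average to zero
        np.testing.assert_allclose(psi.mean(axis=0), 0.0, atol=1e-10)

        def mean_psi(b):
            return _mean_psi_numeric(masked, builder, b)

        jac = np.empty((beta.size, beta.size))
        for k in range(beta.size):
            h = 1e-6 * max(1.0, abs(beta[k]))
            bp, bm = beta.copy(), beta.copy()
            bp[k] += h
            bm[k] -= h
            jac[:, k] = (mean_psi(bp) - mean_psi(bm)) / (2 * h)
        np.testing.assert_allclose(jac, np.diag(diag), atol=1e-6)

    def test_point_estimates_agree_with_direct_path(self, sim_dataset_25pct):
        _, masked = sim_dataset_25pct
        beta, _, _ = _ee_system_differential(masked)
        theta = _g_differential(beta)
        al = estimate_alpha_differential(masked)
        assert theta[0] == pytest.approx(estimate_theta_bio(masked)[0], abs=1e-10)
        assert theta[1] == pytest.approx(
            estimate_theta_sr(masked, ErrorModelSpec("differential"), al), abs=1e-10)


def _mean_psi_numeric(d, builder, beta):
    """Recompute the averaged estimating functions at an arbitrary beta by
    shifting the built-at-solution system (the psi are linear or bilinear in
    beta, so rebuild from raw data)."""
    import dietcalib.mom as mom
    sub = d.in_substudy
    m1 = np.where(sub, d.m[:, 0], 0.0)
    m2 = np.where(sub, d.m[:, 1], 0.0)
    s = sub.astype(float)
    if builder is mom._ee_system_differential:
        out = []
        for g, off in ((1, 0), (2, 6)):
            in_g = (d.group == g).astype(float)
            sg = s * in_g
            mu_q, mu_qs, mu_1, mu_2, c_qm, c_mm = beta[off:off + 6]
            mu_m = (mu_1 + mu_2) / 2
            mbar = (m1 + m2) / 2
            out += [
                (in_g * (d.q - mu_q)).mean(),
                (sg * (d.q - mu_qs)).mean(),
                (sg * (m1 - mu_1)).mean(),
                (sg * (m2 - mu_2)).mean(),
                (sg * ((d.q - mu_qs) * (mbar - mu_m) - c_qm)).mean(),
                (sg * ((m1 - mu_1) * (m2 - mu_2) - c_mm)).mean(),
            ]
        return np.array(out)
    mu_q1, mu_q2, mu_m1, mu_m2, mu_qs, nu1, nu2, c_qm, c_mm = beta
    in1 = (d.group == 1).astype(float)
    in2 = (d.group == 2).astype(float)
    mbar = (m1 + m2) / 2
    nubar = (nu1 + nu2) / 2
    return np.array([
        (in1 * (d.q - mu_q1)).mean(),
        (in2 * (d.q - mu_q2)).mean(),
        (in1 * s * (mbar - mu_m1)).mean(),
        (in2 * s * (mbar - mu_m2)).mean(),
        (s * (d.q - mu_qs)).mean(),
        (s * (m1 - nu1)).mean(),
        (s * (m2 - nu2)).mean(),
        (s * ((d.q - mu_qs) * (mbar - nubar) - c_qm)).mean(),
        (s * ((m1 - nu1) * (m2 - nu2) - c_mm)).mean(),
    ])


class TestFitMom:
    def test_full_calibration_combined_equals_biomarker(self, sim_dataset_25pct,
                                                        spec_diff):
        full, _ = sim_dataset_25pct
        fit = fit_mom(full, spec_diff)
        assert fit.theta_combined == fit.theta_bio
        assert fit.weight_bio == 1.0
        assert fit.valid

    def test_weight_and_variance_coherence(self, sim_dataset_25pct, spec_nondiff):
        _, masked = sim_dataset_25pct
        fit = fit_mom(masked, spec_nondiff)
        assert fit.valid
        assert fit.var_combined <= fit.var_bio + 1e-15
        assert fit.var_combined <= fit.var_sr + 1e-15
        recon = fit.weight_bio * fit.theta_bio + (1 - fit.weight_bio) * fit.theta_sr
        assert recon == pytest.approx(fit.theta_combined, rel=1e-10)

    def test_combined_unbiased_under_correct_nondifferential_spec(self):
        cfg = ScenarioConfig.nondifferential(seed=17)
        ests = []
        for r in range(300):
            rng = replicate_rng(17, r)
            d = mask_calibration(simulate_full_trial(cfg, rng), 0.25, rng)
            fit = fit_mom(d, ErrorModelSpec("nondifferential"))
            if fit.valid:
                ests.append(fit.theta_combined)
        ests = np.asarray(ests)
        mc_se = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean() + 0.5) < 3 * mc_se

    def test_requires_enough_substudy_members(self, spec_diff):
        d = make_dataset([1, 1, 1, 2, 2, 2], [1, 2, 3, 4, 5, 6],
                         [1, 2, np.nan, 4, 5, 6], [1, 2, np.nan, 4, 5, 6])
        with pytest.raises(ValidationError):
            fit_mom(d, spec_diff)
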