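"""Estimation: marginal-likelihood fits, pooled fits, and the LRT."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

import xenopower as xp
from xenopower import GrowthParams, TumorGrowthModel


@pytest.fixture(scope="module")
def tight_study():
    """Simulated study with almost no between-animal variability."""
    p = GrowthParams(mu1=1.29, mu2=-2.4, sigma1=1e-4, sigma2=1e-4, sigma3=0.05)
    return xp.simulate_study(p, n_per_arm=10, horizon=21, seed=3), p


class TestMixedFit:
    def test_recovery_in_no_random_effect_limit(self, tight_study):
        """With sigma1 = sigma2 ~ 0 the fixed effects are recovered well
        within 3 standard errors."""
        study, truth = tight_study
        res = xp.fit_mixed(study, with_treatment_effect=False)
        assert res.converged
        se = res.bse
        assert abs(res.estimates["mu1"] - truth.mu1) < 3 * max(se["mu1"], 1e-3)
        assert abs(res.estimates["mu2"] - truth.mu2) < 3 * max(se["mu2"], 1e-3)

    def test_parameter_recovery_large_study(self, pdx_params):
        """All five population parameters recovered within 10% relative
        error from 200 animals (1800 observations)."""
        study = xp.simulate_study(pdx_params, n_per_arm=100, horizon=28, seed=1)
        res = xp.fit_mixed(study, with_treatment_effect=False)
        assert res.converged
        truth = {
            "mu1": pdx_params.mu1, "mu2": pdx_params.mu2,
            "sigma1": pdx_params.sigma1, "sigma2": pdx_params.sigma2,
            "sigma3": pdx_params.sigma3,
        }
        for name, true_val in truth.items():
            rel = abs(res.estimates[name] - true_val) / abs(true_val)
            assert rel < 0.10, f"{name}: {res.estimates[name]} vs {true_val}"

    def test_null_effect_recovery(self, null_study):
        """On a c=0 study the estimated effect is within 3 SE of zero."""
        res = xp.fit_mixed(null_study, with_treatment_effect=True)
        assert res.converged
        assert abs(res.estimates["c"]) < 3 * res.bse["c"]

    def test_radius_and_volume_scales_agree_noise_free(self):
        """Identical (mu1, mu2) from radius- and volume-scale fits on the
        same near-noise-free data."""
        p = GrowthParams(mu1=1.0, mu2=-2.2, sigma1=1e-4, sigma2=1e-4, sigma3=1e-3)
        study = xp.simulate_study(p, n_per_arm=5, horizon=14, seed=11)
        res_r = xp.fit_mixed(study, scale="radius", with_treatment_effect=False)
        res_v = xp.fit_mixed(study, scale="volume", with_treatment_effect=False)
        assert res_r.estimates["mu1"] == pytest.approx(res_v.estimates["mu1"], abs=1e-3)
        assert res_r.estimates["mu2"] == pytest.approx(res_v.estimates["mu2"], abs=1e-3)

    def test_laplace_and_aghq_agree(self, effect_study):
        """5-node adaptive Gauss-Hermite cross-check stays close to the
        Laplace approximation of the marginal likelihood."""
        res_l = TumorGrowthModel(effect_study, integration="laplace").fit()
        res_q = TumorGrowthModel(effect_study, integration="aghq").fit()
        assert res_l.loglik == pytest.approx(res_q.loglik, abs=1.0)
        assert res_l.estimates["c"] == pytest.approx(res_q.estimates["c"], abs=0.1)

    def test_animal_order_invariance(self, effect_study):
        """The maximized likelihood does not depend on animal ordering."""
        res = xp.fit_mixed(effect_study)
        shuffled = xp.StudyTable(
            study_id=effect_study.study_id,
            animals=list(reversed(effect_study.animals)),
            horizon=effect_study.horizon,
        )
        res2 = xp.fit_mixed(shuffled)
        assert res.loglik == pytest.approx(res2.loglik, abs=1e-3)

    def test_requires_minimum_data(self, pdx_params):
        a = xp.AnimalTrajectory("c1", "control", [0, 7], [100, 200])
        b = xp.AnimalTrajectory("t1", "treated", [0.0], [100.0])
        with pytest.raises(ValueError):
            TumorGrowthModel(xp.StudyTable("s", [a, b], 14))

    def test_summary_renders(self, null_study):
        res = xp.fit_mixed(null_study)
        text = res.summary()
        for token in ("mu1", "sigma3", "log-likelihood", "mixed"):
            assert token in text


class TestPooledFit:
    def test_matches_mixed_in_no_random_effect_limit(self, tight_study):
        """Pooled and mixed point estimates of (mu1, mu2) agree when the
        data carry no between-animal variability."""
        study, _ = tight_study
        res_m = xp.fit_mixed(study, with_treatment_effect=False)
        res_p = xp.fit_pooled(study, with_treatment_effect=False)
        assert res_p.estimates["mu1"] == pytest.approx(res_m.estimates["mu1"], abs=1e-3)
        assert res_p.estimates["mu2"] == pytest.approx(res_m.estimates["mu2"], abs=1e-3)

    def test_noise_free_exact_line(self):
        """Noise-free shared-line data: exact recovery with the residual SD
        pinned at its floor."""
        p = GrowthParams(mu1=1.0, mu2=-2.0, sigma1=0.0, sigma2=0.0, sigma3=0.0)
        study = xp.simulate_study(p, n_per_arm=2, horizon=14, seed=0)
        res = xp.fit_pooled(study, with_treatment_effect=False)
        assert res.estimates["mu1"] == pytest.approx(1.0, abs=1e-5)
        assert res.estimates["mu2"] == pytest.approx(-2.0, abs=1e-5)
        assert res.boundary
        assert np.isfinite(res.loglik)

    def test_nesting(self, effect_study):
        res0 = xp.fit_pooled(effect_study, with_treatment_effect=False)
        res1 = xp.fit_pooled(effect_study, with_treatment_effect=True)
        assert res1.loglik >= res0.loglik - 1e-4


class TestLrt:
    def test_zero_statistic_gives_p_one(self, null_study):
        r0 = xp.fit_pooled(null_study, with_treatment_effect=False)
        r1 = xp.fit_pooled(null_study, with_treatment_effect=True)
        fake = xp.lrt(r0, r1)
        assert fake.statistic >= 0
        # chi-square reference points
        assert 1.0 - stats.chi2.cdf(0.0, 1) == 1.0
        assert stats.chi2.sf(3.841459, 1) == pytest.approx(0.05, abs=1e-6)

    def test_mixed_lrt_detects_strong_effect(self, effect_study):
        tr = xp.lr_treatment_test(effect_study, approach="mixed")
        assert tr.method == "lrt_mixed"
        assert tr.p_value < 0.05
        assert tr.effect < 0  # growth slowed

    def test_nesting_enforced_by_warm_start(self, pdx_params):
        """loglik(with effect) >= loglik(without) on every dataset."""
        for seed in range(5):
            study = xp.simulate_study(pdx_params, 8, 14, seed=seed)
            tr = xp.lr_treatment_test(study)
            assert tr.statistic >= 0.0

    def test_mismatched_fits_rejected(self, null_study, effect_study):
        r0 = xp.fit_pooled(null_study, with_treatment_effect=False)
        r1 = xp.fit_mixed(null_study, with_treatment_effect=True)
        with pytest.raises(ValueError):
            xp.lrt(r0, r1)  # approach mismatch
        r1b = xp.fit_pooled(null_study, with_treatment_effect=True)
        with pytest.raises(ValueError):
            xp.lrt(r1b, r0)  # null/alt swapped


class TestModelApi:
    def test_from_dataframe_roundtrip(self, effect_study):
        df = effect_study.to_dataframe()
        model = TumorGrowthModel.from_dataframe(df, horizon=14)
        res = model.fit()
        direct = xp.fit_mixed(effect_study)
        assert res.loglik == pytest.approx(direct.loglik, abs=1e-3)

    def test_to_dict_serialisable(self, null_study):
        import json

        res = xp.fit_pooled(null_study)
        json.dumps(res.to_dict())
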