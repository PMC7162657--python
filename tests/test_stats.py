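"""Partial correlation, FDR, GAM fits, and mediation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctrlenergy.errors import (
    DegenerateTestError,
    ParameterError,
    UndefinedCorrelationError,
    ValidationError,
)
from ctrlenergy.stats import (
    fdr_correct,
    fit_age_gam,
    fit_age_gam_table,
    fit_cognition_gam,
    fit_cognition_gam_table,
    mediation_bootstrap,
    partial_correlation,
    signed_z_from_p,
)

from oracles import bh_stepup_oracle, partial_correlation_precision_oracle


def _toy_cohort(n, rng, age=None):
    age = rng.uniform(8, 23, n) if age is None else age
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "age": age,
            "sex": rng.integers(0, 2, n).astype(float),
            "handedness": rng.integers(0, 2, n).astype(float),
            "motion": rng.normal(0.08, 0.02, n),
            "tbv": rng.normal(1250, 90, n),
            "network_strength": rng.normal(100, 10, n),
            "ef_score": rng.standard_normal(n),
        }
    )


class TestPartialCorrelation:
    def test_identity(self, rng):
        x = rng.standard_normal(50)
        r, lo, hi = partial_correlation(x, x)
        assert r == pytest.approx(1.0)

    def test_matches_precision_matrix_oracle(self, rng):
        x = rng.standard_normal(200)
        cov = rng.standard_normal((200, 3))
        y = 0.4 * x + cov @ [0.3, -0.2, 0.5] + rng.standard_normal(200)
        r, _, _ = partial_correlation(x, y, cov)
        oracle = partial_correlation_precision_oracle(x, y, cov)
        assert r == pytest.approx(oracle, abs=1e-10)

    def test_fisher_ci_hand_example(self, rng):
        """r = 0.5 at n = 103 with no covariates -> CI ~ [0.34, 0.63]."""
        # construct vectors with sample correlation exactly 0.5
        x = rng.standard_normal(103)
        e = rng.standard_normal(103)
        x = (x - x.mean()) / x.std()
        e = e - e.mean()
        e -= x * (x @ e) / (x @ x)
        e /= e.std()
        rho = 0.5
        y = rho * x + np.sqrt(1 - rho**2) * e
        r, lo, hi = partial_correlation(x, y)
        assert r == pytest.approx(0.5, abs=1e-12)
        assert lo == pytest.approx(0.34, abs=0.005)
        assert hi == pytest.approx(0.63, abs=0.005)

    def test_constant_residuals_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            partial_correlation(np.ones(30), np.arange(30.0))

    def test_small_n_rejected(self, rng):
        with pytest.raises(ParameterError):
            partial_correlation(np.arange(5.0), np.arange(5.0), rng.standard_normal((5, 2)))


class TestFdr:
    def test_all_ones_nothing_rejected(self):
        q, rej = fdr_correct(np.ones(10))
        assert not rej.any()

    def test_hand_stepup_example(self):
        q, rej = fdr_correct([0.001, 0.01, 0.02, 0.04, 0.2], q=0.05)
        np.testing.assert_array_equal(rej, [True, True, True, True, False])

    def test_single_p(self):
        _, rej = fdr_correct([0.04])
        assert rej[0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            fdr_correct([0.5, 1.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(rng.integers(1, 40))
        _, rej = fdr_correct(p, q=0.05)
        np.testing.assert_array_equal(rej, bh_stepup_oracle(p, 0.05))


class TestSignedZ:
    def test_sign_and_magnitude(self):
        assert signed_z_from_p(0.05, -1.0) == pytest.approx(-1.96, abs=0.001)
        assert signed_z_from_p(0.0, 1.0) > 37.0
        assert np.isfinite(signed_z_from_p(0.0, -1.0))


class TestAgeGam:
    def test_planted_linear_decline(self, rng):
        """Slope -0.5 sd per age-sd at n=500 gives Z < -4, partial r < -0.3."""
        cohort = _toy_cohort(500, rng)
        z_age = (cohort.age - cohort.age.mean()) / cohort.age.std()
        feature = -0.5 * z_age + rng.standard_normal(500)
        res = fit_age_gam(feature, cohort)
        assert res.z_value < -4
        assert res.partial_r < -0.3
        assert res.ci_low <= res.partial_r <= res.ci_high

    def test_linear_effect_partial_r_matches_adjusted_pearson(self, rng):
        cohort = _toy_cohort(500, rng)
        z_age = (cohort.age - cohort.age.mean()) / cohort.age.std()
        feature = (-0.4 * z_age + rng.standard_normal(500)).to_numpy()
        res = fit_age_gam(feature, cohort)
        covs = cohort[["sex", "handedness", "motion", "tbv", "network_strength"]]
        r_simple, _, _ = partial_correlation(feature, cohort.age.to_numpy(), covs.to_numpy())
        assert abs(res.partial_r - r_simple) < 0.02

    def test_pure_quadratic_detected_by_smooth_only(self, rng):
        """A centered quadratic age effect: smooth p < 0.01, |partial r| < 0.1."""
        cohort = _toy_cohort(500, rng)
        mid = (8 + 23) / 2
        z2 = ((cohort.age - mid) ** 2 - ((cohort.age - mid) ** 2).mean()).to_numpy()
        age_c = (cohort.age - cohort.age.mean()).to_numpy()
        z2 -= age_c * (age_c @ z2) / (age_c @ age_c)  # exact zero linear component
        feature = 0.5 * z2 / z2.std() + 0.5 * rng.standard_normal(500)
        res = fit_age_gam(feature, cohort)
        assert res.p_value < 0.01
        assert abs(res.partial_r) < 0.1

    def test_null_features_calibrated(self, rng):
        """Pure-noise features produce ~5% false positives at alpha=0.05."""
        cohort = _toy_cohort(300, rng)
        noise = pd.DataFrame(
            rng.standard_normal((300, 120)), columns=[f"f{i}" for i in range(120)]
        )
        tab = fit_age_gam_table(noise, cohort)
        frac = (tab["p_value"] < 0.05).mean()
        assert 0.0 <= frac <= 0.11  # 0.05 +/- ~3 binomial sd at m=120

    def test_rank_deficient_design_names_columns(self, rng):
        cohort = _toy_cohort(100, rng)
        extra = pd.DataFrame({"dup_motion": cohort["motion"]})
        with pytest.raises(ValidationError, match="dup_motion"):
            fit_age_gam(rng.standard_normal(100), cohort, extra_covariates=extra)


class TestCognitionGam:
    def test_planted_ef_effect(self, rng):
        cohort = _toy_cohort(500, rng)
        z_ef = (cohort.ef_score - cohort.ef_score.mean()) / cohort.ef_score.std()
        feature = -0.2 * z_ef + rng.standard_normal(500)
        res = fit_cognition_gam(feature, cohort)
        assert res.z_value < 0
        assert res.p_value < 0.01
        assert res.partial_r < 0

    def test_missing_ef_rows_dropped(self, rng, caplog):
        cohort = _toy_cohort(120, rng)
        cohort.loc[[3, 7], "ef_score"] = np.nan
        with caplog.at_level("INFO", logger="ctrlenergy.stats"):
            res = fit_cognition_gam(rng.standard_normal(120), cohort)
        assert np.isfinite(res.p_value)
        assert any("2 subject" in m for m in caplog.messages)


class TestMediation:
    def test_identity_and_decomposition(self, rng):
        x = rng.standard_normal(400)
        m = 0.5 * x + rng.standard_normal(400)
        y = 0.4 * m + 0.2 * x + rng.standard_normal(400)
        res = mediation_bootstrap(x, m, y, n_boot=500, seed=1)
        assert res.indirect == pytest.approx(res.path_a * res.path_b, abs=1e-12)
        # total effect decomposition is exact for nested OLS
        assert res.path_c == pytest.approx(
            res.path_c_prime + res.path_a * res.path_b, abs=1e-10
        )

    def test_planted_chain_recovery(self):
        rng = np.random.default_rng(17)
        n = 2000
        x = rng.standard_normal(n)
        m = 0.6 * x + np.sqrt(1 - 0.36) * rng.standard_normal(n)
        y = 0.5 * m + np.sqrt(1 - 0.25) * rng.standard_normal(n)
        res = mediation_bootstrap(x, m, y, n_boot=2000, seed=2)
        assert res.indirect == pytest.approx(0.30, abs=0.05)
        assert res.ci_low > 0

    def test_null_mediator_ci_covers_zero(self):
        cover = 0
        for rep in range(40):
            rng = np.random.default_rng(900 + rep)
            x = rng.standard_normal(500)
            m = rng.standard_normal(500)
            y = 0.3 * x + rng.standard_normal(500)
            res = mediation_bootstrap(x, m, y, n_boot=500, seed=rep)
            cover += res.ci_low <= 0 <= res.ci_high
        assert cover >= 35  # expect ~95% coverage

    def test_seed_determinism(self, rng):
        x = rng.standard_normal(200)
        m = 0.5 * x + rng.standard_normal(200)
        y = 0.5 * m + rng.standard_normal(200)
        r1 = mediation_bootstrap(x, m, y, n_boot=300, seed=5)
        r2 = mediation_bootstrap(x, m, y, n_boot=300, seed=5)
        assert (r1.ci_low, r1.ci_high, r1.p_value) == (r2.ci_low, r2.ci_high, r2.p_value)

    def test_matches_pingouin_paths(self, rng):
        """Cross-check point estimates against an independent implementation."""
        pingouin = pytest.importorskip("pingouin")
        x = rng.standard_normal(300)
        m = 0.5 * x + rng.standard_normal(300)
        y = 0.4 * m + 0.1 * x + rng.standard_normal(300)
        xs = (x - x.mean()) / x.std()
        ms = (m - m.mean()) / m.std()
        ys = (y - y.mean()) / y.std()
        res = mediation_bootstrap(x, m, y, n_boot=500, seed=3)
        df = pd.DataFrame({"x": xs, "m": ms, "y": ys})
        pg = pingouin.mediation_analysis(data=df, x="x", m="m", y="y", seed=3)
        coef = pg.set_index("path")["coef"]
        assert res.indirect == pytest.approx(coef["Indirect"], abs=1e-6)
        assert res.path_c == pytest.approx(coef["Total"], abs=1e-6)

    def test_guards(self, rng):
        x = rng.standard_normal(50)
        with pytest.raises(ParameterError):
            mediation_bootstrap(x, x, x, n_boot=10)
        with pytest.raises(ValidationError):
            mediation_bootstrap(x, x[:-1], x)
        with pytest.raises(DegenerateTestError):
            mediation_bootstrap(np.ones(50), x, x, n_boot=200)
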