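"""Correlation rules, partial correlation, bootstrap mediation, the
one-factor latent model, and group statistics, cross-checked against
independent oracles (pingouin, closed forms)."""

import numpy as np
import pytest

from rigidlink import inference as inf


class TestCorrelate:
    def test_pearson_perfect(self):
        r = inf.correlate([1, 2, 3], [2, 4, 6])
        assert r.method == "pearson"
        assert r.coefficient == pytest.approx(1.0)

    def test_ordinal_flag_forces_spearman(self):
        r = inf.correlate([1, 2, 3], [2, 4, 6], y_is_ordinal=True)
        assert r.method == "spearman"

    def test_spearman_monotone_nonlinear(self):
        r = inf.correlate([1, 2, 3], [1, 4, 9], x_is_ordinal=True)
        assert r.coefficient == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            inf.correlate([1, 1, 1], [1, 2, 3])


class TestPartialCorrelation:
    def test_orthogonal_z_recovers_raw(self, rng):
        x = rng.normal(0, 1, 200)
        y = 0.5 * x + rng.normal(0, 1, 200)
        z = rng.normal(0, 1, 200)  # independent of both
        raw = np.corrcoef(x, y)[0, 1]
        assert inf.partial_correlation(x, y, z) == pytest.approx(raw, abs=0.05)

    def test_degenerate_x_equals_z(self, rng):
        z = rng.normal(0, 1, 50)
        y = rng.normal(0, 1, 50)
        with pytest.raises(ValueError, match="degenerate|collinear"):
            inf.partial_correlation(z, y, z)

    def test_matches_precision_matrix_oracle(self, rng):
        """Residual-based partial correlation equals the inverse-
        correlation-matrix formula (independently via pingouin)."""
        import pandas as pd
        import pingouin as pg

        x = rng.normal(0, 1, 50)
        z = rng.normal(0, 1, 50)
        y = 0.4 * x + 0.3 * z + rng.normal(0, 1, 50)
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        expected = pg.partial_corr(df, x="x", y="y", covar="z")["r"].iloc[0]
        assert inf.partial_correlation(x, y, z) == pytest.approx(expected, abs=1e-10)

    def test_symmetric(self, rng):
        x, y, z = rng.normal(size=(3, 40))
        assert inf.partial_correlation(x, y, z) == pytest.approx(
            inf.partial_correlation(y, x, z)
        )


class TestMediate:
    def test_noiseless_chain_exact(self, rng):
        # y depends on m alone; a vanishing perturbation on m keeps the
        # y ~ x + m design full-rank so the chain algebra is recoverable
        x = rng.normal(0, 1, 30)
        m = 2.0 * x + 1e-6 * rng.normal(0, 1, 30)
        y = 3.0 * m
        r = inf.mediate(x, m, y, n_boot=1000, seed=0)
        assert r.alpha == pytest.approx(2.0, abs=1e-5)
        assert r.beta == pytest.approx(3.0, abs=1e-5)
        assert r.indirect == pytest.approx(6.0, abs=1e-4)
        assert r.gamma == pytest.approx(0.0, abs=1e-4)
        assert r.indirect == r.alpha * r.beta

    def test_standardized_scale_invariance(self, rng):
        x = rng.normal(0, 1, 40)
        m = 0.5 * x + rng.normal(0, 1, 40)
        y = 0.5 * m + rng.normal(0, 1, 40)
        a = inf.mediate(x, m, y, n_boot=1000, seed=3, standardize=True)
        b = inf.mediate(x * 13.0, m / 7.0, y * 3.0, n_boot=1000, seed=3, standardize=True)
        assert a.indirect == pytest.approx(b.indirect, rel=1e-10)
        assert a.p_indirect == b.p_indirect

    def test_point_estimates_match_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        x = rng.normal(0, 1, 60)
        m = 0.6 * x + rng.normal(0, 1, 60)
        y = 0.5 * m + 0.2 * x + rng.normal(0, 1, 60)
        r = inf.mediate(x, m, y, n_boot=1000, seed=1)
        df = pd.DataFrame({"x": x, "m": m, "y": y})
        tab = pg.mediation_analysis(df, x="x", m="m", y="y", n_boot=100, seed=1)
        coef = tab.set_index("path")["coef"]
        assert r.alpha == pytest.approx(coef["m ~ X"], rel=1e-8)
        assert r.gamma == pytest.approx(coef["Direct"], rel=1e-8)
        assert r.indirect == pytest.approx(coef["Indirect"], rel=1e-6)

    def test_ci_contains_point_and_converges(self, rng):
        x = rng.normal(0, 1, 50)
        m = 0.7 * x + rng.normal(0, 1, 50)
        y = 0.6 * m + rng.normal(0, 1, 50)
        a = inf.mediate(x, m, y, n_boot=10_000, seed=10)
        b = inf.mediate(x, m, y, n_boot=10_000, seed=99)
        assert a.ci_lower <= a.indirect <= a.ci_upper
        assert a.ci_lower == pytest.approx(b.ci_lower, abs=0.02)
        assert a.ci_upper == pytest.approx(b.ci_upper, abs=0.02)

    def test_p_floor(self, rng):
        x = rng.normal(0, 1, 50)
        m = 2 * x + rng.normal(0, 0.01, 50)
        y = 2 * m + rng.normal(0, 0.01, 50)
        r = inf.mediate(x, m, y, n_boot=1000, seed=2)
        assert r.p_indirect == pytest.approx(1.0 / 1000)

    def test_too_few_subjects(self, rng):
        with pytest.raises(ValueError, match="n >= 10"):
            inf.mediate(np.ones(5), np.ones(5), np.ones(5), n_boot=1000)


class TestVoxelwiseMediation:
    def test_single_voxel_matches_scalar(self, rng):
        n = 30
        x = rng.normal(0, 1, n)
        m = 0.7 * x + rng.normal(0, 1, n)
        y = 0.6 * m + rng.normal(0, 1, n)
        vol = m.reshape(n, 1, 1, 1)
        mask = np.ones((1, 1, 1), bool)
        ind_map, p_map, fdr, failed = inf.voxelwise_mediation(
            x, vol, y, mask, n_boot=2000, seed=4
        )
        scalar = inf.mediate(x, m, y, n_boot=2000, seed=4, standardize=True)
        assert failed == 0
        assert ind_map[0, 0, 0] == pytest.approx(scalar.indirect, rel=1e-8)
        assert p_map[0, 0, 0] == pytest.approx(scalar.p_indirect, abs=0.03)

    def test_null_volume_quiet(self, rng):
        n = 25
        x = rng.normal(0, 1, n)
        y = rng.normal(0, 1, n)
        vol = rng.normal(0, 1, (n, 4, 4, 2))
        mask = np.ones((4, 4, 2), bool)
        _, _, fdr, _ = inf.voxelwise_mediation(x, vol, y, mask, n_boot=1000, seed=5)
        assert fdr.sum() == 0


class TestLatentModel:
    def test_loading_recovery(self, rng):
        lam = np.array([1.0, 0.8, 0.6])
        theta = np.array([0.3, 0.5, 0.7])
        n = 2000
        f = rng.normal(0, 1, (n, 1))
        X = f @ lam[None, :] + rng.normal(0, 1, (n, 3)) * np.sqrt(theta)
        fit = inf.fit_latent_model(X, standardize=False)
        assert fit.converged
        assert np.allclose(fit.loadings, lam, atol=0.1)

    def test_just_identified_saturation(self, rng):
        lam = np.array([0.9, 0.7, 0.5])
        f = rng.normal(0, 1, (500, 1))
        X = f @ lam[None, :] + rng.normal(0, 1, (500, 3)) * 0.7
        fit = inf.fit_latent_model(X)
        assert fit.srmr == pytest.approx(0.0, abs=1e-3)
        assert fit.rmsea == 0.0
        assert fit.df == 0
        assert np.isnan(fit.agfi)

    def test_sign_convention(self, rng):
        lam = np.array([-0.8, -0.7, -0.6])  # generating loadings all negative
        f = rng.normal(0, 1, (800, 1))
        X = f @ lam[None, :] + rng.normal(0, 1, (800, 3)) * 0.5
        fit = inf.fit_latent_model(X)
        assert fit.loadings[0] >= 0  # first loading forced non-negative

    def test_model_reproduces_generating_covariance(self, rng):
        lam = np.array([0.9, 0.8, 0.7, 0.6])
        f = rng.normal(0, 1, (2000, 1))
        X = f @ lam[None, :] + rng.normal(0, 1, (2000, 4)) * 0.6
        fit = inf.fit_latent_model(X)
        assert fit.srmr < 0.05
        assert fit.cfi > 0.95

    def test_too_few_indicators(self, rng):
        with pytest.raises(ValueError, match="3 indicators"):
            inf.fit_latent_model(rng.normal(size=(50, 2)))


class TestGroupStats:
    def test_cohens_d_hand_value(self):
        assert abs(inf.cohens_d([1, 2, 3], [3, 4, 5])) == pytest.approx(2.0)

    def test_identical_groups(self):
        t, dof, p = inf.two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert dof == 4
        f, _, _ = inf.one_way_anova([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert f == pytest.approx(0.0)

    def test_split_plot_matches_mixed_anova_oracle(self, rng):
        """Group main-effect F equals pingouin's mixed ANOVA on the same
        long-format data."""
        import pandas as pd
        import pingouin as pg

        n, runs = 12, 5
        groups = np.repeat(["a", "b"], n // 2)
        data = rng.normal(0, 1, (n, runs)) + (groups == "b")[:, None] * 0.8
        f, (df1, df2), p = inf.split_plot_anova(data, groups)
        long = pd.DataFrame(
            {
                "y": data.ravel(),
                "subject": np.repeat(np.arange(n), runs),
                "run": np.tile(np.arange(runs), n),
                "group": np.repeat(groups, runs),
            }
        )
        aov = pg.mixed_anova(long, dv="y", within="run", subject="subject", between="group")
        row = aov[aov["Source"] == "group"].iloc[0]
        assert f == pytest.approx(row["F"], rel=1e-8)
        assert (df1, df2) == (row["DF1"], row["DF2"])
        assert p == pytest.approx(row["p_unc"], rel=1e-8)

    def test_split_plot_rejects_unbalanced(self, rng):
        data = rng.normal(size=(5, 3))
        with pytest.raises(ValueError, match="unbalanced"):
            inf.split_plot_anova(data, ["a", "a", "a", "b", "b"])

    def test_bonferroni(self):
        assert inf.bonferroni_alpha(0.05, 2) == 0.025
        assert inf.bonferroni_alpha(0.05, 1) == 0.05

    def test_rrb_strata(self):
        roi = np.array([1.0, 1.1, 0.9, 0.5, 0.6])
        rrb = np.array([0, 0, 0, 1, 2])
        t, p = inf.rrb_strata_test(roi, rrb)
        assert t > 0  # RRB = 0 stratum has larger GMV
        with pytest.raises(ValueError, match="RRB >= 1"):
            inf.rrb_strata_test(roi[:3], rrb[:3])

    def test_rrb_strata_sign_on_generated_cohorts(self):
        """ASD cohorts with a negative cluster loading show lower ROI GMV
        in the RRB >= 1 stratum in nearly all simulations."""
        import dataclasses

        from rigidlink.synthetic import CohortSpec, generate_gmv_images

        from scipy.stats import norm

        spec = CohortSpec(volume_shape=(16, 16, 16), voxel_size_mm=6.0,
                          cluster_center=(10, 6, 10), cluster_radius_mm=12.0)
        cal = spec.demo_calibration
        rng = np.random.default_rng(17)
        ok = 0
        n_sims = 50
        for _ in range(n_sims):
            trait = rng.normal(spec.trait_mean_asd, spec.trait_sd, 22)
            u_rrb = trait + rng.normal(0, cal.rrb_trait_noise_sd, 22)
            sd = np.hypot(spec.trait_sd, cal.rrb_trait_noise_sd)
            cuts = [spec.trait_mean_asd + sd * norm.ppf(q) for q in cal.rrb_cut_quantiles]
            rrb = np.digitize(u_rrb, cuts)
            if (rrb == 0).sum() == 0 or (rrb >= 1).sum() == 0:
                continue
            stack = generate_gmv_images(trait, np.ones(22, bool), spec, rng)
            roi = stack.values[:, stack.planted].mean(axis=1)
            t, _ = inf.rrb_strata_test(roi, rrb)
            ok += t > 0
            n_checked = ok
        assert ok / n_sims >= 0.9
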