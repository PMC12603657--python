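import numpy as np
import pandas as pd
import pytest

from vssr import datasets, simulate
from vssr.forward import HeadModel, build_grid
from vssr.group_stats import (chi_square_independence, demographic_comparison,
                              derive_auditory_covariates,
                              fit_entrainment_lme, partial_correlation,
                              peak_behavior_correlation,
                              pooled_t_from_summary,
                              whole_brain_partial_correlation)


class TestAuditoryCovariates:
    def test_flat_audiogram(self):
        bepta, weekly = derive_auditory_covariates(
            [40, 40, 40, 40], [40, 40, 40, 40], 8.0, 4.0)
        assert bepta == 40.0
        assert weekly == 48.0

    def test_better_ear_selected(self):
        bepta, _ = derive_auditory_covariates(
            [30, 40, 50, 60], [20, 30, 40, 50], 8.0, 8.0)
        assert bepta == 35.0

    def test_sixteen_hours_daily_gives_112(self):
        _, weekly = derive_auditory_covariates(
            [40] * 4, [40] * 4, 16.0, 16.0)
        assert weekly == 112.0

    def test_missing_threshold_raises(self):
        with pytest.raises(ValueError):
            derive_auditory_covariates([30, 40, np.nan, 60], [20] * 4,
                                       8.0, 8.0)

    def test_out_of_range_hours_raise(self):
        with pytest.raises(ValueError):
            derive_auditory_covariates([30] * 4, [20] * 4, 25.0, 8.0)


class TestEntrainmentLME:
    @staticmethod
    def noiseless_table(slope_per_ms=0.002):
        from vssr.tfr import entrainment_bin_centers
        t_ms = entrainment_bin_centers() * 1000.0
        rows = []
        for sid, group in (("a", "CNH"), ("b", "CNH"),
                           ("c", "CHH"), ("d", "CHH")):
            for tm in t_ms:
                rows.append((sid, group, tm, 1.0 + slope_per_ms * tm))
        return pd.DataFrame(rows, columns=["subject_id", "group",
                                           "time_ms", "relative_power"])

    def test_noiseless_closed_form(self):
        """Deterministic shared line: slope exact, interaction zero."""
        fit = fit_entrainment_lme(self.noiseless_table())
        assert fit.params["time_ms"] == pytest.approx(0.002, abs=1e-9)
        assert fit.params["group:time_ms"] == pytest.approx(0.0, abs=1e-9)
        assert fit.params["group"] == pytest.approx(0.0, abs=1e-7)
        assert fit.residual_var < 1e-12
        assert fit.n_obs == 4 * 14

    def test_reduces_to_ols_without_subject_variance(self):
        import statsmodels.api as sm
        tab = self.noiseless_table()
        fit = fit_entrainment_lme(tab)
        g = (tab.group == "CHH").astype(float)
        X = np.column_stack([np.ones(len(tab)), g, tab.time_ms,
                             g * tab.time_ms])
        ols = sm.OLS(tab.relative_power, X).fit()
        assert np.allclose(fit.params.to_numpy(), ols.params, atol=1e-6)

    def test_group_slope_difference_recovered(self):
        """Planted CHH-minus-CNH slope: sign and magnitude, 12 reps."""
        ests = []
        for rep in range(12):
            spec = simulate.CohortSpec(23, 17, seed=900 + rep)
            truths, _ = simulate.draw_subject_truths(spec, seed=900 + rep)
            tab = simulate.simulate_envelope_table(truths, seed=1900 + rep)
            ests.append(fit_entrainment_lme(tab).interaction)
        ests = np.array(ests)
        assert np.all(ests > 0)
        assert ests.mean() * 1000 == pytest.approx(1.055, rel=0.25)

    def test_unknown_group_label_raises(self):
        tab = self.noiseless_table()
        tab.loc[0, "group"] = "XX"
        with pytest.raises(ValueError):
            fit_entrainment_lme(tab)

    def test_single_subject_group_raises(self):
        tab = self.noiseless_table()
        tab = tab[tab.subject_id != "a"]
        with pytest.raises(ValueError, match="2 subjects"):
            fit_entrainment_lme(tab)


class TestPartialCorrelation:
    def test_control_orthogonal_to_both(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        z = np.array([1.0, -1.0, -1.0, 1.0])
        r, df, p = partial_correlation(x, x.copy(), z)
        assert r == pytest.approx(1.0)
        assert df == 1

    def test_equals_simple_correlation_when_control_orthogonal(self, rng):
        n = 60
        x = rng.standard_normal(n)
        y = 0.5 * x + rng.standard_normal(n)
        z = rng.standard_normal(n)
        z -= np.polyval(np.polyfit(x, z, 1), x) * 0  # keep raw z
        r_simple = np.corrcoef(x, y)[0, 1]
        r_part, _, _ = partial_correlation(x, y, z)
        # z is (nearly) independent of both: r_partial ≈ r_simple
        assert r_part == pytest.approx(r_simple, abs=0.06)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        n = 40
        z = rng.standard_normal(n)
        x = z + rng.standard_normal(n)
        y = -0.5 * z + rng.standard_normal(n)
        r, df, p = partial_correlation(x, y, z)
        out = pingouin.partial_corr(
            pd.DataFrame({"x": x, "y": y, "z": z}), x="x", y="y",
            covar="z")
        assert r == pytest.approx(float(out["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(out["p_val"].iloc[0]), abs=1e-10)

    def test_pure_confound_removed(self, rng):
        """Voxel driven only by BEPTA: partial r with use ≈ 0."""
        n = 200
        bepta = rng.uniform(24, 76, n)
        use = 1.1 * bepta + 20 * rng.standard_normal(n)
        voxel = 0.05 * bepta
        r, _, _ = partial_correlation(use, voxel, bepta)
        assert abs(r) < 0.1

    def test_zero_variance_control_raises(self):
        with pytest.raises(ValueError):
            partial_correlation(np.arange(5.0), np.arange(5.0), np.ones(5))


@pytest.fixture(scope="module")
def grid():
    return build_grid(HeadModel(), spacing=0.012)


class TestWholeBrainMapping:

    def test_detects_planted_negative_cluster(self, grid):
        hits = 0
        for seed in range(10):
            spec = simulate.CohortSpec(2, 17, seed=seed)
            truths, _ = simulate.draw_subject_truths(spec, seed=seed)
            chh = [t for t in truths if t.group == "CHH"]
            imgs = simulate.simulate_source_images(chh, grid,
                                                   seed=seed + 100)
            res = whole_brain_partial_correlation(
                imgs, np.array([t.ha_use for t in chh]),
                np.array([t.bepta for t in chh]), grid)
            v_aud = grid.nearest_voxel(simulate.AUDITORY_LOC)
            neg = [c for c in res.clusters if c.sign < 0]
            hits += any(v_aud in c.voxels for c in neg)
        assert hits >= 8

    def test_cluster_contract(self, grid):
        spec = simulate.CohortSpec(2, 17, seed=3)
        truths, _ = simulate.draw_subject_truths(spec, seed=3)
        chh = [t for t in truths if t.group == "CHH"]
        imgs = simulate.simulate_source_images(chh, grid, seed=103)
        res = whole_brain_partial_correlation(
            imgs, np.array([t.ha_use for t in chh]),
            np.array([t.bepta for t in chh]), grid, k=5)
        assert res.df == len(chh) - 3
        for cl in res.clusters:
            assert len(cl.voxels) >= 5
            assert cl.peak_voxel in cl.voxels
            assert cl.peak_r == res.r[cl.peak_voxel]
            assert np.all(res.p[cl.voxels] < 0.001)

    def test_no_clusters_without_coupling(self, grid):
        eff = simulate.EffectConfig(crossmodal_a1=0.0)
        false_hits = 0
        for seed in range(10):
            spec = simulate.CohortSpec(2, 17, seed=700 + seed)
            truths, _ = simulate.draw_subject_truths(spec, eff,
                                                     seed=700 + seed)
            chh = [t for t in truths if t.group == "CHH"]
            imgs = simulate.simulate_source_images(chh, grid,
                                                   seed=800 + seed)
            res = whole_brain_partial_correlation(
                imgs, np.array([t.ha_use for t in chh]),
                np.array([t.bepta for t in chh]), grid)
            false_hits += bool(res.clusters)
        assert false_hits <= 1

    def test_too_few_subjects_raise(self, grid, rng):
        with pytest.raises(ValueError):
            whole_brain_partial_correlation(
                rng.standard_normal((4, grid.n_voxels)),
                np.arange(4.0), np.arange(4.0) + 1, grid)


class TestPeakBehavior:
    def test_perfect_correlation(self):
        v = np.array([1.0, 2.0, 3.0, 5.0])
        r, df, p = peak_behavior_correlation(v, v * 2 + 1)
        assert r == pytest.approx(1.0)
        assert df == 2

    def test_independent_samples_near_zero(self, rng):
        r, _, _ = peak_behavior_correlation(rng.standard_normal(1000),
                                            rng.standard_normal(1000))
        assert abs(r) < 0.1

    def test_verbal_coupling_recovered_negative(self):
        signs = []
        for seed in range(10):
            spec = simulate.CohortSpec(2, 17, seed=seed)
            truths, _ = simulate.draw_subject_truths(spec, seed=seed)
            chh = [t for t in truths if t.group == "CHH"]
            r, _, _ = peak_behavior_correlation(
                [t.parietal_gain for t in chh],
                [t.verbal_score for t in chh])
            signs.append(r < 0)
        assert sum(signs) >= 9

    def test_too_few_pairs_raise(self):
        with pytest.raises(ValueError):
            peak_behavior_correlation([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestDemographics:
    def test_sex_chi_square_reproduced(self):
        chi2, dof, p = chi_square_independence(datasets.sex_table().values)
        assert round(chi2, 3) == 0.001
        assert p == pytest.approx(0.973, abs=5e-4)

    def test_handedness_chi_square_reproduced(self):
        chi2, _, p = chi_square_independence(
            datasets.handedness_table().values)
        assert round(chi2, 3) == 1.687
        assert p == pytest.approx(0.194, abs=5e-4)

    def test_category_fluency_t_zero(self):
        s = datasets.cohort_summary().loc["dkefs_category_fluency"]
        t, df, p = pooled_t_from_summary(
            s.cnh_mean, s.cnh_sd, int(s.cnh_n),
            s.chh_mean, s.chh_sd, int(s.chh_n))
        assert round(abs(t), 3) == 0.000
        assert p == pytest.approx(1.0)

    def test_identical_group_means_give_zero_t(self):
        t, _, _ = pooled_t_from_summary(5.0, 1.0, 10, 5.0, 2.0, 12)
        assert t == 0.0

    def test_empty_category_raises(self):
        with pytest.raises(ValueError):
            chi_square_independence([[0, 0], [3, 4]])

    def test_comparison_table_from_records(self):
        spec = simulate.CohortSpec(23, 17, seed=0)
        _, cov = simulate.draw_subject_truths(spec, seed=0)
        out = demographic_comparison(cov)
        assert set(out.variable) >= {"age", "verbal_score", "sex",
                                     "handedness"}
        assert out.p_value.between(0, 1).all()
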