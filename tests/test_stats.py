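import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from periwater import (
    CohortDesign,
    adjusted_regression,
    fit_cross_sectional_lmm,
    fit_longitudinal_lmm,
    lesion_volume_change,
    one_sample_t,
    power_one_sample_t,
    simulate_cohort,
    simulate_measures,
    spearman,
    ttest_table,
    zscore_within_group,
)
from periwater.stats import (
    DegenerateDataError,
    RankDeficiencyError,
    average_measures,
)


@pytest.fixture(scope="module")
def merged_cohort():
    design = CohortDesign(seed=0)
    measures = simulate_measures(design)
    subjects = simulate_cohort(design).subject_table
    return measures.merge(subjects, on=["subject_id", "timepoint"], how="left")


class TestOneSampleT:
    def test_hand_calculation(self):
        """(1,2,3): mean 2, sd 1, se 1/sqrt(3) -> t = 3.464, d = 2."""
        r = one_sample_t([1.0, 2.0, 3.0])
        assert r.mean_pct == pytest.approx(200.0)
        assert r.t_stat == pytest.approx(2 * np.sqrt(3), abs=1e-9)
        assert r.cohens_d == pytest.approx(2.0)
        assert r.dof == 2
        # identity t = d * sqrt(n) and CI contains the mean
        assert r.t_stat == pytest.approx(r.cohens_d * np.sqrt(r.n))
        assert r.ci95[0] < r.mean_pct < r.ci95[1]

    def test_symmetric_values_null(self):
        r = one_sample_t([-2.0, -1.0, 1.0, 2.0])
        assert r.t_stat == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegenerateDataError, match="variance"):
            one_sample_t([1.5, 1.5, 1.5])

    def test_too_few_values(self):
        with pytest.raises(DegenerateDataError):
            one_sample_t([1.0])

    def test_simulated_effect_recovery(self):
        """Cohort lesion means recover the configured +0.41 across replicates."""
        means = []
        for rep in range(40):
            df = simulate_measures(CohortDesign(seed=3000 + rep))
            vals = df[(df.location == "lesion") & (df.measure == "fw")
                      & (df.timepoint == "TP1")].normalized
            means.append(vals.mean())
        mc_se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert np.mean(means) == pytest.approx(0.41, abs=3 * mc_se)

    def test_table_covers_all_cells(self, merged_cohort):
        tab = ttest_table(merged_cohort)
        assert len(tab) == 4 * 9 * 2  # timepoints x locations x measures
        assert (tab.dof == tab.n - 1).all()


class TestZScoreWithinGroup:
    def test_single_group(self):
        np.testing.assert_allclose(
            zscore_within_group([3.0, 4.0, 5.0], ["a"] * 3), [-1.0, 0.0, 1.0]
        )

    def test_constant_group_maps_to_zero(self):
        np.testing.assert_array_equal(
            zscore_within_group([2.0, 2.0], ["a", "a"]), [0.0, 0.0]
        )

    def test_two_groups_match_per_group_brute_force(self, rng):
        x = rng.normal(size=20)
        g = np.array(["a"] * 12 + ["b"] * 8)
        z = zscore_within_group(x, g)
        for grp in ("a", "b"):
            sel = g == grp
            expected = (x[sel] - x[sel].mean()) / x[sel].std(ddof=1)
            np.testing.assert_allclose(z[sel], expected, atol=1e-12)
            assert z[sel].mean() == pytest.approx(0.0, abs=1e-12)


class TestLongitudinalLmm:
    def test_study_structure_recovered(self, merged_cohort):
        res = fit_longitudinal_lmm(merged_cohort, "fw")
        assert res.omnibus_dof == 3
        assert res.omnibus_p < 1e-6
        assert len(res.contrasts) == 6  # C(4,2) pairwise timepoint contrasts
        assert res.r2_marginal <= res.r2_conditional <= 1.0
        assert set(res.vc) == {"subject", "location"}
        # dummy coding against the first visit: estimates increase with time
        est = res.contrasts.set_index("contrast")["estimate"]
        assert est["TP4 - TP1"] > est["TP3 - TP1"] > est["TP2 - TP1"]

    def test_intercept_only_variance_partition(self):
        """With no fixed effects but real subject heterogeneity, marginal R^2
        is near zero while conditional R^2 is substantial."""
        design = CohortDesign(
            seed=21,
            between_subject_sd={"fw": 0.4, "fat": 0.1},
            within_subject_sd={"fw": 0.05, "fat": 0.02},
        )
        df = simulate_measures(design, null=True)
        subj = simulate_cohort(design).subject_table
        merged = df.merge(subj, on=["subject_id", "timepoint"], how="left")
        res = fit_longitudinal_lmm(merged, "fw")
        assert res.r2_marginal < 0.05
        assert res.r2_conditional > 0.5

    def test_lrt_omnibus_available(self, merged_cohort):
        res = fit_longitudinal_lmm(merged_cohort, "fw", omnibus="lrt")
        assert res.omnibus_p < 1e-6
        assert res.omnibus_chi2 > 0

    def test_preconditions(self, merged_cohort):
        single_tp = merged_cohort[merged_cohort.timepoint == "TP1"]
        with pytest.raises(DegenerateDataError, match="timepoints"):
            fit_longitudinal_lmm(single_tp, "fw")
        single_loc = merged_cohort[merged_cohort.location == "lesion"]
        with pytest.raises(DegenerateDataError, match="locations"):
            fit_longitudinal_lmm(single_loc, "fw")


class TestCrossSectionalLmm:
    def test_lesion_vs_farthest_shell_contrast_largest(self, merged_cohort):
        """With a decaying effect profile the largest location contrast is
        the farthest shell against the lesion."""
        res = fit_cross_sectional_lmm(merged_cohort, "TP1", "fw")
        mags = res.contrasts.set_index("contrast")["estimate"].abs()
        assert mags.idxmax() == "16mm - lesion"
        assert res.omnibus_p < 1e-6

    def test_single_location_rejected(self, merged_cohort):
        only_lesion = merged_cohort[merged_cohort.location == "lesion"]
        with pytest.raises(DegenerateDataError, match="locations"):
            fit_cross_sectional_lmm(only_lesion, "TP1", "fw")


class TestSpearman:
    def test_monotone_limits(self):
        x = np.arange(8.0)
        rho, p = spearman(x, x**3 + 2)
        assert rho == pytest.approx(1.0)
        rho, _ = spearman(x, -np.exp(x))
        assert rho == pytest.approx(-1.0)

    def test_rank_formula_and_exact_permutation_oracle(self, rng):
        """n=5: rho equals the centered-rank formula; p equals explicit
        enumeration over all 120 pairings."""
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        rho, p = spearman(x, y)
        rx = sps.rankdata(x) - 3.0
        ry = sps.rankdata(y) - 3.0
        rho_oracle = (rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum())
        assert rho == pytest.approx(rho_oracle, abs=1e-12)
        count = 0
        total = 0
        for perm in itertools.permutations(range(5)):
            r = (rx * ry[list(perm)]).sum() / np.sqrt(
                (rx**2).sum() * (ry**2).sum()
            )
            count += abs(r) >= abs(rho) - 1e-12
            total += 1
        assert p == pytest.approx(count / total, abs=1e-12)

    def test_ties_use_midranks(self, rng):
        x = np.array([1.0, 1.0, 2.0, 3.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0])
        y = rng.normal(size=12)
        rho, _ = spearman(x, y)
        ref = sps.spearmanr(x, y).statistic
        assert rho == pytest.approx(ref, abs=1e-12)

    def test_constant_vector_missing_sentinel(self, caplog):
        with caplog.at_level("WARNING", logger="periwater.stats"):
            rho, p = spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert np.isnan(rho) and np.isnan(p)


class TestLesionVolumeChange:
    def test_halving_and_identity(self):
        out = lesion_volume_change({"TP1": 10.0, "TP2": 5.0, "TP3": 10.0})
        assert out["TP2"] == pytest.approx(-0.5)
        assert out["TP3"] == pytest.approx(0.0)

    def test_missing_timepoint_is_nan(self):
        out = lesion_volume_change({"TP1": 10.0, "TP3": np.nan})
        assert np.isnan(out["TP3"])

    def test_missing_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            lesion_volume_change({"TP2": 5.0})

    def test_cohort_shrinkage_contract(self):
        """The generated cohort's negative-change fraction matches design."""
        cohort = simulate_cohort(CohortDesign(seed=8))
        piv = cohort.subject_table.pivot_table(
            index="subject_id", columns="timepoint", values="lesion_volume_ml"
        ).dropna(subset=["TP1", "TP3"])
        changes = [
            lesion_volume_change({"TP1": r.TP1, "TP3": r.TP3})["TP3"]
            for r in piv.itertuples()
        ]
        frac = np.mean(np.array(changes) < 0)
        assert frac == round(0.72 * len(piv)) / len(piv)


class TestAdjustedRegression:
    def test_orthogonal_predictor_equals_unadjusted_slope(self, rng):
        """Frisch-Waugh: with predictor orthogonal to the covariates the
        adjusted coefficient equals the simple regression slope."""
        n = 60
        cov1 = np.repeat([1.0, -1.0], n // 2)  # centered, orthogonal by design
        pred = np.tile([1.0, -1.0], n // 2)
        y = 2.5 * pred + 0.8 * cov1 + rng.normal(0, 0.5, n)
        df = pd.DataFrame({"y": y, "pred": pred, "c1": cov1})
        got = adjusted_regression(df, "y", "pred", covariates=("c1",))
        slope = np.polyfit(pred, y, 1)[0]
        assert got.loc["pred", "estimate"] == pytest.approx(slope, abs=1e-10)

    def test_duplicated_covariate_named(self, rng):
        n = 30
        x = rng.normal(size=n)
        df = pd.DataFrame({"y": rng.normal(size=n), "pred": x, "c1": x})
        with pytest.raises(RankDeficiencyError) as exc:
            adjusted_regression(df, "y", "pred", covariates=("c1",))
        assert "c1" in exc.value.columns

    def test_confounded_recovery(self, rng):
        """Coefficient recovery under confounding, within Monte-Carlo CI."""
        ests = []
        for rep in range(30):
            r = np.random.default_rng(rep)
            n = 80
            conf = r.normal(size=n)
            pred = 0.7 * conf + r.normal(size=n)
            y = 1.5 * pred + 2.0 * conf + r.normal(0, 1.0, n)
            df = pd.DataFrame({"y": y, "pred": pred, "conf": conf})
            got = adjusted_regression(df, "y", "pred", covariates=("conf",))
            ests.append(got.loc["pred", "estimate"])
        se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert np.mean(ests) == pytest.approx(1.5, abs=3 * se)

    def test_small_n_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0], "pred": [1.0, 2.0, 3.0]})
        with pytest.raises(DegenerateDataError):
            adjusted_regression(df, "y", "pred", covariates=())


class TestPower:
    def test_null_effect_gives_alpha(self):
        assert power_one_sample_t(0.0, 26, 0.05) == pytest.approx(0.05, abs=1e-10)

    def test_matches_numerical_integration(self):
        """d=0.5, n=26: power equals chi-square mixture quadrature to 1e-4."""
        d, n, alpha = 0.5, 26, 0.05
        dof = n - 1
        ncp = d * np.sqrt(n)
        tcrit = sps.t.ppf(1 - alpha / 2, dof)
        # independent oracle: integrate P(|T| > tcrit | V=v) over the
        # chi-square density of V, with T | V ~ N(ncp, 1) / sqrt(v / dof)
        from scipy.integrate import quad

        def integrand(v):
            s = np.sqrt(v / dof)
            upper = 1 - sps.norm.cdf(tcrit * s - ncp)
            lower = sps.norm.cdf(-tcrit * s - ncp)
            return (upper + lower) * sps.chi2.pdf(v, dof)

        oracle, _ = quad(integrand, 0, dof * 12, limit=200)
        assert power_one_sample_t(d, n, alpha) == pytest.approx(oracle, abs=1e-4)

    def test_monotone_in_n_and_effect(self):
        p1 = [power_one_sample_t(0.5, n) for n in (5, 10, 20, 40)]
        assert all(a < b for a, b in zip(p1, p1[1:]))
        p2 = [power_one_sample_t(d, 20) for d in (0.1, 0.3, 0.6, 1.0)]
        assert all(a < b for a, b in zip(p2, p2[1:]))

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            power_one_sample_t(0.5, 1)
        with pytest.raises(ValueError):
            power_one_sample_t(0.5, 10, alpha=1.5)


class TestAverageMeasures:
    def test_shell_summary_is_unweighted_mean(self, merged_cohort):
        out = average_measures(merged_cohort, rois="shells", measure="fw")
        row = out.iloc[0]
        manual = merged_cohort[
            (merged_cohort.subject_id == row.subject_id)
            & (merged_cohort.timepoint == row.timepoint)
            & (merged_cohort.measure == "fw")
            & (merged_cohort.location != "lesion")
        ].normalized.mean()
        assert row.fw_shells == pytest.approx(manual, abs=1e-12)
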