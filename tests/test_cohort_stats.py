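import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hipmorph.cohort_stats import (
    _tstat_pooled,
    select_limbs,
    spm_ttest,
    volume_regression,
)
from hipmorph.phantom import CohortSpec, MFIProfile, generate_cohort, \
    simulate_profile_group


def toy_cohort(n_symp=10, n_ctrl=10, kick_match=0.6, seed=0):
    """Cohort where a fixed fraction of symptomatic limbs are kicking limbs."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_symp):
        kick = "R"
        symp = "R" if i < round(kick_match * n_symp) else "L"
        rows.append({"group": "symptomatic", "sex": "M", "kicking_limb": kick,
                     "symptomatic_limb": symp})
    for _ in range(n_ctrl):
        rows.append({"group": "control", "sex": "M",
                     "kicking_limb": rng.choice(["L", "R"]),
                     "symptomatic_limb": None})
    return pd.DataFrame(rows)


class TestSelectLimbs:
    def test_exact_integer_match(self):
        """60% of symptomatic limbs are kicking limbs; 10 male controls get
        exactly 6 kicking-limb assignments."""
        df = select_limbs(toy_cohort(), seed=1)
        ctrl = df[df["group"] == "control"]
        n_kick = (ctrl["selected_limb"] == ctrl["kicking_limb"]).sum()
        assert n_kick == 6

    def test_symptomatic_rows_untouched(self):
        base = toy_cohort()
        df = select_limbs(base, seed=2)
        symp = df[df["group"] == "symptomatic"]
        assert (symp["selected_limb"] == symp["symptomatic_limb"]).all()
        pd.testing.assert_frame_equal(
            df[base.columns][df["group"] == "symptomatic"],
            base[base["group"] == "symptomatic"],
        )

    def test_same_seed_identical(self):
        a = select_limbs(toy_cohort(), seed=3)
        b = select_limbs(toy_cohort(), seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_stratum_proportions_within_one_person_over_seeds(self):
        """Sex-stratified control proportions never deviate from the
        symptomatic stratum target by one person or more (100 reseedings of a
        full synthetic cohort)."""
        cohort = generate_cohort(CohortSpec(seed=5))
        symp = cohort[cohort["group"] == "symptomatic"]
        targets = {
            sex: (g["symptomatic_limb"] == g["kicking_limb"]).mean()
            for sex, g in symp.groupby("sex")
        }
        for seed in range(100):
            out = select_limbs(cohort, seed=seed)
            ctrl = out[out["group"] == "control"]
            for sex, g in ctrl.groupby("sex"):
                n_kick = (g["selected_limb"] == g["kicking_limb"]).sum()
                assert abs(n_kick - targets[sex] * len(g)) < 1.0

    def test_missing_stratum_falls_back_to_overall(self, caplog):
        df = toy_cohort()
        df.loc[df["group"] == "control", "sex"] = "F"  # no symptomatic females
        with caplog.at_level("WARNING", logger="hipmorph.cohort_stats"):
            out = select_limbs(df, seed=1)
        assert out["selected_limb"].notna().all()
        assert any("absent in symptomatic" in r.message for r in caplog.records)

    def test_exactly_one_selected_limb_per_participant(self):
        out = select_limbs(toy_cohort(), seed=4)
        assert out["selected_limb"].isin(["L", "R"]).all()


class TestSPM:
    def test_duplicated_groups_give_zero_t_no_clusters(self):
        prof = simulate_profile_group(MFIProfile("constant", (0.3,)), 8, 0.02, seed=1)
        res = spm_ttest(prof, prof.copy(), n_perm=200, seed=0)
        np.testing.assert_allclose(res.t, 0.0, atol=1e-12)
        assert res.clusters == [] and not res.significant

    def test_single_node_matches_hand_t(self, rng):
        """Node-wise t equals the classic pooled two-sample t computed from
        the textbook formula on that node's values."""
        xa = rng.normal(0.3, 0.05, (7, 101))
        xb = rng.normal(0.32, 0.05, (9, 101))
        t = _tstat_pooled(xa, xb)
        k = 40
        a, b = xa[:, k], xb[:, k]
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
            len(a) + len(b) - 2
        )
        hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        assert t[k] == pytest.approx(hand, rel=1e-12)
        # and the scipy implementation agrees
        assert t[k] == pytest.approx(
            stats.ttest_ind(a, b, equal_var=True).statistic, rel=1e-12
        )

    def test_zero_variance_node_flagged_excluded(self):
        xa = np.tile(np.linspace(0.2, 0.4, 101), (5, 1))
        xb = xa.copy()
        rng = np.random.default_rng(0)
        xa = xa + rng.normal(0, 0.01, xa.shape)
        xb = xb + rng.normal(0, 0.01, xb.shape)
        xa[:, 50] = 0.3
        xb[:, 50] = 0.3  # identical constant node -> zero pooled variance
        res = spm_ttest(xa, xb, n_perm=200, seed=1)
        assert np.isnan(res.t[50])
        assert np.isfinite(res.t_crit)

    def test_permutation_threshold_bounded(self):
        """t* sits between the uncorrected two-sided critical value and the
        Bonferroni value across 101 nodes, over several simulated datasets."""
        base = MFIProfile("constant", (0.3,))
        for seed in range(5):
            xa = simulate_profile_group(base, 15, 0.03, seed=seed)
            xb = simulate_profile_group(base, 15, 0.03, seed=seed + 100)
            res = spm_ttest(xa, xb, n_perm=1000, seed=seed)
            dof = 28
            lo = stats.t.ppf(1 - 0.025, dof)
            hi = stats.t.ppf(1 - 0.025 / 101, dof)
            assert lo <= res.t_crit <= hi

    def test_rft_threshold_bounded_and_detects_large_effect(self):
        base = MFIProfile("constant", (0.3,))
        xa = simulate_profile_group(base, 20, 0.03, seed=0, effect=0.08)
        xb = simulate_profile_group(base, 20, 0.03, seed=1)
        res = spm_ttest(xa, xb, method="rft")
        dof = 38
        assert stats.t.ppf(0.975, dof) <= res.t_crit
        assert res.t_crit <= stats.t.ppf(1 - 0.025 / 101, dof)
        assert res.significant  # a 0.08 shift at noise 0.03 is a huge effect
        assert res.fwhm is not None and res.fwhm > 0

    def test_seeded_permutation_reproducible(self):
        base = MFIProfile("constant", (0.3,))
        xa = simulate_profile_group(base, 10, 0.03, seed=2)
        xb = simulate_profile_group(base, 10, 0.03, seed=3)
        r1 = spm_ttest(xa, xb, n_perm=500, seed=7)
        r2 = spm_ttest(xa, xb, n_perm=500, seed=7)
        assert r1.t_crit == r2.t_crit

    def test_preconditions(self):
        prof = np.zeros((1, 101))
        with pytest.raises(ValueError):
            spm_ttest(prof, prof)
        with pytest.raises(ValueError):
            spm_ttest(np.zeros((3, 50)), np.zeros((3, 50)))


class TestVolumeRegression:
    def test_recovers_known_effect_without_confounding(self):
        """Known 20 000 mm^3 effect, no covariate effects, n=500, noise SD
        10 000: mean estimate over 30 replicates within +/- 1000 of truth."""
        from hipmorph.phantom import MuscleEffect

        muscles = {"Gmed": MuscleEffect(
            baseline_mm3=300_000, group_effect_mm3=20_000,
            noise_sd_mm3=10_000,
        )}
        ests = []
        for rep in range(30):
            spec = CohortSpec(n_symptomatic=250, n_control=250,
                              muscles=dict(muscles), seed=900 + rep)
            df = generate_cohort(spec)
            ests.append(volume_regression(df, "Gmed").adjusted_difference_mm3)
        assert abs(np.mean(ests) - 20_000) < 1000

    def test_interaction_dropped_iff_p_above_threshold(self):
        df = generate_cohort(CohortSpec(seed=3))
        res = volume_regression(df, "Gmed")
        assert res.interaction_p is not None
        assert res.interaction_retained == (res.interaction_p <= 0.05)

    def test_ci_contains_point_estimate(self):
        df = generate_cohort(CohortSpec(seed=4))
        res = volume_regression(df, "TFL")
        assert res.ci_low <= res.adjusted_difference_mm3 <= res.ci_high
        assert res.n_symptomatic == 180 and res.n_control == 48

    def test_invariant_to_covariate_rescaling(self):
        df = generate_cohort(CohortSpec(seed=5))
        res1 = volume_regression(df, "Gmed")
        df2 = df.copy()
        df2["age"] = df2["age"] * 12.0  # months
        df2["bmi"] = df2["bmi"] / 10.0 + 3.0
        res2 = volume_regression(df2, "Gmed")
        assert res2.adjusted_difference_mm3 == pytest.approx(
            res1.adjusted_difference_mm3, rel=1e-9
        )

    def test_percent_difference_uses_adjusted_control_mean(self):
        df = generate_cohort(CohortSpec(seed=6))
        res = volume_regression(df, "Gmed")
        assert res.percent_difference == pytest.approx(
            100 * res.adjusted_difference_mm3 / res.adjusted_control_mean_mm3
        )

    def test_collinear_covariates_named(self):
        df = generate_cohort(CohortSpec(seed=7))
        df["bmi"] = 2.0 * df["age"] + 1.0
        with pytest.raises(ValueError, match="collinear"):
            volume_regression(df, "Gmed")

    def test_single_sex_skips_interaction(self, caplog):
        df = generate_cohort(CohortSpec(seed=8))
        df["sex"] = "M"
        with caplog.at_level("WARNING", logger="hipmorph.cohort_stats"):
            res = volume_regression(df, "Gmed")
        assert res.interaction_p is None and not res.interaction_retained
        assert any("single-sex" in r.message for r in caplog.records)

    def test_preconditions(self):
        df = generate_cohort(CohortSpec(seed=9)).head(5)
        with pytest.raises(ValueError):
            volume_regression(df, "Gmed")
        df2 = generate_cohort(CohortSpec(seed=9))
        df2["group"] = "symptomatic"
        with pytest.raises(ValueError):
            volume_regression(df2, "Gmed")
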