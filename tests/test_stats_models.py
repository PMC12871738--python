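"""Weighted nested mixed models, hormone decomposition, EMMs, and GVIFs."""

import numpy as np
import pandas as pd
import pytest

from mudra import stats_models as sm
from mudra import synthetic_data as sd


def simulate_rows(seed=0, n_participants=15, n_trials=4, n_units=6):
    """Small two-level dataset with known fixed effects for solver checks."""
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_participants):
        u_p = rng.normal(0, 1.0)
        for t in range(n_trials):
            v_t = rng.normal(0, 0.7)
            for _ in range(n_units):
                x1, x2 = rng.normal(size=2)
                y = 2.0 + 0.5 * x1 - 0.3 * x2 + u_p + v_t + rng.normal(0, 1.2)
                rows.append((f"P{p}", f"P{p}_t{t}", x1, x2, y))
    return pd.DataFrame(rows, columns=["participant_id", "trial_id", "x1", "x2", "y"])


def fit(df, weights, reml=True):
    X = np.column_stack([np.ones(len(df)), df["x1"], df["x2"]])
    return sm.fit_weighted_lmm(
        X,
        df["y"].to_numpy(),
        weights,
        df["participant_id"].to_numpy(),
        df["trial_id"].to_numpy(),
        names=["Intercept", "x1", "x2"],
        reml=reml,
    )


class TestSolver:
    @pytest.mark.parametrize("reml", [True, False], ids=["reml", "ml"])
    def test_agrees_with_statsmodels_at_unit_weights(self, reml):
        smf = pytest.importorskip("statsmodels.formula.api")
        df = simulate_rows()
        ours = fit(df, np.ones(len(df)), reml=reml)
        ref = smf.mixedlm(
            "y ~ x1 + x2",
            df,
            groups="participant_id",
            re_formula="1",
            vc_formula={"trial_id": "0 + C(trial_id)"},
        ).fit(reml=reml)
        np.testing.assert_allclose(ours.beta, ref.params[:3].to_numpy(), atol=1e-4)
        np.testing.assert_allclose(ours.se, ref.bse[:3].to_numpy(), atol=1e-4)
        assert ours.var_participant == pytest.approx(ref.cov_re.values[0, 0], abs=1e-3)
        assert ours.var_trial == pytest.approx(float(ref.vcomp[0]), abs=1e-3)
        assert ours.var_residual == pytest.approx(ref.scale, abs=1e-3)

    def test_constant_weights_equal_unweighted_fit(self):
        df = simulate_rows(seed=1)
        a = fit(df, np.ones(len(df)))
        b = fit(df, np.full(len(df), 7.0))
        assert np.abs(a.beta - b.beta).max() < 1e-6
        assert np.abs(a.se - b.se).max() < 1e-6
        assert a.var_residual == pytest.approx(b.var_residual, rel=1e-4)

    def test_weights_change_the_fit(self):
        df = simulate_rows(seed=2)
        rng = np.random.default_rng(3)
        w = rng.integers(1, 10, size=len(df)).astype(float)
        a = fit(df, np.ones(len(df)))
        b = fit(df, w)
        assert np.abs(a.beta - b.beta).max() > 1e-4

    def test_rank_deficient_design_raises(self):
        df = simulate_rows(seed=4)
        X = np.column_stack([np.ones(len(df)), df["x1"], df["x1"]])
        with pytest.raises(sm.RankDeficiencyError):
            sm.fit_weighted_lmm(
                X,
                df["y"].to_numpy(),
                np.ones(len(df)),
                df["participant_id"].to_numpy(),
                df["trial_id"].to_numpy(),
            )

    def test_lrt_requires_ml_fits(self):
        df = simulate_rows(seed=5)
        a = fit(df, np.ones(len(df)), reml=True)
        with pytest.raises(ValueError, match="ML"):
            sm.likelihood_ratio_test(a, a)


class TestHormoneDecomposition:
    def panel(self, e2, p4, pid="P1"):
        return pd.DataFrame(
            {
                "participant_id": pid,
                "phase": ["EF", "LF", "ML"],
                "e2": e2,
                "p4": p4,
            }
        )

    def test_mean_and_centering_arithmetic(self):
        panel = self.panel(np.exp([1.0, 2.0, 3.0]), [1.0, 1.0, 1.0])
        out = sm.decompose_hormones(panel)
        assert out["e2_mean"].iloc[0] == pytest.approx(2.0)
        np.testing.assert_allclose(out["e2_within"], [-1.0, 0.0, 1.0], atol=1e-12)

    def test_identical_values_center_to_zero(self):
        out = sm.decompose_hormones(self.panel([0.5] * 3, [5.0] * 3))
        np.testing.assert_allclose(out["e2_within"], 0.0, atol=1e-12)

    def test_reconstruction_and_sum_to_zero(self, cohort_small):
        df, _ = cohort_small
        panel = df.drop_duplicates(["participant_id", "phase"])[
            ["participant_id", "phase", "e2", "p4"]
        ]
        out = sm.decompose_hormones(panel)
        np.testing.assert_allclose(
            out["p4_mean"] + out["p4_within"], np.log(out["p4"]), atol=1e-12
        )
        sums = out.groupby("participant_id")["p4_within"].sum()
        np.testing.assert_allclose(sums, 0.0, atol=1e-12)

    def test_nonpositive_hormone_names_participant(self):
        with pytest.raises(ValueError, match="P9"):
            sm.decompose_hormones(self.panel([0.5, -0.1, 0.5], [1, 1, 1], pid="P9"))

    def test_decomposition_identities_hold_for_arbitrary_panels(self):
        from hypothesis import given, settings, strategies as st

        positive = st.floats(min_value=1e-3, max_value=1e3)

        @settings(derandomize=True, deadline=None, max_examples=50)
        @given(e2=st.tuples(positive, positive, positive),
               p4=st.tuples(positive, positive, positive))
        def check(e2, p4):
            out = sm.decompose_hormones(self.panel(list(e2), list(p4)))
            for h in ("e2", "p4"):
                np.testing.assert_allclose(
                    out[f"{h}_mean"] + out[f"{h}_within"], out[f"log_{h}"], atol=1e-12
                )
                assert abs(out[f"{h}_within"].sum()) < 1e-9

        check()


class TestStandardize:
    def test_zero_mean_unit_sd(self, cohort_small):
        df, _ = cohort_small
        out = sm.standardize_outcomes(df, ["peak_rate", "delta_f"])
        for col in ("peak_rate", "delta_f"):
            assert out[col].mean() == pytest.approx(0.0, abs=1e-9)
            assert out[col].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_constant_outcome_rejected(self):
        df = pd.DataFrame({"y": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="zero variance"):
            sm.standardize_outcomes(df, ["y"])

    def test_zscoring_leaves_t_statistics_unchanged(self, cohort_small):
        df, _ = cohort_small
        raw = sm.fit_phase_model(df, "peak_rate", interaction="never", term_lrts=())
        z = sm.fit_phase_model(
            sm.standardize_outcomes(df, ["peak_rate"]),
            "peak_rate",
            interaction="never",
            term_lrts=(),
        )
        # the intercept moves under centering; all slope/contrast t-statistics
        # are invariant to the affine outcome transform
        keep = [i for i, n in enumerate(raw.fit.names) if n != "Intercept"]
        np.testing.assert_allclose(
            (raw.fit.beta / raw.fit.se)[keep], (z.fit.beta / z.fit.se)[keep], rtol=1e-4
        )


class TestPhaseModelLadder:
    def test_recovers_injected_phase_effect(self, cohort_small):
        df, _ = cohort_small
        eff = sd.CohortEffects(phase={"peak_rate": {"LF": 1.5, "ML": 1.5}})
        df2, _ = sd.simulate_cohort(n_participants=12, effects=eff, seed=6)
        res = sm.fit_phase_model(df2, "peak_rate", interaction="never", term_lrts=("phase",))
        i = res.fit.names.index("phase[T.LF]")
        assert res.fit.beta[i] == pytest.approx(1.5, abs=4 * res.fit.se[i])
        assert res.lrt_terms["phase"][2] < 0.01

    def test_log_transform_requires_positive_outcomes(self, cohort_small):
        df, _ = cohort_small
        df = df.copy()
        df.loc[df.index[0], "accel_slope"] = -1.0
        with pytest.raises(ValueError, match="nonpositive"):
            sm.fit_phase_model(df, "accel_slope", log_outcome=True, interaction="never")

    def test_hormone_model_zero_within_variance_flagged(self, cohort_small):
        df, _ = cohort_small
        panel = df.drop_duplicates(["participant_id", "phase"])[
            ["participant_id", "phase", "e2", "p4"]
        ].copy()
        panel["e2"] = 0.5
        panel["p4"] = 5.0
        dec = sm.decompose_hormones(panel)
        merged = df.merge(
            dec[["participant_id", "phase", "e2_mean", "e2_within", "p4_mean", "p4_within"]],
            on=["participant_id", "phase"],
        )
        with pytest.raises(ValueError, match="inestimable"):
            sm.fit_hormone_model(merged, "peak_rate", interaction="never")

    def test_swapping_within_between_moves_the_recovered_effect(self):
        eff = sd.CohortEffects(hormones={"peak_rate": {"p4_within": 0.8}})
        df, _ = sd.simulate_cohort(n_participants=20, effects=eff, seed=7)
        panel = df.drop_duplicates(["participant_id", "phase"])[
            ["participant_id", "phase", "e2", "p4"]
        ]
        dec = sm.decompose_hormones(panel)
        merged = df.merge(
            dec[["participant_id", "phase", "e2_mean", "e2_within", "p4_mean", "p4_within"]],
            on=["participant_id", "phase"],
        )
        res = sm.fit_hormone_model(merged, "peak_rate", interaction="never")
        i_w = res.fit.names.index("p4_within")
        swapped = merged.rename(
            columns={"p4_within": "p4_mean", "p4_mean": "p4_within"}
        )
        res_sw = sm.fit_hormone_model(swapped, "peak_rate", interaction="never")
        i_m = res_sw.fit.names.index("p4_mean")
        assert res.fit.beta[i_w] == pytest.approx(0.8, abs=0.25)
        assert res_sw.fit.beta[i_m] == pytest.approx(0.8, abs=0.25)


class TestEMMs:
    def balanced_fit(self, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        means = {"EF": 10.0, "LF": 11.0, "ML": 12.5}
        for p in range(8):
            for ph in ("EF", "LF", "ML"):
                for u in range(5):
                    rows.append(
                        {
                            "participant_id": f"P{p}",
                            "trial_id": f"P{p}_{ph}",
                            "phase": ph,
                            "y": means[ph] + rng.normal(0, 1.0),
                        }
                    )
        df = pd.DataFrame(rows)
        spec = sm.ModelSpec("y", factors={"phase": ["EF", "LF", "ML"]})
        X, names, slices = spec.build(df)
        fit = sm.fit_weighted_lmm(
            X,
            df["y"].to_numpy(),
            np.ones(len(df)),
            df["participant_id"].to_numpy(),
            df["trial_id"].to_numpy(),
            names=names,
            term_slices=slices,
        )
        fit.spec, fit.data = spec, df
        return fit, df

    def test_balanced_design_emms_equal_cell_means(self):
        fit, df = self.balanced_fit()
        emm, _ = sm.emm_contrasts(fit, "phase")
        cell = df.groupby("phase")["y"].mean()
        for _, row in emm.iterrows():
            assert row["emmean"] == pytest.approx(cell[row["level"]], abs=1e-6)

    def test_contrast_effect_size_is_estimate_over_total_sd(self):
        fit, _ = self.balanced_fit()
        _, con = sm.emm_contrasts(fit, "phase")
        for _, row in con.iterrows():
            assert row["cohens_d"] == pytest.approx(row["estimate"] / fit.total_sd)

    def test_tukey_p_not_below_unadjusted(self):
        from scipy import stats as sps

        fit, _ = self.balanced_fit()
        _, con = sm.emm_contrasts(fit, "phase")
        for _, row in con.iterrows():
            p_unadj = 2 * sps.norm.sf(abs(row["t"]))
            assert row["p_tukey"] >= p_unadj - 1e-12

    def test_empty_cells_are_reported(self):
        fit, df = self.balanced_fit()
        sub = df[~((df["phase"] == "ML"))].copy()
        spec = sm.ModelSpec("y", factors={"phase": ["EF", "LF", "ML"]})
        fit.data = sub
        fit.spec = spec
        with pytest.raises(ValueError, match="empty design cells"):
            sm.emm_contrasts(fit, "phase")


class TestGVIF:
    def make_X(self, r):
        rng = np.random.default_rng(0)
        n = 4000
        x1 = rng.normal(size=n)
        x2 = r * x1 + np.sqrt(1 - r**2) * rng.normal(size=n)
        X = np.column_stack([np.ones(n), x1, x2])
        names = ["Intercept", "x1", "x2"]
        slices = {"Intercept": [0], "x1": [1], "x2": [2]}
        return X, names, slices

    def test_orthogonal_predictors_give_unit_gvif(self):
        X, names, slices = self.make_X(0.0)
        out = sm.collinearity_diagnostics(X, names, slices)
        assert np.allclose(out["gvif"], 1.0, atol=0.05)

    def test_two_predictor_closed_form(self):
        # VIF = 1 / (1 - r^2) = 2.778 with the sample correlation pinned to 0.8
        rng = np.random.default_rng(0)
        n = 4000
        x1 = rng.normal(size=n)
        x1 = (x1 - x1.mean()) / x1.std()
        z = rng.normal(size=n)
        z = z - z.mean()
        z -= x1 * (x1 @ z) / (x1 @ x1)
        z /= z.std()
        x2 = 0.8 * x1 + np.sqrt(1 - 0.64) * z
        X = np.column_stack([np.ones(n), x1, x2])
        out = sm.collinearity_diagnostics(
            X, ["Intercept", "x1", "x2"], {"Intercept": [0], "x1": [1], "x2": [2]}
        )
        assert out["gvif"].iloc[0] == pytest.approx(1 / (1 - 0.8**2), abs=1e-9)

    def test_duplicated_predictor_flagged_as_collinear(self):
        X, names, slices = self.make_X(0.0)
        X[:, 2] = X[:, 1]
        out = sm.collinearity_diagnostics(X, names, slices)
        assert np.isinf(out["gvif"]).any() or (out["gvif"] > 1e6).any()

    def test_multi_df_terms_scaled_by_degrees_of_freedom(self, cohort_small):
        df, _ = cohort_small
        res = sm.fit_phase_model(df, "peak_rate", interaction="never", term_lrts=())
        out = sm.collinearity_diagnostics(res.fit)
        phase = out.set_index("term").loc["phase"]
        assert phase["df"] == 2
        assert phase["scaled_gvif"] == pytest.approx(phase["gvif"] ** 0.25)
        assert (out["scaled_gvif"] < 2.0).all()
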