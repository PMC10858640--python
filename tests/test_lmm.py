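"""Nested random-intercept model: oracle equivalence, closed forms,
recovery, invariances."""

import numpy as np
import pandas as pd
import pytest

import hfscore as h
from hfscore.lmm import (
    ModelSpec,
    dense_loglik,
    fit_nested_lmm,
    fit_variance_components,
    predict_group_mean,
    profile_loglik,
    wald_contrasts,
)


def _simulate_weekly(
    rng, n_event=20, n_control=30, beta=(30.0, -0.1, 12.0, 0.9),
    sd_p=6.0, sd_a=4.0, sd_e=5.0, two_anchor_fraction=0.3, weeks=13,
):
    """Weekly observations drawn directly from the nested model."""
    rows = []
    b0, b1, b2, b3 = beta
    for i in range(n_event + n_control):
        is_event = i < n_event
        pid = f"P{i:04d}"
        u = rng.normal(0, sd_p)
        n_anchor = (
            2 if (is_event and rng.random() < two_anchor_fraction) else 1
        )
        for a in range(n_anchor):
            v = rng.normal(0, sd_a)
            for w in range(weeks):
                week = w - 12
                t = week + 12.0
                g = 1.0 if is_event else 0.0
                y = b0 + b1 * t + b2 * g + b3 * t * g + u + v + rng.normal(0, sd_e)
                rows.append(
                    {
                        "patient_id": pid,
                        "anchor_id": f"{pid}-A{a}",
                        "group": "event" if is_event else "control",
                        "week": week,
                        "mean_score": y,
                    }
                )
    return pd.DataFrame(rows)


class TestOracleEquivalence:
    def test_profiled_matches_dense_on_small_instances(self):
        """Blockwise profiled REML equals a dense multivariate-normal
        evaluation at the same variance components, to 1e-6."""
        rng = np.random.default_rng(31)
        for trial in range(5):
            n_pat = int(rng.integers(3, 7))
            rows = []
            for i in range(n_pat):
                for a in range(int(rng.integers(1, 3))):
                    for w in range(int(rng.integers(2, 4))):
                        rows.append((f"P{i}", f"P{i}-A{a}", float(w)))
            rows = rows[:50]
            pid = np.array([r[0] for r in rows])
            aid = np.array([r[1] for r in rows])
            t = np.array([r[2] for r in rows])
            X = np.column_stack([np.ones(len(rows)), t])
            y = rng.normal(10 + t, 3.0)
            for gp, ga in [(0.5, 0.2), (2.0, 1.0), (1e-6, 3.0)]:
                ll, beta, sigma2 = profile_loglik(y, X, pid, aid, gp, ga)
                for reml in (True, False):
                    ll_r, _, s2 = profile_loglik(y, X, pid, aid, gp, ga, reml=reml)
                    oracle = dense_loglik(
                        y, X, pid, aid, gp * s2, ga * s2, s2, reml=reml
                    )
                    assert ll_r == pytest.approx(oracle, abs=1e-6)

    def test_fitted_point_is_a_local_optimum(self):
        """No +/-1e-3 perturbation of the variance components improves
        the dense REML likelihood at the fitted point."""
        rng = np.random.default_rng(32)
        obs = _simulate_weekly(rng, n_event=6, n_control=6, weeks=3,
                               sd_p=3.0, sd_a=2.0, sd_e=2.0)
        fit = fit_nested_lmm(obs)
        t = obs["week"].to_numpy() + 12.0
        g = (obs["group"] == "event").to_numpy(float)
        X = np.column_stack([np.ones(len(obs)), t, g, t * g])
        args = (obs["mean_score"].to_numpy(), X,
                obs["patient_id"].to_numpy(), obs["anchor_id"].to_numpy())
        best = dense_loglik(*args, fit.var_patient, fit.var_anchor, fit.var_resid)
        assert best == pytest.approx(fit.loglik, abs=1e-6)
        for i in range(3):
            for eps in (-1e-3, 1e-3):
                vp, va, ve = fit.var_patient, fit.var_anchor, fit.var_resid
                comps = [vp, va, ve]
                comps[i] = max(comps[i] + eps, 1e-12)
                assert dense_loglik(*args, *comps) <= best + 1e-7


class TestClosedForms:
    def test_balanced_nested_anova_estimators(self):
        """On a balanced two-level nested layout with intercept-only fixed
        effects, REML variance components equal the ANOVA mean-square
        estimators."""
        rng = np.random.default_rng(33)
        k, a, m = 8, 3, 4  # patients x anchors x replicates
        sd_p, sd_a, sd_e = 3.0, 2.0, 1.5
        y, pid, aid = [], [], []
        for i in range(k):
            u = rng.normal(0, sd_p)
            for j in range(a):
                v = rng.normal(0, sd_a)
                for r in range(m):
                    y.append(5.0 + u + v + rng.normal(0, sd_e))
                    pid.append(i)
                    aid.append(f"{i}-{j}")
        y = np.array(y)
        df = pd.DataFrame({"y": y, "pid": pid, "aid": aid})
        grand = y.mean()
        pm = df.groupby("pid")["y"].mean()
        am = df.groupby("aid")["y"].mean()
        ss_p = a * m * ((pm - grand) ** 2).sum()
        ss_a = m * ((am - am.groupby(lambda s: int(s.split("-")[0])).transform("mean")) ** 2).sum()
        ss_e = ((df["y"] - df.groupby("aid")["y"].transform("mean")) ** 2).sum()
        ms_p = ss_p / (k - 1)
        ms_a = ss_a / (k * (a - 1))
        ms_e = ss_e / (k * a * (m - 1))
        anova = {
            "resid": ms_e,
            "anchor": (ms_a - ms_e) / m,
            "patient": (ms_p - ms_a) / (a * m),
        }
        fit = fit_variance_components(
            y, np.ones((len(y), 1)), np.array(pid), np.array(aid)
        )
        assert fit.var_resid == pytest.approx(anova["resid"], rel=1e-4)
        assert fit.var_anchor == pytest.approx(anova["anchor"], rel=1e-4)
        assert fit.var_patient == pytest.approx(anova["patient"], rel=1e-4)

    def test_zero_variance_limit_is_ols(self):
        rng = np.random.default_rng(34)
        obs = _simulate_weekly(rng, n_event=5, n_control=5, weeks=4,
                               sd_p=0.0, sd_a=0.0, sd_e=2.0)
        t = obs["week"].to_numpy() + 12.0
        g = (obs["group"] == "event").to_numpy(float)
        X = np.column_stack([np.ones(len(obs)), t, g, t * g])
        y = obs["mean_score"].to_numpy()
        fit = fit_variance_components(
            y, X, obs["patient_id"].to_numpy(), obs["anchor_id"].to_numpy(),
            fixed_gamma=(0.0, 0.0),
        )
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(fit.beta, ols, atol=1e-10)

    def test_noise_free_interpolation(self):
        obs = _simulate_weekly(
            np.random.default_rng(35), n_event=4, n_control=4,
            sd_p=0.0, sd_a=0.0, sd_e=0.0, weeks=5,
        )
        fit = fit_nested_lmm(obs)
        assert np.allclose(fit.beta, [30.0, -0.1, 12.0, 0.9], atol=1e-8)
        assert fit.var_patient == fit.var_anchor == fit.var_resid == 0.0
        assert fit.converged

    def test_constant_response_rejected(self):
        obs = _simulate_weekly(np.random.default_rng(36), 3, 3, weeks=3)
        obs["mean_score"] = 4.2
        with pytest.raises(ValueError, match="constant"):
            fit_nested_lmm(obs)


class TestStatsmodelsCrossCheck:
    def test_against_mixedlm(self):
        """Betas, SEs and variance components agree with an independent
        REML implementation on a moderate nested dataset."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(37)
        obs = _simulate_weekly(rng, n_event=25, n_control=25,
                               two_anchor_fraction=0.5)
        fit = fit_nested_lmm(obs)
        df = obs.assign(
            t=obs["week"] + 12.0, g=(obs["group"] == "event").astype(float)
        )
        md = sm.MixedLM.from_formula(
            "mean_score ~ t * g",
            groups="patient_id",
            re_formula="1",
            vc_formula={"anchor": "0 + C(anchor_id)"},
            data=df,
        )
        res = md.fit(reml=True, method="lbfgs")
        ref = np.array(
            [
                res.params["Intercept"], res.params["t"],
                res.params["g"], res.params["t:g"],
            ]
        )
        mine = dict(zip(fit.beta_names, fit.beta))
        ours = np.array(
            [mine["intercept"], mine["week"], mine["group"], mine["week_x_group"]]
        )
        assert np.allclose(ours, ref, rtol=1e-4, atol=1e-4)
        assert fit.var_patient == pytest.approx(
            float(res.cov_re.iloc[0, 0]), rel=2e-3, abs=1e-3
        )
        assert fit.var_anchor == pytest.approx(
            float(res.vcomp[0]), rel=2e-3, abs=1e-3
        )
        assert fit.var_resid == pytest.approx(res.scale, rel=2e-3)
        ses = dict(zip(fit.beta_names, fit.se))
        assert ses["week_x_group"] == pytest.approx(
            float(res.bse["t:g"]), rel=2e-3
        )


class TestInvariances:
    def test_shift_moves_only_intercept(self):
        rng = np.random.default_rng(38)
        obs = _simulate_weekly(rng, 8, 8, weeks=6)
        base = fit_nested_lmm(obs)
        shifted = fit_nested_lmm(obs.assign(mean_score=obs["mean_score"] + 100.0))
        assert shifted.beta[0] == pytest.approx(base.beta[0] + 100.0, abs=1e-6)
        assert np.allclose(shifted.beta[1:], base.beta[1:], atol=1e-6)

    def test_rescaling_scales_betas_and_sds(self):
        rng = np.random.default_rng(39)
        obs = _simulate_weekly(rng, 8, 8, weeks=6)
        base = fit_nested_lmm(obs)
        scaled = fit_nested_lmm(obs.assign(mean_score=3.0 * obs["mean_score"]))
        assert np.allclose(scaled.beta, 3.0 * base.beta, rtol=1e-5)
        assert scaled.var_resid == pytest.approx(9.0 * base.var_resid, rel=1e-3)
        assert scaled.var_patient == pytest.approx(9.0 * base.var_patient, rel=1e-3)

    def test_group_relabelling_flips_contrasts(self):
        rng = np.random.default_rng(40)
        obs = _simulate_weekly(rng, 10, 10, weeks=5)
        fit = fit_nested_lmm(obs)
        # relabel so that the former reference becomes the indicator level
        swapped = obs.assign(
            group=obs["group"].map({"event": "a_ctrl", "control": "b_event"})
        )
        fit2 = fit_nested_lmm(swapped)
        c1, c2 = wald_contrasts(fit), wald_contrasts(fit2)
        assert c2.intercept_diff == pytest.approx(-c1.intercept_diff, rel=1e-6)
        assert c2.slope_diff == pytest.approx(-c1.slope_diff, rel=1e-6)
        assert c2.intercept_p == pytest.approx(c1.intercept_p, abs=1e-6)
        assert c2.slope_p == pytest.approx(c1.slope_p, abs=1e-6)


class TestPrediction:
    @staticmethod
    def _toy_fit(beta=(10.0, 1.0, 5.0, 0.5)):
        beta = np.asarray(beta, float)
        return h.LMMFit(
            beta=beta, beta_names=("intercept", "week", "group", "week_x_group"),
            se=np.ones(4), vcov=np.eye(4), var_patient=1.0, var_anchor=1.0,
            var_resid=1.0, loglik=0.0, converged=True, n_obs=10, n_patients=5,
            n_anchors=5, method="REML", group_levels=("control", "event"),
        )

    def test_linear_predictor_arithmetic(self):
        fit = self._toy_fit()
        assert predict_group_mean(fit, 0, "event") == pytest.approx(33.0)
        assert predict_group_mean(fit, -12, "control") == pytest.approx(10.0)

    def test_week_out_of_range(self):
        with pytest.raises(ValueError, match="week"):
            predict_group_mean(self._toy_fit(), 1, "event")
        with pytest.raises(ValueError, match="unknown group"):
            predict_group_mean(self._toy_fit(), 0, "nope")

    def test_small_groups_rejected(self):
        obs = _simulate_weekly(np.random.default_rng(41), 1, 5, weeks=3)
        with pytest.raises(ValueError, match="fewer than 2 patients"):
            fit_nested_lmm(obs)


class TestParameterRecovery:
    def test_mean_bias_of_betas_is_small(self):
        """Across seeded replicates the fixed effects are recovered with
        negligible bias (within 3 Monte-Carlo SEs and 2% of truth)."""
        true = np.array([30.0, -0.1, 12.0, 0.9])
        estimates = []
        for rep in range(24):
            rng = np.random.default_rng(1000 + rep)
            obs = _simulate_weekly(rng, n_event=40, n_control=60, beta=tuple(true))
            fit = fit_nested_lmm(obs, ModelSpec(n_starts=1))
            estimates.append(fit.beta)
        est = np.array(estimates)
        bias = est.mean(axis=0) - true
        mc_se = est.std(axis=0, ddof=1) / np.sqrt(len(est))
        for i in range(4):
            assert abs(bias[i]) < max(3 * mc_se[i], 0.02 * abs(true[i]))
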