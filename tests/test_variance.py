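"""Heteroscedastic random-effects model, LRT, and the wg1 mixed ANOVA."""
import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from isochron.errors import FitError, ValidationError
from isochron.synthetic import StudyDesign, gen_study
from isochron.variance import (
    _aggregate,
    _neg2_reml,
    fit_hetero_lmm,
    fit_wgamma_anova,
    lrt_heteroscedasticity,
    variance_ratio,
)


def _two_group_frame(rng, sd_nktt=0.03, sd_ktt=0.02, n_per_set=200, n_subj=4, sets_per_cell=2):
    """Observations with no subject/set effects: residual structure only."""
    rows = []
    for i in range(n_subj):
        for ktt in (0, 1):
            for rep in range(sets_per_cell):
                sd = sd_ktt if ktt else sd_nktt
                y = rng.normal(0.0, sd, n_per_set)
                for v in y:
                    rows.append((f"s{i}", f"s{i}|{ktt}|{rep}", ktt, "slow", v))
    return pd.DataFrame(rows, columns=["subject", "set", "ktt", "speed", "response_s"])


class TestVarianceRatio:
    @pytest.mark.parametrize(
        "s2_ktt,s2_nktt,expected",
        [
            (0.0006625549, 0.00076729, 0.8635),
            (0.0008080108, 0.00085849, 0.9412),
            (0.0007996383, 0.00082369, 0.9708),
            (0.5, 0.5, 1.0),
        ],
    )
    def test_printed_ratios(self, s2_ktt, s2_nktt, expected):
        assert variance_ratio(s2_ktt, s2_nktt) == expected

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValidationError):
            variance_ratio(0.0, 1.0)


class TestHeteroFit:
    def test_degenerate_two_group_data_reduces_to_pooled_variances(self, rng):
        df = _two_group_frame(rng)
        fit = fit_hetero_lmm(df, heteroscedastic=True, compute_ci=False)
        g = df.groupby("set").agg(
            ktt=("ktt", "first"), sse=("response_s", lambda y: np.sum((y - y.mean()) ** 2)),
            n=("response_s", "size"),
        )
        pooled = (
            g[g.ktt == 1].sse.sum() / (g[g.ktt == 1].n - 1).sum()
        ) / (g[g.ktt == 0].sse.sum() / (g[g.ktt == 0].n - 1).sum())
        assert fit.variance_ratio == pytest.approx(pooled, rel=0.05)
        assert fit.within_individual_sd < 0.005
        assert fit.within_set_sd < 0.005

    def test_homoscedastic_truth_estimates_ratio_near_one(self, rng):
        df = _two_group_frame(rng, sd_nktt=0.03, sd_ktt=0.03, n_per_set=160, n_subj=4, sets_per_cell=4)
        assert len(df) >= 5000
        fit = fit_hetero_lmm(df, heteroscedastic=True, compute_ci=False)
        assert 0.9 <= fit.variance_ratio <= 1.1

    def test_full_design_recovers_all_components(self, small_design):
        df = gen_study(StudyDesign(), seed=3).error_frame()
        fit = fit_hetero_lmm(df, heteroscedastic=True)
        d = StudyDesign()
        assert fit.variance_ratio == pytest.approx(d.ktt_variance_ratio, rel=0.05)
        assert fit.within_individual_sd == pytest.approx(d.within_individual_sd, rel=0.4)
        assert fit.within_set_sd == pytest.approx(d.within_set_sd, rel=0.15)
        assert fit.residual_sd_nktt == pytest.approx(d.residual_sd_nktt, rel=0.05)
        assert fit.fixed_effects.loc["intercept", "estimate"] == pytest.approx(
            d.mean_error_slow, abs=0.002
        )
        lo, hi = fit.variance_ratio_ci
        assert lo < hi

    def test_estimates_invariant_to_identifier_relabeling(self, small_design):
        df = gen_study(small_design, seed=6).error_frame()
        fit_a = fit_hetero_lmm(df, heteroscedastic=True, compute_ci=False)
        relabeled = df.copy()
        relabeled["subject"] = relabeled["subject"].map(lambda s: f"zz_{hash(s) % 97}_{s}")
        relabeled["set"] = relabeled["set"].map(lambda s: f"q{hash(s) % 89}_{s}")
        fit_b = fit_hetero_lmm(relabeled, heteroscedastic=True, compute_ci=False)
        assert fit_b.variance_ratio == pytest.approx(fit_a.variance_ratio, rel=1e-5)
        assert fit_b.loglik == pytest.approx(fit_a.loglik, abs=1e-4)
        assert np.allclose(
            fit_a.fixed_effects["estimate"], fit_b.fixed_effects["estimate"], atol=1e-8
        )

    def test_reported_optimum_is_locally_optimal(self, small_design):
        df = gen_study(small_design, seed=8).error_frame()
        fit = fit_hetero_lmm(df, heteroscedastic=True, compute_ci=False)
        ss = _aggregate(df)
        theta = np.array(
            [
                np.log(max(fit.within_individual_sd, 1e-10)),
                np.log(max(fit.within_set_sd, 1e-10)),
                np.log(fit.residual_sd_nktt),
                np.log(fit.variance_ratio),
            ]
        )
        base = _neg2_reml(theta, ss, True)[0]
        for i in range(4):
            for sign in (-1, 1):
                perturbed = theta.copy()
                perturbed[i] += sign * 0.05
                assert _neg2_reml(perturbed, ss, True)[0] >= base - 1e-6

    def test_single_subject_rejected(self, rng):
        df = _two_group_frame(rng, n_subj=1)
        with pytest.raises(FitError):
            fit_hetero_lmm(df)

    def test_heteroscedastic_fit_needs_both_taping_levels(self, rng):
        df = _two_group_frame(rng)
        with pytest.raises(FitError):
            fit_hetero_lmm(df[df.ktt == 0], heteroscedastic=True)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not available")
class TestAgainstNlme:
    def test_matches_lme_with_varident(self, tmp_path):
        """Independent oracle: nlme::lme with a varIdent residual structure."""
        design = StudyDesign(n_subjects=8, sets_per_tempo=1, intervals_per_set=20)
        df = gen_study(design, seed=7).error_frame()
        fit = fit_hetero_lmm(df, heteroscedastic=True)

        csv = tmp_path / "obs.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            f"""
            library(nlme)
            d <- read.csv("{csv}")
            d$fast <- as.integer(d$speed == "fast")
            m <- lme(response_s ~ fast + ktt, random = ~1 | subject/set,
                     weights = varIdent(form = ~1 | ktt), data = d, method = "REML")
            vc <- as.numeric(VarCorr(m)[, "StdDev"])
            w <- coef(m$modelStruct$varStruct, unconstrained = FALSE, allCoef = TRUE)
            v <- (m$sigma * w)^2
            names(v) <- names(w)
            cat(jsonlite::toJSON(list(
                fixef = as.numeric(fixef(m)), sd_subj = vc[2], sd_set = vc[4],
                var0 = v[["0"]], var1 = v[["1"]],
                logLik = as.numeric(logLik(m))), digits = 12))
            """
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        ref = json.loads(out.stdout)

        assert fit.fixed_effects["estimate"].to_numpy() == pytest.approx(
            np.asarray(ref["fixef"], dtype=float), rel=1e-4, abs=1e-8
        )
        assert fit.within_individual_sd == pytest.approx(ref["sd_subj"][0], rel=1e-3)
        assert fit.within_set_sd == pytest.approx(ref["sd_set"][0], rel=1e-3)
        ref_ratio = ref["var1"][0] / ref["var0"][0]
        assert fit.variance_ratio == pytest.approx(ref_ratio, rel=1e-3)
        assert fit.loglik == pytest.approx(ref["logLik"][0], abs=1e-3)


class TestLRT:
    def test_identical_fits_give_zero_statistic(self, rng):
        df = _two_group_frame(rng, sd_ktt=0.03)
        full = fit_hetero_lmm(df, heteroscedastic=True, compute_ci=False)
        restricted = fit_hetero_lmm(df, heteroscedastic=False, compute_ci=False)
        fake_full = full
        res = lrt_heteroscedasticity(restricted, fake_full)
        assert res.statistic >= 0
        same = lrt_heteroscedasticity(restricted, restricted.__class__(**{**restricted.__dict__, "heteroscedastic": True}))
        assert same.statistic == 0.0
        assert same.p_value == 1.0

    def test_full_model_never_has_lower_likelihood(self):
        for seed in (41, 42):
            df = gen_study(
                StudyDesign(n_subjects=5, sets_per_tempo=1, intervals_per_set=30), seed=seed
            ).error_frame()
            full = fit_hetero_lmm(df, heteroscedastic=True, compute_ci=False)
            restricted = fit_hetero_lmm(df, heteroscedastic=False, compute_ci=False)
            assert full.loglik >= restricted.loglik - 1e-6

    def test_mismatched_fits_rejected(self, rng, small_design):
        df1 = _two_group_frame(rng)
        df2 = gen_study(small_design, seed=1).error_frame()
        f1 = fit_hetero_lmm(df1, heteroscedastic=False, compute_ci=False)
        f2 = fit_hetero_lmm(df2, heteroscedastic=True, compute_ci=False)
        with pytest.raises(ValidationError):
            lrt_heteroscedasticity(f1, f2)

    def test_power_against_a_strong_ratio(self):
        """Ratio 0.6 truth should be detected nearly always."""
        rej = 0
        n_rep = 25
        design = StudyDesign(ktt_variance_ratio=0.6, n_subjects=10, intervals_per_set=40)
        for r in range(n_rep):
            df = gen_study(design, seed=60_000 + r).error_frame()
            full = fit_hetero_lmm(df, heteroscedastic=True, compute_ci=False)
            restricted = fit_hetero_lmm(df, heteroscedastic=False, compute_ci=False)
            rej += lrt_heteroscedasticity(restricted, full).p_value < 0.05
        assert rej >= 0.8 * n_rep


def _wgamma_frame(rng, shift_ktt=0.0, interaction=0.0, n_subj=25, subj_sd=0.1, resid_sd=0.2):
    rows = []
    for i in range(n_subj):
        u = rng.normal(0, subj_sd)
        for ktt in (0, 1):
            for speed in ("fast", "slow"):
                z = (
                    u
                    + shift_ktt * ktt
                    + interaction * ktt * (1 if speed == "fast" else -1)
                    + rng.normal(0, resid_sd)
                )
                rows.append((f"s{i:02d}", ktt, speed, z))
    return pd.DataFrame(rows, columns=["subject", "ktt", "speed", "z"])


class TestWgammaAnova:
    def test_taping_shift_is_detected(self, rng):
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            table = fit_wgamma_anova(_wgamma_frame(rng, shift_ktt=0.15)).table
            hits += table.loc["ktt", "p_value"] < 0.05
        assert hits >= 0.8 * n_rep

    def test_null_p_values_are_uniform(self, rng):
        pvals = [
            fit_wgamma_anova(_wgamma_frame(rng)).table.loc["ktt", "p_value"]
            for _ in range(500)
        ]
        assert sstats.kstest(pvals, "uniform").pvalue > 0.01

    def test_interaction_only_truth_is_attributed_to_the_interaction(self, rng):
        table = fit_wgamma_anova(_wgamma_frame(rng, interaction=0.25)).table
        assert table.loc["ktt_x_speed", "p_value"] < 0.01
        assert table.loc["ktt_x_speed", "F"] > table.loc["ktt", "F"]

    def test_missing_columns_rejected(self):
        with pytest.raises(ValidationError):
            fit_wgamma_anova(pd.DataFrame({"subject": ["a"], "ktt": [1]}))
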