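"""Trend models: Gamma GLMM, Gaussian LMM with Tukey contrasts, stage-link OLS."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from nestcoord.core import ValidationError
from nestcoord.models import (
    fit_chickrearing_trend,
    fit_gamma_glmm,
    fit_incubation_trend,
    fit_stage_link,
    wald_type3,
)
from nestcoord.simulate import (
    simulate_chick_lmm,
    simulate_incubation_glmm,
    simulate_stage_link,
)


class TestGammaGLMM:
    def test_recovers_generating_parameters(self):
        df = simulate_incubation_glmm(n_pairs=40, rng=1)
        rep = fit_incubation_trend(df)
        phase = rep.term("phase")
        # generator: eta = 7e-6 + 8e-8 * days (+ pair intercept)
        assert phase["estimate"] > 0
        assert phase["estimate"] == pytest.approx(8.0e-8, rel=0.35)
        assert rep.term("Intercept")["estimate"] == pytest.approx(7.0e-6, rel=0.2)
        assert phase["p_value"] < 0.05

    def test_zero_response_rejected(self):
        df = simulate_incubation_glmm(n_pairs=5, rng=0)
        df.loc[0, "coordination_s"] = 0.0
        with pytest.raises(ValidationError, match="positive"):
            fit_incubation_trend(df)

    def test_single_year_drops_year_term(self):
        df = simulate_incubation_glmm(n_pairs=10, rng=2)
        df["year"] = 2019
        with pytest.warns(UserWarning, match="year"):
            rep = fit_incubation_trend(df)
        assert set(rep.terms["term"]) == {"Intercept", "phase"}

    def test_two_year_model_reports_interaction(self):
        a = simulate_incubation_glmm(n_pairs=12, rng=3).assign(year=2019)
        b = simulate_incubation_glmm(n_pairs=12, rng=4).assign(year=2020)
        b["pair_id"] = b["pair_id"] + "y2"
        rep = fit_incubation_trend(pd.concat([a, b], ignore_index=True))
        terms = set(rep.terms["term"])
        assert any("phase:" in t for t in terms) and any("year" in t.lower() for t in terms)

    def test_wald_equals_independent_quadratic_form(self):
        df = simulate_incubation_glmm(n_pairs=15, rng=5)
        import patsy

        y, X = patsy.dmatrices("coordination_s ~ phase", df, return_type="dataframe")
        fit = fit_gamma_glmm(
            y.to_numpy().ravel(), X.to_numpy(), df["pair_id"], list(X.columns)
        )
        terms = wald_type3(fit.params, fit.cov_params, X.design_info)
        for i, row in terms.iterrows():
            b = fit.params[i]
            v = fit.cov_params[i, i]
            assert row["stat_value"] == pytest.approx(b * b / v, rel=1e-6)

    def test_wald_and_likelihood_ratio_agree_qualitatively(self):
        """On a balanced design the type-III Wald chi-square for the phase
        term and the likelihood-ratio statistic from refitting without it
        give the same significance call and similar magnitude."""
        import patsy
        from scipy import stats as sps

        df = simulate_incubation_glmm(n_pairs=30, rng=8)
        y, X_full = patsy.dmatrices(
            "coordination_s ~ phase", df, return_type="dataframe"
        )
        yv = y.to_numpy().ravel()
        full = fit_gamma_glmm(yv, X_full.to_numpy(), df["pair_id"])
        null = fit_gamma_glmm(yv, X_full.to_numpy()[:, :1], df["pair_id"])
        lr = 2.0 * (full.llf - null.llf)
        wald = float(full.params[1] ** 2 / full.cov_params[1, 1])
        assert lr > 0
        p_lr = sps.chi2.sf(lr, 1)
        p_wald = sps.chi2.sf(wald, 1)
        assert (p_lr < 0.05) == (p_wald < 0.05)
        assert wald == pytest.approx(lr, rel=0.5)  # asymptotic agreement only

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_against_lme4_oracle(self, tmp_path):
        """Fixed effects agree with lme4::glmer (adaptive quadrature) on the
        same data, as an independent implementation of the same likelihood."""
        df = simulate_incubation_glmm(n_pairs=25, rng=7)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        # fit on a unit-mean response (inverse-link coefficients scale as
        # 1/response, and raw seconds underflow glmer's PIRLS loop), then
        # map the coefficients back to the original scale
        script.write_text(
            textwrap.dedent(
                f"""
                suppressMessages(library(lme4))
                d <- read.csv("{csv}")
                s <- mean(d$coordination_s)
                d$y <- d$coordination_s / s
                m <- glmer(y ~ phase + (1|pair_id), data = d,
                           family = Gamma(link = "inverse"), nAGQ = 25)
                cat(fixef(m) / s, sep = "\\n")
                """
            )
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        r_coefs = [float(x) for x in out.stdout.strip().splitlines()[-2:]]
        rep = fit_incubation_trend(df)
        ours = [rep.term("Intercept")["estimate"], rep.term("phase")["estimate"]]
        for mine, theirs in zip(ours, r_coefs):
            assert mine == pytest.approx(theirs, rel=0.05)


class TestChickRearingLMM:
    def test_interaction_detected_on_generator_defaults(self):
        df = simulate_chick_lmm(rng=1)
        rep = fit_chickrearing_trend(df)
        inter = [t for t in rep.terms["term"] if ":" in t]
        assert inter, "interaction term missing"
        assert rep.term(inter[0])["p_value"] < 0.05
        assert "tukey" in rep.extras and len(rep.extras["tukey"]) == 6  # C(4,2) cells

    def test_identical_cell_means_nonsignificant(self):
        cells = {(y, p): 0.2 for y in (0, 1) for p in ("EARLY", "MID")}
        df = simulate_chick_lmm(cells=cells, rng=3)
        rep = fit_chickrearing_trend(df)
        non_icpt = rep.terms[rep.terms["term"] != "Intercept"]
        assert (non_icpt["p_value"] > 0.05).all()
        assert (rep.extras["tukey"]["p_tukey"] > 0.05).all()

    def test_single_pair_falls_back_to_fixed_effects(self):
        df = simulate_chick_lmm(n_pairs=1, rng=4)
        with pytest.warns(UserWarning, match="random intercept"):
            rep = fit_chickrearing_trend(df)
        assert "single pair" in rep.random_effects

    def test_missing_phase_rejected(self):
        df = simulate_chick_lmm(rng=5)
        with pytest.raises(ValidationError, match="phase"):
            fit_chickrearing_trend(df[df["phase"] == "EARLY"])

    def test_tukey_pvalues_in_unit_interval(self):
        rep = fit_chickrearing_trend(simulate_chick_lmm(rng=6))
        p = rep.extras["tukey"]["p_tukey"]
        assert ((p >= 0) & (p <= 1)).all()


class TestStageLink:
    def test_vifs_near_one_for_independent_predictors(self):
        g = np.random.default_rng(10)
        df = pd.DataFrame(
            {
                "early_inc": g.normal(size=200),
                "mid_inc": g.normal(size=200),
                "late_inc": g.normal(size=200),
                "chick_index_mid": g.normal(size=200),
            }
        )
        reports = fit_stage_link(df, n_boot=200, rng=0)
        vifs = reports["chick_index_mid"].extras["vif"]
        assert all(1.0 <= v <= 1.1 for v in vifs.values())

    def test_perfect_collinearity_flagged(self):
        g = np.random.default_rng(11)
        x = g.normal(size=30)
        df = pd.DataFrame(
            {
                "early_inc": x,
                "mid_inc": x,  # duplicated predictor
                "late_inc": g.normal(size=30),
                "chick_index_mid": g.normal(size=30),
            }
        )
        with pytest.raises(ValidationError, match="collinear"):
            fit_stage_link(df, n_boot=50, rng=0)

    def test_refuses_underdetermined_fit(self):
        df = simulate_stage_link(n_pairs=4, rng=0).rename(
            columns={"chick_index": "chick_index_mid"}
        )
        with pytest.raises(ValidationError, match="refusing"):
            fit_stage_link(df, n_boot=10, rng=0)

    def test_detects_the_linked_phase(self):
        df = simulate_stage_link(rng=1).rename(columns={"chick_index": "chick_index_mid"})
        reports = fit_stage_link(df, n_boot=2000, rng=2)
        boot = reports["chick_index_mid"].extras["bootstrap"].set_index("term")
        mid = boot.loc["mid_inc"]
        assert mid["ci_lo"] > 0  # the true positive link
        assert mid["p_boot"] < 0.05

    def test_bootstrap_interval_tightens_with_b(self):
        """Percentile-interval midpoint approaches the point estimate as B
        grows on a fixed dataset."""
        df = simulate_stage_link(n_pairs=30, rng=3).rename(
            columns={"chick_index": "chick_index_mid"}
        )
        gaps = []
        for B in (100, 10_000):
            reports = fit_stage_link(df, n_boot=B, rng=4)
            boot = reports["chick_index_mid"].extras["bootstrap"].set_index("term")
            mid = boot.loc["mid_inc"]
            gaps.append(abs((mid["ci_lo"] + mid["ci_hi"]) / 2 - mid["estimate"]))
        assert gaps[1] <= gaps[0]
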