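from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import methrisk as mr
from methrisk.cohort import GENES, GeneMarginal, MISSING_TOKEN
from methrisk.errors import ConfigurationError, ParseError, ValidationError


class TestConfigValidation:
    def test_non_positive_definite_correlation_rejected(self):
        cfg = mr.pca1_config(10, seed=0)
        bad = np.full((5, 5), 1.0)
        with pytest.raises(ConfigurationError, match="positive definite"):
            replace(cfg, copula_correlation=bad).validate()

    def test_frequencies_must_sum_to_one(self):
        cfg = mr.pca1_config(10, seed=0)
        freqs = dict(cfg.clinical_freqs)
        freqs["margins"] = {"positive": 0.5, "negative": 0.4}
        with pytest.raises(ConfigurationError, match="sum"):
            replace(cfg, clinical_freqs=freqs).validate()

    def test_cut_ordering_enforced(self):
        cfg = mr.pca1_config(10, seed=0)
        with pytest.raises(ConfigurationError):
            replace(cfg, group_cuts=(50.0, 15.0)).validate()


class TestMethylation:
    def test_empty_cohort(self):
        m = mr.generate_methylation(mr.pca1_config(0, seed=1))
        assert m.shape == (0, 5)

    def test_values_bounded(self, tumor_cohort):
        vals = tumor_cohort[list(GENES)].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        assert vals.min() >= 0.0 and vals.max() <= 100.0

    def test_deterministic_given_seed(self):
        cfg = mr.pca1_config(50, seed=33)
        a = mr.generate_cohort(cfg)
        b = mr.generate_cohort(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_benign_baseline_stays_below_two_percent(self):
        for s in range(20):
            m = mr.generate_methylation(mr.bph_config(42, seed=s))
            assert m.mean().max() <= 2.0

    def test_empirical_correlation_matches_copula_implied(self):
        # Monte-Carlo estimate of the copula-implied Pearson matrix at n=1e5
        big = mr.generate_methylation(
            replace(mr.pca1_config(100_000, seed=71), missing_rates={})
        )
        implied = np.corrcoef(big.to_numpy().T)
        small = mr.generate_methylation(
            replace(mr.pca1_config(2000, seed=72), missing_rates={})
        )
        emp = np.corrcoef(small.to_numpy().T)
        assert np.abs(emp - implied).max() <= 0.1

    def test_rank_correlation_converges_to_gaussian_copula_value(self):
        # with no zero-inflation the margins are continuous, so Spearman's
        # rho equals the closed-form 6/pi*arcsin(rho/2) of the copula
        from scipy import stats

        cfg = mr.pca1_config(100_000, seed=73)
        marg = {g: GeneMarginal(zero_mass=0.0, alpha=1.5, beta=2.5) for g in GENES}
        cfg = replace(cfg, marginal_params=marg, missing_rates={})
        m = mr.generate_methylation(cfg)
        rho_latent = cfg.copula_correlation[0, 1]
        expected = 6 / np.pi * np.arcsin(rho_latent / 2)
        observed = stats.spearmanr(m["GSTP1"], m["APC"]).statistic
        assert observed == pytest.approx(expected, abs=0.02)

    def test_missingness_rate_respected(self):
        cfg = replace(
            mr.pca1_config(20_000, seed=74), missing_rates={"RARB": 0.07}
        )
        m = mr.generate_methylation(cfg)
        assert m["RARB"].isna().mean() == pytest.approx(0.07, abs=0.01)
        assert m["GSTP1"].isna().sum() == 0


class TestClinical:
    def test_category_frequencies(self):
        clin = mr.generate_clinical(mr.pca1_config(10_000, seed=21))
        frac = (clin["gleason_group"] == "2-6").mean()
        assert frac == pytest.approx(0.38, abs=0.02)

    def test_point_mass_category(self):
        cfg = mr.pca1_config(30, seed=22)
        freqs = dict(cfg.clinical_freqs)
        freqs["pt_group"] = {"pT2": 1.0}
        clin = mr.generate_clinical(replace(cfg, clinical_freqs=freqs))
        assert (clin["pt_group"] == "pT2").all()

    def test_determinism(self):
        cfg = mr.pca1_config(100, seed=23)
        pd.testing.assert_frame_equal(
            mr.generate_clinical(cfg), mr.generate_clinical(cfg)
        )

    def test_psa_lognormal_median(self):
        clin = mr.generate_clinical(mr.pca1_config(20_000, seed=24))
        assert np.median(clin["psa"]) == pytest.approx(38.3, rel=0.05)


class TestSurvival:
    def test_no_censoring_all_events(self):
        cfg = replace(
            mr.pca1_config(200, seed=31),
            log_hazard={},
            target_event_fraction=None,
            censoring_horizon_years=np.inf,
            censoring_rate_per_year=0.0,
            missing_rates={},
        )
        meth = mr.generate_methylation(cfg)
        clin = mr.generate_clinical(cfg)
        surv = mr.generate_survival(meth, clin, cfg)
        assert (surv["cf_event"] == 1).all()
        assert (surv["followup_years"] > 0).all()

    def test_event_fraction_near_target_at_cohort_size(self):
        coh = mr.generate_cohort(mr.pca1_config(147, seed=32))
        assert coh["cf_event"].mean() == pytest.approx(0.20, abs=0.10)

    def test_event_fraction_tight_at_large_n(self):
        coh = mr.generate_cohort(mr.pca1_config(4000, seed=33))
        assert coh["cf_event"].mean() == pytest.approx(0.20, abs=0.05)

    def test_missing_first_gene_names_patient(self):
        cfg = replace(mr.pca1_config(10, seed=34), missing_rates={})
        meth = mr.generate_methylation(cfg)
        clin = mr.generate_clinical(cfg)
        meth.loc[3, "GSTP1"] = np.nan
        with pytest.raises(ValidationError, match="P0004"):
            mr.generate_survival(meth, clin, cfg)

    def test_cox_recovers_generating_hazard_ratio(self):
        cfg = replace(
            mr.pca1_config(5000, seed=35),
            log_hazard={"lm_hm": float(np.log(3.0))},
            missing_rates={},
        )
        coh = mr.generate_cohort(cfg)
        df = pd.DataFrame(
            {
                "time": coh["followup_years"],
                "event": coh["cf_event"],
                "lm_hm": (coh["true_group"] != "MM").astype(float),
            }
        )
        fit = mr.cox_fit(df, ["lm_hm"])
        hr, *_ = mr.hazard_ratio(fit, "lm_hm")
        assert 2.5 <= hr <= 3.6

    def test_single_coefficient_recovery_within_three_se(self):
        hits = 0
        betas = [-1.5, -0.5, 0.5, 1.0, 1.5]
        for i, b in enumerate(betas):
            for s in range(2):
                cfg = replace(
                    mr.pca1_config(5000, seed=900 + 10 * i + s),
                    log_hazard={"lm_hm": b},
                    missing_rates={},
                )
                coh = mr.generate_cohort(cfg)
                df = pd.DataFrame(
                    {
                        "time": coh["followup_years"],
                        "event": coh["cf_event"],
                        "lm_hm": (coh["true_group"] != "MM").astype(float),
                    }
                )
                fit = mr.cox_fit(df, ["lm_hm"])
                hits += abs(fit.coef[0] - b) <= 3 * fit.se[0]
        assert hits >= 9  # 3-SE coverage should only rarely fail


class TestCohortIO:
    def test_round_trip_preserves_values_and_missing(self, tmp_path):
        coh = mr.generate_cohort(mr.pca2_config(50, seed=41))
        assert coh[list(GENES)].isna().sum().sum() >= 0
        path = tmp_path / "cohort.csv"
        mr.write_cohort(coh, path)
        back = mr.read_cohort(path)
        assert len(back) == 50
        for g in GENES:
            orig, new = coh[g], back[g]
            assert orig.isna().equals(new.isna())
            np.testing.assert_allclose(
                orig.dropna().to_numpy(), new.dropna().to_numpy(), atol=1e-12
            )
        assert back["followup_years"].to_numpy() == pytest.approx(
            coh["followup_years"].to_numpy(), abs=1e-6
        )
        assert (back["cf_event"] == coh["cf_event"]).all()

    def test_missing_token_read_as_missing_not_zero(self, tmp_path):
        coh = mr.generate_cohort(mr.pca1_config(5, seed=42))
        coh.loc[2, "APC"] = np.nan
        path = tmp_path / "c.csv"
        mr.write_cohort(coh, path)
        assert MISSING_TOKEN in path.read_text()
        back = mr.read_cohort(path)
        assert pd.isna(back.loc[2, "APC"])

    def test_negative_followup_rejected_with_line(self, tmp_path):
        coh = mr.generate_cohort(mr.pca1_config(5, seed=43))
        path = tmp_path / "c.csv"
        mr.write_cohort(coh, path)
        text = path.read_text().splitlines()
        row = text[3].split(",")
        row[-3] = "-1.000000"
        text[3] = ",".join(row)
        path.write_text("\n".join(text) + "\n")
        with pytest.raises(ParseError, match="line 4"):
            mr.read_cohort(path)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("patient_id,GSTP1\nP1,5\n")
        with pytest.raises(ParseError, match="lacks columns"):
            mr.read_cohort(path)
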