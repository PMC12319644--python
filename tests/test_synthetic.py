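"""Generator: margin recovery, determinism, recoding, splitting, guards."""

import numpy as np
import pandas as pd
import pytest

from relint import synthetic as syn


class TestCovariates:
    def test_margins_match_configuration(self, big_table):
        df = big_table
        assert df.age.mean() == pytest.approx(46.8, abs=0.2)
        assert (df.sex == "female").mean() * 100 == pytest.approx(46.6, abs=1.0)
        cp = syn.GeneratorConfig().covariate_params
        for var in ("education", "region", "urges"):
            obs = df[var].value_counts(normalize=True, dropna=True)
            for lev, p in cp[var].items():
                assert obs[lev] == pytest.approx(p, abs=0.015)
        assert df.income.mean() == pytest.approx(1.47, abs=0.02)
        assert df.income.std() == pytest.approx(0.818, abs=0.02)
        # right-skew: median below mean, as in the study sample
        assert df.income.median() < df.income.mean()
        assert df.age.between(18, 99).all()
        assert df.income.dropna().between(0, 7).all()

    def test_n_zero_forbidden(self):
        with pytest.raises(ValueError):
            syn.GeneratorConfig(n_records=0)

    def test_bad_proportions_rejected(self):
        cfg = syn.GeneratorConfig()
        cfg.covariate_params["education"] = {"low": 0.5, "middle": 0.4,
                                             "high": 0.2}
        with pytest.raises(ValueError):
            syn.GeneratorConfig(covariate_params=cfg.covariate_params)

    def test_unordered_bounds_rejected(self):
        cp = syn._default_covariate_params()
        cp["age_min"], cp["age_max"] = 90, 20
        with pytest.raises(ValueError):
            syn.GeneratorConfig(covariate_params=cp)

    def test_determinism_byte_identical(self):
        cfg = syn.GeneratorConfig(n_records=2000, seed=5)
        a = syn.generate_table(cfg)
        b = syn.generate_table(syn.GeneratorConfig(n_records=2000, seed=5))
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self):
        a = syn.generate_table(syn.GeneratorConfig(n_records=500, seed=1))
        b = syn.generate_table(syn.GeneratorConfig(n_records=500, seed=2))
        assert not a.equals(b)


class TestMTSS:
    def test_symmetric_null_model_gives_equal_thirds(self):
        cfg = syn.GeneratorConfig(n_records=60_000, seed=3)
        for c in cfg.mtss_coefficients.values():
            c.update(intercept=0.0, female=0.0, income=0.0,
                     age_linear_per10=0.0, age_basis=(0, 0, 0),
                     age_basis_x_income=(0, 0, 0),
                     urges={k: 0.0 for k in c["urges"]},
                     year={k: 0.0 for k in c["year"]},
                     education={k: 0.0 for k in c["education"]},
                     region={k: 0.0 for k in c["region"]})
        df = syn.generate_mtss(syn.generate_covariates(cfg), cfg)
        r = syn.recode_outcomes(df)
        shares = r[r.smoker_status == "current"].mtss3.value_counts(normalize=True)
        for v in shares:
            assert v == pytest.approx(1 / 3, abs=0.015)

    def test_level1_frequency_matches_study_margin(self, big_table):
        cur = big_table[big_table.smoker_status == "current"]
        obs = cur.mtss_level.dropna()
        assert 100 * (obs == 1).mean() == pytest.approx(47.2, abs=1.5)

    def test_degenerate_expansion_suppresses_levels(self):
        cfg = syn.GeneratorConfig(n_records=20_000, seed=4)
        cfg.mtss_expansion[3] = (1.0, 0.0, 0.0, 0.0)
        df = syn.generate_mtss(syn.generate_covariates(cfg), cfg)
        lev = df.mtss_level.dropna()
        assert not lev.isin([5, 6, 7]).any()
        assert (lev == 4).any()

    def test_recent_ex_never_assessed(self, big_table):
        assert big_table.loc[big_table.smoker_status == "recent_ex",
                             "mtss_level"].isna().all()

    def test_missing_covariate_rejected(self):
        cfg = syn.GeneratorConfig(n_records=100, seed=0)
        df = syn.generate_covariates(cfg).drop(columns=["income"])
        with pytest.raises(ValueError, match="income"):
            syn.generate_mtss(df, cfg)


class TestQA:
    def test_prevalence_matches_study(self, big_table):
        r = syn.recode_outcomes(big_table)
        obs = r.qa.dropna()
        assert 100 * (obs == "yes").mean() == pytest.approx(18.3, abs=1.5)

    def test_zero_slopes_give_half(self):
        cfg = syn.GeneratorConfig(n_records=40_000, seed=9)
        c = cfg.qa_coefficients
        c.update(intercept=0.0, year_per_year=0.0, age_per_10y=0.0,
                 female=0.0, income=0.0,
                 urges={k: 0.0 for k in c["urges"]},
                 education={k: 0.0 for k in c["education"]},
                 region={k: 0.0 for k in c["region"]},
                 female_x_education={"middle": 0.0, "high": 0.0})
        df = syn.generate_qa(syn.generate_covariates(cfg), cfg)
        assert (df.n_quit_attempts >= 1).mean() == pytest.approx(0.5, abs=0.01)

    def test_interaction_or_from_contingency_table(self):
        """Empirical 2x2-table OR of high-educated females vs low-educated
        males matches the configured product of main and interaction ORs."""
        cfg = syn.GeneratorConfig(n_records=200_000, seed=13)
        df = syn.recode_outcomes(
            syn.generate_qa(syn.generate_covariates(cfg), cfg))

        def odds(sub):
            return (sub.qa == "yes").sum() / (sub.qa == "no").sum()

        fh = df[(df.sex == "female") & (df.education == "high")]
        ml = df[(df.sex == "male") & (df.education == "low")]
        assert odds(fh) / odds(ml) == pytest.approx(1.26 * 1.42 * 0.67,
                                                    abs=0.05)


class TestMissingness:
    def test_rates_match_study_margins(self, big_table):
        df = big_table
        assert 100 * df.mtss_level.isna().mean() == pytest.approx(4.8, abs=1.0)
        assert 100 * df.n_quit_attempts.isna().mean() == pytest.approx(4.6, abs=1.0)
        assert 100 * df.education.isna().mean() == pytest.approx(1.4, abs=0.5)
        assert 100 * df.urges.isna().mean() == pytest.approx(1.2, abs=0.5)

    def test_zero_rates_noop(self):
        cfg = syn.GeneratorConfig(n_records=5000, seed=21)
        cfg.missingness_params["rates"] = {k: 0.0 for k in
                                           cfg.missingness_params["rates"]}
        base = syn.generate_qa(syn.generate_mtss(
            syn.generate_covariates(cfg), cfg), cfg)
        out = syn.inject_missingness(base, cfg)
        pd.testing.assert_frame_equal(base, out)

    def test_male_high_stratum_rate_exceeds_female_low(self):
        cfg = syn.GeneratorConfig(n_records=80_000, seed=23)
        cfg.missingness_params["male_high_increment"] = 2.0
        df = syn.generate_table(cfg)
        mh = df[(df.sex == "male") & (df.education == "high")]
        fl = df[(df.sex == "female") & (df.education == "low")]
        assert (mh.n_quit_attempts.isna().mean()
                > fl.n_quit_attempts.isna().mean())

    def test_invalid_rate_rejected(self):
        mp = syn._default_missingness_params()
        mp["rates"]["urges"] = 1.5
        with pytest.raises(ValueError):
            syn.GeneratorConfig(missingness_params=mp)


class TestRecode:
    @pytest.mark.parametrize("level,expected", [
        (1, "absence"), (2, "unspecific"), (3, "unspecific"),
        (4, "motivation"), (7, "motivation")])
    def test_collapse_mapping(self, level, expected):
        df = pd.DataFrame({"mtss_level": [float(level)],
                           "n_quit_attempts": [0.0]})
        assert syn.recode_outcomes(df).mtss3[0] == expected

    def test_qa_mapping_and_missing_propagation(self):
        df = pd.DataFrame({"mtss_level": [np.nan, 1.0],
                           "n_quit_attempts": [0.0, np.nan]})
        r = syn.recode_outcomes(df)
        assert r.qa[0] == "no" and pd.isna(r.qa[1])
        assert pd.isna(r.mtss3[0]) and r.mtss3[1] == "absence"

    def test_out_of_range_level_rejected(self):
        df = pd.DataFrame({"mtss_level": [8.0], "n_quit_attempts": [0.0]})
        with pytest.raises(ValueError):
            syn.recode_outcomes(df)

    def test_idempotent(self, big_table):
        once = syn.recode_outcomes(big_table)
        twice = syn.recode_outcomes(once)
        pd.testing.assert_frame_equal(once, twice)


class TestSplit:
    def test_sizes_and_disjointness(self, small_table):
        learn, valid = syn.split_learning_validation(small_table, 0.7, seed=3)
        assert len(learn) == 2800 and len(valid) == 1200
        assert set(learn.id).isdisjoint(valid.id)
        assert set(learn.id) | set(valid.id) == set(small_table.id)

    def test_study_size_rounding_convention(self):
        df = pd.DataFrame({"id": range(13245)})
        learn, valid = syn.split_learning_validation(df, 0.7, seed=0)
        assert (len(learn), len(valid)) == (9272, 3973)

    def test_ten_rows(self):
        df = pd.DataFrame({"id": range(10)})
        learn, valid = syn.split_learning_validation(df, 0.7, seed=1)
        assert (len(learn), len(valid)) == (7, 3)

    def test_same_seed_reproducible(self, small_table):
        a1, b1 = syn.split_learning_validation(small_table, 0.3, seed=8)
        a2, b2 = syn.split_learning_validation(small_table, 0.3, seed=8)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(b1, b2)

    def test_bad_fraction_rejected(self, small_table):
        for f in (0.0, 1.0, -0.2, 1.7):
            with pytest.raises(ValueError):
                syn.split_learning_validation(small_table, f, seed=0)


class TestStrataCount:
    def test_study_example(self):
        assert syn.count_full_strata([2, 3, 3, 3, 3]) == 162

    def test_single_dimension(self):
        assert syn.count_full_strata([1]) == 1

    def test_two_dimensions(self):
        assert syn.count_full_strata([4, 5]) == 20

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            syn.count_full_strata([])

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            syn.count_full_strata([2, 0, 3])
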