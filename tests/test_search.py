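"""Candidate enumeration, bootstrap OOB selection, backward elimination."""

import numpy as np
import pytest

from relint import synthetic as syn
from relint.glm import ModelSpec, Term
from relint.impute import ImputationSet, _complete_set
from relint.search import (CandidateSpace, backward_eliminate,
                           bootstrap_select, confirm_interaction,
                           default_space, enumerate_candidates)


class TestEnumeration:
    def test_counting_formula(self):
        space = CandidateSpace(
            outcome="qa",
            base_terms=[Term("urges", "categorical"), Term("year", "linear")],
            spline_options={"age": ["linear", "rcs4"],
                            "income": ["linear", "rcs4"]},
            max_interactions=1)
        cands = enumerate_candidates(space)
        # 2 x 2 functional forms x (1 + 10 interaction choices)
        assert len(cands) == 44

    def test_zero_interactions(self):
        space = default_space("qa")
        space.max_interactions = 0
        cands = enumerate_candidates(space)
        assert all(not c.interactions for c in cands)

    def test_duplicate_pair_rejected(self):
        with pytest.raises(ValueError):
            CandidateSpace(outcome="qa",
                           interaction_pool=[("age", "sex"), ("sex", "age")])

    def test_hierarchy_members_present(self):
        for c in enumerate_candidates(default_space("mtss3")):
            names = c.term_names
            for a, b in c.interactions:
                assert a in names and b in names


@pytest.fixture(scope="module")
def qa_set():
    cfg = syn.GeneratorConfig(n_records=3000, seed=17)
    df = syn.recode_outcomes(syn.generate_qa(syn.generate_covariates(cfg), cfg))
    return _complete_set(df, 1, 17)


class TestBootstrapSelect:
    def test_single_candidate_wins_with_full_score_vector(self, qa_set):
        cand = ModelSpec(outcome="qa", terms=[Term("sex", "categorical"),
                                              Term("income", "linear")])
        sel = bootstrap_select(qa_set, [cand], B=50, rule="brier", seed=1)
        assert sel.winner is cand
        assert sel.scores.shape == (50, 1)
        assert np.isfinite(sel.scores).sum() >= 45

    def test_reproducible_given_seed(self, qa_set):
        cands = [ModelSpec(outcome="qa", terms=[Term("sex", "categorical")]),
                 ModelSpec(outcome="qa", terms=[Term("sex", "categorical"),
                                                Term("income", "linear")])]
        s1 = bootstrap_select(qa_set, cands, B=50, rule="brier", seed=9)
        s2 = bootstrap_select(qa_set, cands, B=50, rule="brier", seed=9)
        assert s1.winner_index == s2.winner_index
        np.testing.assert_array_equal(s1.scores, s2.scores)

    def test_oob_disjoint_from_bootstrap_sample(self):
        """The out-of-bag construction never overlaps the in-bag index set."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(10, 500))
            idx = rng.integers(0, n, size=n)
            inbag = np.zeros(n, dtype=bool)
            inbag[idx] = True
            oob = np.flatnonzero(~inbag)
            assert set(oob).isdisjoint(set(idx))

    def test_b_below_minimum_rejected(self, qa_set):
        cand = ModelSpec(outcome="qa", terms=[Term("sex", "categorical")])
        with pytest.raises(ValueError):
            bootstrap_select(qa_set, [cand], B=10, rule="brier", seed=0)

    def test_unknown_rule_rejected(self, qa_set):
        cand = ModelSpec(outcome="qa", terms=[Term("sex", "categorical")])
        with pytest.raises(ValueError):
            bootstrap_select(qa_set, [cand], B=50, rule="auc", seed=0)


class TestBackwardElimination:
    def test_noise_covariate_eliminated(self):
        """A pure-noise covariate (region has no effect in this generator
        configuration) is dropped by BIC-based backward elimination."""
        dropped = 0
        for seed in range(8):
            cfg = syn.GeneratorConfig(n_records=5000, seed=100 + seed)
            cfg.qa_coefficients["region"] = {"rural": 0.0, "urban": 0.0,
                                             "metropolitan": 0.0}
            cfg.qa_coefficients["female_x_education"] = {"middle": 0.0,
                                                         "high": 0.0}
            df = syn.recode_outcomes(
                syn.generate_qa(syn.generate_covariates(cfg), cfg))
            iset = _complete_set(df, 1, seed)
            full = ModelSpec(outcome="qa", terms=[
                Term("urges", "categorical"), Term("year", "linear"),
                Term("sex", "categorical"), Term("education", "categorical"),
                Term("region", "categorical"), Term("income", "linear")])
            out = backward_eliminate(iset, full)
            dropped += "region" not in out.term_names
        assert dropped >= 7

    def test_idempotent_fixed_point(self, qa_set):
        spec = ModelSpec(outcome="qa", terms=[
            Term("urges", "categorical"), Term("year", "linear"),
            Term("sex", "categorical"), Term("income", "linear")])
        once = backward_eliminate(qa_set, spec)
        twice = backward_eliminate(qa_set, once)
        assert twice.to_dict() == once.to_dict()

    def test_hierarchy_interaction_blocks_main_effect_removal(self, qa_set):
        spec = ModelSpec(outcome="qa", terms=[
            Term("urges", "categorical"), Term("year", "linear"),
            Term("sex", "categorical"), Term("education", "categorical")],
            interactions=[("sex", "education")])
        out = backward_eliminate(qa_set, spec)
        # whatever is eliminated, sex/education may only go after the
        # interaction is gone
        if out.interactions:
            assert "sex" in out.term_names and "education" in out.term_names

    def test_spline_reduced_to_linear_not_dropped_first(self):
        """With a truly linear age effect, the spline term simplifies to
        linear rather than disappearing."""
        cfg = syn.GeneratorConfig(n_records=8000, seed=200)
        df = syn.recode_outcomes(
            syn.generate_qa(syn.generate_covariates(cfg), cfg))
        iset = _complete_set(df, 1, 0)
        spec = ModelSpec(outcome="qa", terms=[
            Term("urges", "categorical"), Term("year", "linear"),
            Term("sex", "categorical"), Term("income", "linear"),
            Term("age", "rcs4")])
        out = backward_eliminate(iset, spec)
        age_terms = [t for t in out.terms if t.name == "age"]
        if age_terms:
            assert age_terms[0].form in {"linear", "rcs4"}


class TestConfirmInteraction:
    def test_winner_without_interaction_passes_vacuously(self, qa_set):
        cand = ModelSpec(outcome="qa", terms=[Term("sex", "categorical")])
        sel = bootstrap_select(qa_set, [cand], B=50, rule="brier", seed=2)
        sel = confirm_interaction(sel, qa_set)
        assert sel.lr_confirmation["retained"] is True
        assert sel.lr_confirmation["p"] is None

    def test_strong_interaction_confirmed(self):
        cfg = syn.GeneratorConfig(n_records=9000, seed=301)
        cfg.qa_coefficients["female_x_education"] = {"middle": 0.0,
                                                     "high": -0.7}
        df = syn.recode_outcomes(
            syn.generate_qa(syn.generate_covariates(cfg), cfg))
        iset = _complete_set(df, 1, 0)
        cand = ModelSpec(outcome="qa", terms=[
            Term("urges", "categorical"), Term("year", "linear"),
            Term("sex", "categorical"), Term("education", "categorical"),
            Term("income", "linear")],
            interactions=[("sex", "education")])
        sel = bootstrap_select(iset, [cand], B=50, rule="brier", seed=3)
        sel = confirm_interaction(sel, iset)
        assert sel.lr_confirmation["retained"] is True
        assert sel.lr_confirmation["p"] < 0.001
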