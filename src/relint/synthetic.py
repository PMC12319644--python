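"""Synthetic survey generator emulating a German tobacco-use household survey.

The real data behind this pipeline are third-party and cannot be shipped, so
every downstream stage (imputation, model selection, validation) is exercised
on synthetic tables whose *margins*, *outcome models* and *missingness
mechanism* mirror the published characteristics of the study sample:

* covariates: age (truncated normal), sex, education, region, urges to smoke
  (categorical draws), standardised net household income on a 0-7 scale
  (moment-matched gamma, truncated — right-skewed like the real margin),
  survey year, and current-smoker vs recent ex-smoker status;
* a 3-category motivation-to-stop outcome drawn from a multinomial-logit
  model whose "motivation" predictor carries a smooth age bump (restricted
  cubic spline) whose amplitude decays with income — i.e. a true age x income
  interaction peaking at ages 30-50 for low incomes — then expanded to the
  7-level scale with fixed conditional proportions;
* a past-year quit-attempt outcome drawn from a logistic model with a true
  sex x education interaction;
* selective missing-at-random missingness, with an extra log-odds increment
  for highly educated males on the smoking-habit variables.

All draws are deterministic given the configured seed.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

from .splines import SplineSpec, rcs_basis

__all__ = [
    "GeneratorConfig", "generate_covariates", "generate_mtss", "generate_qa",
    "inject_missingness", "recode_outcomes", "split_learning_validation",
    "count_full_strata", "generate_table", "STUDY_COUNTS",
]

#: Published sample counts used as generator defaults and sanity anchors.
STUDY_COUNTS = {
    "current_smokers": 12784,
    "recent_ex_smokers": 461,
    "past_year_smokers": 13245,
    "learning_past_year": 9253,
    "validation_past_year": 3992,
    "learning_qa_yes": 1689,
    "validation_qa_yes": 778,
}

#: Knots of the spline carrying the generator's true age effect on motivation.
_AGE_KNOTS = SplineSpec(knots=(25.0, 40.0, 55.0, 75.0))


def _default_covariate_params() -> dict:
    return {
        "age_mean": 46.8, "age_sd": 16.7, "age_min": 18.0, "age_max": 99.0,
        "p_female": 0.466,
        # shares renormalised over observed (non-missing) cells
        "education": {"low": 0.3415, "middle": 0.3973, "high": 0.2612},
        "region": {"rural": 0.359, "urban": 0.432, "metropolitan": 0.209},
        "urges": {"none": 0.0729, "light": 0.2237, "medium_strong": 0.4060,
                  "strong": 0.2308, "very_strong": 0.0568,
                  "extremely_strong": 0.0098},
        "income_mean": 1.47, "income_sd": 0.818,
        "income_min": 0.0, "income_max": 7.0,
        "p_current": STUDY_COUNTS["current_smokers"] / STUDY_COUNTS["past_year_smokers"],
    }


def _default_mtss_coefficients() -> dict:
    """Linear-predictor coefficients of the 3-category motivation model.

    Contrasts are "unspecific" and "motivation", each versus "absence".
    Categorical effects are log odds-ratios taken from the published pooled
    model.  The motivation contrast carries the age bump ``f(age)`` (on the
    spline basis over knots 25/40/55/75) modulated by income,
    ``f(age) * (1 - 0.30 * income)``, plus a per-unit income main effect —
    a true smooth age x income interaction whose motivation probability
    peaks between ages 30 and 50 for incomes below ~2.
    Intercepts are calibrated so collapsed-category frequencies among
    current smokers match the published margin (47.2 / 37.5 / 15.3).
    """
    lg = math.log
    # f(age) coefficients on the (age/10, C2, C3) basis, least-squares matched
    # to the published age contrasts for the motivation category (see docs).
    age_basis_motiv = (0.4903, -0.1582, 0.3099)
    return {
        "unspecific": {
            "intercept": -0.3669,
            "urges": {"none": lg(0.64), "light": lg(0.75), "medium_strong": 0.0,
                      "strong": lg(0.86), "very_strong": lg(0.72),
                      "extremely_strong": lg(0.52)},
            "year": {2016: 0.0, 2017: lg(1.26), 2018: lg(1.20),
                     2019: lg(1.15), 2020: lg(1.25)},
            "female": lg(1.18),
            "education": {"low": 0.0, "middle": lg(1.13), "high": lg(1.33)},
            "region": {"rural": 0.0, "urban": lg(1.12), "metropolitan": lg(0.92)},
            "income": 0.02,
            "age_linear_per10": -0.03,
            "age_basis": (0.0, 0.0, 0.0),
            "age_basis_x_income": (0.0, 0.0, 0.0),
        },
        "motivation": {
            "intercept": -1.4384,
            "urges": {"none": lg(0.63), "light": lg(0.85), "medium_strong": 0.0,
                      "strong": lg(0.73), "very_strong": lg(0.43),
                      "extremely_strong": lg(0.80)},
            "year": {2016: 0.0, 2017: lg(0.84), 2018: lg(0.70),
                     2019: lg(0.59), 2020: lg(0.54)},
            "female": lg(1.13),
            "education": {"low": 0.0, "middle": lg(1.19), "high": lg(1.65)},
            "region": {"rural": 0.0, "urban": lg(1.17), "metropolitan": lg(0.91)},
            "income": -0.30,
            "age_linear_per10": 0.0,
            "age_basis": age_basis_motiv,
            "age_basis_x_income": tuple(-0.30 * a for a in age_basis_motiv),
        },
    }


def _default_mtss_expansion() -> dict:
    # conditional proportions from the published 7-level frequencies
    return {
        1: (1.0,),
        2: (0.710, 0.290),                    # levels 2, 3
        3: (0.238, 0.615, 0.077, 0.070),      # levels 4, 5, 6, 7
    }


def _default_qa_coefficients() -> dict:
    """Logit coefficients for >= 1 past-year quit attempt.

    Log odds-ratios from the published pooled model; age enters per 10 years
    (OR 0.95 per decade) and calendar time per year (OR 0.77 per year).
    The sex x education interaction is the model's true intersection.
    The intercept is calibrated so the overall prevalence of a past-year
    quit attempt is 18.3% under the default covariate margins.
    """
    lg = math.log
    return {
        "intercept": -0.7727,
        "urges": {"none": lg(2.54), "light": lg(0.90), "medium_strong": 0.0,
                  "strong": lg(1.06), "very_strong": lg(0.80),
                  "extremely_strong": lg(1.47)},
        "year_per_year": lg(0.77),
        "age_per_10y": lg(0.95),
        "female": lg(1.26),
        "education": {"low": 0.0, "middle": lg(1.10), "high": lg(1.42)},
        "region": {"rural": 0.0, "urban": lg(1.02), "metropolitan": lg(0.99)},
        "income": lg(0.83),
        "female_x_education": {"middle": lg(0.94), "high": lg(0.67)},
        "positive_count_props": (0.7, 0.2, 0.1),   # counts 1, 2, 3 given >= 1
    }


def _default_missingness_params() -> dict:
    return {
        # marginal missing rates among eligible rows
        "rates": {"education": 0.014, "urges": 0.012, "mtss_level": 0.015,
                  "n_quit_attempts": 0.046, "income": 0.0002},
        # extra log-odds of missingness for male x high education on
        # smoking-habit variables (selective MAR)
        "male_high_increment": 0.5,
        "smoking_habit_vars": ("urges", "mtss_level", "n_quit_attempts"),
    }


@dataclass
class GeneratorConfig:
    """Everything needed to synthesise one survey table, incl. the seed."""

    n_records: int = STUDY_COUNTS["past_year_smokers"]
    year_range: tuple[int, int] = (2016, 2020)
    covariate_params: dict = field(default_factory=_default_covariate_params)
    mtss_coefficients: dict = field(default_factory=_default_mtss_coefficients)
    mtss_expansion: dict = field(default_factory=_default_mtss_expansion)
    qa_coefficients: dict = field(default_factory=_default_qa_coefficients)
    missingness_params: dict = field(default_factory=_default_missingness_params)
    seed: int = 0

    def __post_init__(self):
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range must be an ordered pair")
        cp = self.covariate_params
        for key in ("education", "region", "urges"):
            tot = sum(cp[key].values())
            if abs(tot - 1.0) > 1e-12:
                raise ValueError(f"{key} proportions must sum to 1, got {tot}")
        if not (0 <= cp["p_female"] <= 1 and 0 <= cp["p_current"] <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if cp["age_min"] >= cp["age_max"] or cp["income_min"] >= cp["income_max"]:
            raise ValueError("bounds must be ordered")
        for v, r in self.missingness_params["rates"].items():
            if not 0 <= r <= 1:
                raise ValueError(f"missingness rate for {v} outside [0, 1]")
        for cat, props in self.mtss_expansion.items():
            if abs(sum(props) - 1.0) > 1e-12:
                raise ValueError(f"mtss_expansion[{cat}] must sum to 1")

    def provenance_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _truncnorm_underlying(mean: float, sd: float, a: float, b: float):
    """Underlying normal (mu, sigma) whose [a, b]-truncation has the target moments."""
    from scipy import optimize

    def moments(params):
        mu, lsig = params
        sig = math.exp(lsig)
        m, v = stats.truncnorm.stats((a - mu) / sig, (b - mu) / sig,
                                     loc=mu, scale=sig, moments="mv")
        return [m - mean, math.sqrt(v) - sd]

    sol = optimize.fsolve(moments, [mean, math.log(sd)], full_output=False)
    return float(sol[0]), float(math.exp(sol[1]))


def _rng(config: GeneratorConfig, stream: str) -> np.random.Generator:
    # independent, reproducible stream per generation stage
    h = int.from_bytes(hashlib.sha256(
        f"{config.seed}:{stream}".encode()).digest()[:8], "big")
    return np.random.default_rng(h)


def generate_covariates(config: GeneratorConfig) -> pd.DataFrame:
    """Draw the covariate block: one row per respondent, no outcomes yet."""
    rng = _rng(config, "covariates")
    n = config.n_records
    cp = config.covariate_params

    a, b = cp["age_min"], cp["age_max"]
    mu, sd = _truncnorm_underlying(cp["age_mean"], cp["age_sd"], a, b)
    age = stats.truncnorm.rvs((a - mu) / sd, (b - mu) / sd, loc=mu, scale=sd,
                              size=n, random_state=rng)

    sex = np.where(rng.random(n) < cp["p_female"], "female", "male")

    def cat_draw(props: dict):
        levels = list(props)
        return rng.choice(levels, size=n, p=[props[l] for l in levels])

    education = cat_draw(cp["education"])
    region = cat_draw(cp["region"])
    urges = cat_draw(cp["urges"])

    # right-skewed income: moment-matched gamma, redrawn into [0, 7]
    m, s = cp["income_mean"], cp["income_sd"]
    shape = (m / s) ** 2
    scale = s * s / m
    income = rng.gamma(shape, scale, size=n)
    bad = (income < cp["income_min"]) | (income > cp["income_max"])
    while bad.any():
        income[bad] = rng.gamma(shape, scale, size=int(bad.sum()))
        bad = (income < cp["income_min"]) | (income > cp["income_max"])

    year = rng.integers(config.year_range[0], config.year_range[1] + 1, size=n)
    smoker_status = np.where(rng.random(n) < cp["p_current"], "current", "recent_ex")

    return pd.DataFrame({
        "id": np.arange(n, dtype=int),
        "year": year.astype(int),
        "age": age,
        "sex": sex,
        "education": education,
        "region": region,
        "income": income,
        "urges": urges,
        "mtss_level": np.full(n, np.nan),
        "n_quit_attempts": np.full(n, np.nan),
        "smoker_status": smoker_status,
    })


def _mtss_linear_predictor(df: pd.DataFrame, coefs: dict) -> np.ndarray:
    age_b = rcs_basis(df["age"].to_numpy(dtype=float), _AGE_KNOTS)
    income = df["income"].to_numpy(dtype=float)
    eta = np.full(len(df), coefs["intercept"], dtype=float)
    eta += df["urges"].map(coefs["urges"]).to_numpy(dtype=float)
    eta += df["year"].map(coefs["year"]).fillna(0.0).to_numpy(dtype=float)
    eta += np.where(df["sex"].to_numpy() == "female", coefs["female"], 0.0)
    eta += df["education"].map(coefs["education"]).to_numpy(dtype=float)
    eta += df["region"].map(coefs["region"]).to_numpy(dtype=float)
    eta += coefs["income"] * income
    eta += coefs["age_linear_per10"] * df["age"].to_numpy(dtype=float) / 10.0
    basis = np.column_stack([age_b[:, 0] / 10.0, age_b[:, 1], age_b[:, 2]])
    eta += basis @ np.asarray(coefs["age_basis"])
    eta += (basis @ np.asarray(coefs["age_basis_x_income"])) * income
    return eta


def generate_mtss(table: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Draw the 7-level motivation outcome for current smokers.

    A 3-category latent outcome (absence / unspecific / motivation) comes
    from the configured multinomial-logit model; categories 2 and 3 are then
    expanded to scale levels {2,3} and {4,5,6,7} with the configured
    conditional proportions.  Recent ex-smokers are never assessed and keep
    a missing value.
    """
    for name in ("age", "income", "urges", "education", "region", "sex", "year"):
        if name not in table.columns:
            raise ValueError(f"covariate {name!r} absent from the table")
    rng = _rng(config, "mtss")
    df = table.copy()
    cur = df["smoker_status"].to_numpy() == "current"
    sub = df.loc[cur]
    eta2 = _mtss_linear_predictor(sub, config.mtss_coefficients["unspecific"])
    eta3 = _mtss_linear_predictor(sub, config.mtss_coefficients["motivation"])
    E = np.column_stack([np.zeros(len(sub)), eta2, eta3])
    E -= E.max(axis=1, keepdims=True)
    P = np.exp(E)
    P /= P.sum(axis=1, keepdims=True)
    u = rng.random(len(sub))
    cat = 1 + (u > P[:, 0]).astype(int) + (u > P[:, 0] + P[:, 1]).astype(int)

    level = np.empty(len(sub), dtype=float)
    level_sets = {1: (1,), 2: (2, 3), 3: (4, 5, 6, 7)}
    for c, levels in level_sets.items():
        m = cat == c
        if m.any():
            props = np.asarray(config.mtss_expansion[c], dtype=float)
            if len(props) != len(levels):
                raise ValueError(f"mtss_expansion[{c}] needs {len(levels)} proportions")
            level[m] = rng.choice(levels, size=int(m.sum()), p=props)
    vals = df["mtss_level"].to_numpy(dtype=float)
    vals[cur] = level
    df["mtss_level"] = vals
    return df


def generate_qa(table: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Draw past-year quit attempts from the configured logistic model."""
    for name in ("age", "income", "urges", "education", "region", "sex", "year"):
        if name not in table.columns:
            raise ValueError(f"covariate {name!r} absent from the table")
    rng = _rng(config, "qa")
    df = table.copy()
    c = config.qa_coefficients
    eta = np.full(len(df), c["intercept"], dtype=float)
    eta += df["urges"].map(c["urges"]).to_numpy(dtype=float)
    eta += c["year_per_year"] * (df["year"].to_numpy(dtype=float)
                                 - config.year_range[0])
    eta += c["age_per_10y"] * df["age"].to_numpy(dtype=float) / 10.0
    female = df["sex"].to_numpy() == "female"
    eta += np.where(female, c["female"], 0.0)
    eta += df["education"].map(c["education"]).to_numpy(dtype=float)
    eta += df["region"].map(c["region"]).to_numpy(dtype=float)
    eta += c["income"] * df["income"].to_numpy(dtype=float)
    edu = df["education"].to_numpy()
    for lev, b in c["female_x_education"].items():
        eta += np.where(female & (edu == lev), b, 0.0)
    p = 1.0 / (1.0 + np.exp(-eta))
    any_qa = rng.random(len(df)) < p
    counts = np.zeros(len(df))
    kpos = int(any_qa.sum())
    if kpos:
        counts[any_qa] = rng.choice([1, 2, 3], size=kpos,
                                    p=np.asarray(c["positive_count_props"]))
    df["n_quit_attempts"] = counts
    return df


def inject_missingness(table: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Set cells missing under a MAR mechanism.

    Each variable's missingness follows a logit model with an intercept
    calibrated to the configured marginal rate and an additive log-odds
    increment for male x high-education respondents on the smoking-habit
    variables (selective item non-response).  All masks are computed from
    the complete table before any cell is blanked.
    """
    rng = _rng(config, "missing")
    df = table.copy()
    mp = config.missingness_params
    inc = float(mp["male_high_increment"])
    habit = set(mp["smoking_habit_vars"])
    male_high = ((df["sex"].to_numpy() == "male")
                 & (df["education"].to_numpy() == "high"))

    def logit(p):
        return math.log(p / (1 - p))

    for var, rate in mp["rates"].items():
        if rate <= 0:
            continue
        if var == "mtss_level":
            eligible = df["smoker_status"].to_numpy() == "current"
        else:
            eligible = np.ones(len(df), dtype=bool)
        bump = inc if var in habit else 0.0
        share = float((male_high & eligible).sum()) / max(int(eligible.sum()), 1)
        b0 = logit(rate) - bump * share
        eta = b0 + bump * male_high[eligible]
        p = 1.0 / (1.0 + np.exp(-eta))
        miss = rng.random(int(eligible.sum())) < p
        col_idx = np.flatnonzero(eligible)[miss]
        target = "income" if var == "income" else var
        if df[target].dtype == object:
            col = df[target].astype(object)
            col.iloc[col_idx] = np.nan
            df[target] = col
        else:
            vals = df[target].to_numpy(dtype=float)
            vals[col_idx] = np.nan
            df[target] = vals
    return df


def recode_outcomes(table: pd.DataFrame) -> pd.DataFrame:
    """Add the collapsed motivation category and the binary quit-attempt flag.

    Motivation scale level 1 -> "absence", 2-3 -> "unspecific", 4-7 ->
    "motivation"; quit attempts >= 1 -> "yes", 0 -> "no".  Missing raw values
    propagate.  Idempotent.
    """
    df = table.copy()
    lev = df["mtss_level"].to_numpy(dtype=float)
    finite = np.isfinite(lev)
    if np.any((lev[finite] < 1) | (lev[finite] > 7)):
        raise ValueError("mtss_level outside 1..7")
    mtss3 = np.full(len(df), np.nan, dtype=object)
    mtss3[finite & (lev == 1)] = "absence"
    mtss3[finite & (lev >= 2) & (lev <= 3)] = "unspecific"
    mtss3[finite & (lev >= 4)] = "motivation"
    df["mtss3"] = mtss3

    nqa = df["n_quit_attempts"].to_numpy(dtype=float)
    qa = np.full(len(df), np.nan, dtype=object)
    qa[np.isfinite(nqa) & (nqa >= 1)] = "yes"
    qa[np.isfinite(nqa) & (nqa == 0)] = "no"
    df["qa"] = qa
    return df


def split_learning_validation(table: pd.DataFrame, fraction: float, seed: int):
    """Random partition into learning and validation tables.

    The learning size is ``round(n * fraction)`` with exact (decimal)
    arithmetic and round-half-to-even, so e.g. n = 13245 at 70% gives
    9272 / 3973.  Disjoint by construction; union equals the input.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie strictly between 0 and 1")
    n = len(table)
    n_learn = int(round(Fraction(n) * Fraction(str(float(fraction)))))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    learn = table.iloc[np.sort(perm[:n_learn])].reset_index(drop=True)
    valid = table.iloc[np.sort(perm[n_learn:])].reset_index(drop=True)
    return learn, valid


def count_full_strata(levels_per_dimension) -> int:
    """Number of cells in a full cross-stratification (product of level counts)."""
    levels = list(levels_per_dimension)
    if not levels:
        raise ValueError("need at least one dimension")
    if any(int(l) != l or l < 1 for l in levels):
        raise ValueError("level counts must be positive integers")
    return math.prod(int(l) for l in levels)


def generate_table(config: GeneratorConfig, missingness: bool = True) -> pd.DataFrame:
    """Covariates -> motivation outcome -> quit attempts [-> missingness]."""
    df = generate_covariates(config)
    df = generate_mtss(df, config)
    df = generate_qa(df, config)
    if missingness:
        df = inject_missingness(df, config)
    return df
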