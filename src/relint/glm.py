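"""Binary- and multinomial-logistic model fitting from a declarative spec.

``ModelSpec`` describes one candidate regression — which covariates enter,
in which functional form (categorical dummies, linear, or a restricted cubic
spline with 3-5 knots), and which pairwise interactions are included.  The
design matrix is built deterministically from the spec: dummy coding against
fixed reference levels, spline columns with knots frozen at learning-data
quantiles, interaction columns as elementwise products of the member terms'
columns.  Fitting is plain maximum likelihood by Newton-Raphson with
step-halving; the covariance is the inverse observed information.

Rows with a missing value in any used column are dropped (complete-case per
dataset; multiple imputation upstream is responsible for missing data).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .splines import SplineSpec, place_knots, rcs_basis

__all__ = [
    "Term", "ModelSpec", "FitResult", "DesignData",
    "build_design", "fit_logistic", "fit_multinomial", "fit_model",
    "bic", "lr_test", "predict_probs",
]

#: Canonical level order for each categorical covariate (first = default ref).
LEVELS: dict[str, list[str]] = {
    "sex": ["male", "female"],
    "education": ["low", "middle", "high"],
    "region": ["rural", "urban", "metropolitan"],
    "urges": ["none", "light", "medium_strong", "strong",
              "very_strong", "extremely_strong"],
    "smoker_status": ["current", "recent_ex"],
}

DEFAULT_REFERENCES: dict[str, str] = {
    "sex": "male",
    "education": "low",
    "region": "rural",
    "urges": "medium_strong",
    "year": "2016",
}

#: Outcome encodings.  mtss3 is multinomial with "absence" as reference.
MTSS3_LEVELS = ["absence", "unspecific", "motivation"]

VALID_FORMS = {"categorical", "linear", "rcs3", "rcs4", "rcs5"}


@dataclass(frozen=True)
class Term:
    name: str
    form: str  # categorical | linear | rcs3 | rcs4 | rcs5

    def __post_init__(self):
        if self.form not in VALID_FORMS:
            raise ValueError(f"unknown term form {self.form!r}")

    @property
    def spline_k(self) -> int | None:
        return int(self.form[3:]) if self.form.startswith("rcs") else None


@dataclass
class ModelSpec:
    """Declarative description of one candidate regression."""

    outcome: str  # "mtss3" or "qa"
    terms: list[Term]
    interactions: list[tuple[str, str]] = field(default_factory=list)
    reference_levels: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_REFERENCES))
    spline_specs: dict[str, SplineSpec] = field(default_factory=dict)

    def __post_init__(self):
        if self.outcome not in {"mtss3", "qa"}:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        names = [t.name for t in self.terms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate terms in spec")
        self.interactions = [tuple(p) for p in self.interactions]
        for a, b in self.interactions:
            if a not in names or b not in names:
                raise ValueError(
                    f"interaction ({a},{b}) violates hierarchy: members must be terms")

    def term(self, name: str) -> Term:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    @property
    def term_names(self) -> list[str]:
        return [t.name for t in self.terms]

    def drop_interactions(self) -> "ModelSpec":
        return ModelSpec(outcome=self.outcome, terms=list(self.terms),
                         interactions=[], reference_levels=dict(self.reference_levels),
                         spline_specs=dict(self.spline_specs))

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "terms": [[t.name, t.form] for t in self.terms],
            "interactions": [list(p) for p in self.interactions],
            "reference_levels": dict(self.reference_levels),
            "spline_specs": {k: v.to_dict() for k, v in self.spline_specs.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            outcome=d["outcome"],
            terms=[Term(n, f) for n, f in d["terms"]],
            interactions=[tuple(p) for p in d["interactions"]],
            reference_levels=dict(d["reference_levels"]),
            spline_specs={k: SplineSpec.from_dict(v)
                          for k, v in d.get("spline_specs", {}).items()},
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "ModelSpec":
        return cls.from_dict(json.loads(s))


@dataclass
class DesignData:
    X: np.ndarray              # (n, p) incl. intercept column
    y: np.ndarray              # binary 0/1 or category codes 0..K-1
    column_names: list[str]
    index: np.ndarray          # positional indices of rows kept (complete cases)


@dataclass
class FitResult:
    spec: ModelSpec
    coefficients: np.ndarray   # (p,) binary / (K-1, p) multinomial
    covariance: np.ndarray     # (q, q) over all free parameters
    loglik: float
    n_obs: int
    n_params: int
    converged: bool
    separation: bool
    column_names: list[str]
    contrast_names: list[str]  # ["qa"] or ["unspecific", "motivation"]

    @property
    def spline_specs(self) -> dict[str, SplineSpec]:
        return self.spec.spline_specs


# ---------------------------------------------------------------------------
# design construction


def _term_columns(df: pd.DataFrame, term: Term, spec: ModelSpec):
    """Columns (values, names) of one main-effect term."""
    name = term.name
    if term.form == "categorical":
        vals = df[name].astype(str)
        levels = LEVELS.get(name)
        if levels is None:  # e.g. year as categorical: sorted observed values
            levels = sorted(vals.dropna().unique())
        ref = str(spec.reference_levels.get(name, levels[0]))
        if ref not in levels:
            levels = [ref] + [l for l in levels if l != ref]
        seen = set(vals.dropna().unique())
        unknown = seen - set(levels)
        if unknown:
            raise ValueError(f"unseen level(s) {sorted(unknown)} for covariate {name!r}")
        cols, names = [], []
        for lev in levels:
            if lev == ref:
                continue
            cols.append((vals == lev).to_numpy(dtype=float))
            names.append(f"{name}[{lev}]")
        return cols, names
    x = df[name].to_numpy(dtype=float)
    if term.form == "linear":
        if name == "year":
            # calendar time per year, centred at the reference year
            ref = float(spec.reference_levels.get("year", x.min()))
            return [x - ref], [name]
        return [x], [name]
    # spline
    sspec = spec.spline_specs.get(name)
    if sspec is None:
        raise ValueError(f"no frozen knots for spline term {name!r}; "
                         "build the design with freeze_knots=True first")
    B = rcs_basis(x, sspec)
    names = [name] + [name + "'" * j for j in range(1, B.shape[1])]
    return [B[:, j] for j in range(B.shape[1])], names


def freeze_knots(df: pd.DataFrame, spec: ModelSpec) -> ModelSpec:
    """Compute and freeze knot locations for every spline term (learning data)."""
    for t in spec.terms:
        k = t.spline_k
        if k is not None and t.name not in spec.spline_specs:
            spec.spline_specs[t.name] = place_knots(df[t.name].to_numpy(dtype=float), k)
    return spec


def _outcome_vector(df: pd.DataFrame, outcome: str):
    if outcome == "qa":
        col = df["qa"].astype(str)
        ok = col.isin(["yes", "no"])
        y = (col == "yes").to_numpy(dtype=float)
        return y, ok.to_numpy()
    col = df["mtss3"].astype(str)
    ok = col.isin(MTSS3_LEVELS)
    codes = pd.Categorical(col, categories=MTSS3_LEVELS).codes
    return codes.astype(int), ok.to_numpy()


def build_design(df: pd.DataFrame, spec: ModelSpec) -> DesignData:
    """Design matrix + outcome vector for ``spec`` on ``df`` (complete cases).

    Spline knots must already be frozen in the spec (see ``freeze_knots``);
    this is what lets validation data reuse learning-data knots.
    """
    y_all, y_ok = _outcome_vector(df, spec.outcome)
    mask = y_ok.copy()
    for t in spec.terms:
        col = df[t.name]
        if t.form == "categorical":
            mask &= col.notna().to_numpy()
        else:
            mask &= np.isfinite(col.to_numpy(dtype=float))
    sub = df.loc[mask]
    idx = np.flatnonzero(mask)

    cols: list[np.ndarray] = [np.ones(len(sub))]
    names: list[str] = ["(Intercept)"]
    per_term: dict[str, tuple[list[np.ndarray], list[str]]] = {}
    for t in spec.terms:
        c, n = _term_columns(sub, t, spec)
        per_term[t.name] = (c, n)
        cols.extend(c)
        names.extend(n)
    for a, b in spec.interactions:
        ca, na = per_term[a]
        cb, nb = per_term[b]
        for xa, la in zip(ca, na):
            for xb, lb in zip(cb, nb):
                cols.append(xa * xb)
                names.append(f"{la}:{lb}")
    X = np.column_stack(cols) if cols else np.empty((len(sub), 0))
    return DesignData(X=X, y=y_all[mask], column_names=names, index=idx)


# ---------------------------------------------------------------------------
# likelihoods


def _logistic_loglik(X, y, beta):
    eta = X @ beta
    # log sigma(eta)*y + log sigma(-eta)*(1-y), numerically stable
    return float(-np.sum(np.logaddexp(0.0, -eta) * y + np.logaddexp(0.0, eta) * (1 - y)))


def _multinomial_probs(X, B):
    """B: (K-1, p).  Returns (n, K) probabilities, reference = category 0."""
    eta = X @ B.T                       # (n, K-1)
    full = np.column_stack([np.zeros(len(X)), eta])
    full -= full.max(axis=1, keepdims=True)
    ex = np.exp(full)
    return ex / ex.sum(axis=1, keepdims=True)


def _multinomial_loglik(X, y, B):
    P = _multinomial_probs(X, B)
    return float(np.sum(np.log(np.clip(P[np.arange(len(y)), y], 1e-300, None))))


def _check_rank(X):
    # Cholesky of X'X fails for rank deficiency (p is small, this is cheap).
    XtX = X.T @ X
    try:
        np.linalg.cholesky(XtX + np.eye(X.shape[1]) * 0.0)
    except np.linalg.LinAlgError:
        raise ValueError("design matrix is rank deficient") from None
    # guard against near-singular designs the Cholesky tolerates
    if np.linalg.cond(XtX) > 5e13:
        raise ValueError("design matrix is rank deficient (ill-conditioned)")


def _separation(X, beta, scale=None):
    if scale is None:
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
    return bool(np.any(np.abs(beta * scale) > 15.0))


def fit_logistic(X, y, spec: ModelSpec | None = None,
                 column_names: list[str] | None = None,
                 penalty: float = 0.0, beta0: np.ndarray | None = None,
                 max_iter: int = 100, tol_score: float = 1e-8,
                 tol_loglik: float = 1e-10) -> FitResult:
    """ML logistic fit by Newton-Raphson with step-halving.

    Converges when every score coordinate is below ``tol_score`` or the
    relative log-likelihood change is below ``tol_loglik``.  ``penalty`` adds
    an optional tiny ridge (used only by the imputation engine for stability;
    the analysis models use ``penalty=0``).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.all((y == 0.0) | (y == 1.0)):
        raise ValueError("y must be binary 0/1")
    n, p = X.shape
    if penalty == 0.0:
        _check_rank(X)
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    ll = _logistic_loglik(X, y, beta) - 0.5 * penalty * beta @ beta
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1 - mu)
        score = X.T @ (y - mu) - penalty * beta
        H = (X.T * w) @ X + penalty * np.eye(p)
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            H = H + 1e-8 * np.eye(p)
            step = np.linalg.solve(H, score)
        # step-halving
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            ll_new = _logistic_loglik(X, y, cand) - 0.5 * penalty * cand @ cand
            if ll_new >= ll - 1e-12:
                break
            t /= 2
        beta = beta + t * step
        ll_prev, ll = ll, ll_new
        if np.max(np.abs(score)) < tol_score or abs(ll - ll_prev) < tol_loglik * (abs(ll_prev) + 1e-12):
            converged = True
            break
    eta = X @ beta
    mu = expit(eta)
    w = mu * (1 - mu)
    H = (X.T * w) @ X + penalty * np.eye(p)
    cov = np.linalg.inv(H)
    return FitResult(
        spec=spec, coefficients=beta, covariance=cov,
        loglik=_logistic_loglik(X, y, beta), n_obs=n, n_params=p,
        converged=converged, separation=_separation(X, beta),
        column_names=list(column_names) if column_names else [f"x{j}" for j in range(p)],
        contrast_names=["qa"],
    )


def fit_multinomial(X, y, spec: ModelSpec | None = None,
                    column_names: list[str] | None = None,
                    n_categories: int | None = None,
                    penalty: float = 0.0, beta0: np.ndarray | None = None,
                    max_iter: int = 200, tol_score: float = 1e-8,
                    tol_loglik: float = 1e-10) -> FitResult:
    """Joint ML multinomial-logit fit, reference = category 0.

    Coefficients are a ``(K-1, p)`` matrix; the covariance covers the
    ``(K-1)*p`` free parameters in row-major (contrast-by-contrast) order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n, p = X.shape
    K = int(n_categories if n_categories is not None else y.max() + 1)
    if K < 2:
        raise ValueError("need at least 2 outcome categories")
    if penalty == 0.0:
        _check_rank(X)
    Y = np.zeros((n, K))
    Y[np.arange(n), y] = 1.0
    q = (K - 1) * p
    B = (np.zeros((K - 1, p)) if beta0 is None
         else np.asarray(beta0, dtype=float).reshape(K - 1, p).copy())
    ll = _multinomial_loglik(X, y, B) - 0.5 * penalty * np.sum(B * B)
    converged = False
    for _ in range(max_iter):
        P = _multinomial_probs(X, B)
        score = np.empty(q)
        for j in range(1, K):
            score[(j - 1) * p:j * p] = X.T @ (Y[:, j] - P[:, j]) - penalty * B[j - 1]
        H = np.empty((q, q))
        for j in range(1, K):
            for k in range(j, K):
                w = P[:, j] * ((1.0 if j == k else 0.0) - P[:, k])
                blk = (X.T * w) @ X
                if j == k:
                    blk = blk + penalty * np.eye(p)
                H[(j - 1) * p:j * p, (k - 1) * p:k * p] = blk
                H[(k - 1) * p:k * p, (j - 1) * p:j * p] = blk.T
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(H + 1e-8 * np.eye(q), score)
        t = 1.0
        for _ in range(30):
            cand = B + t * step.reshape(K - 1, p)
            ll_new = _multinomial_loglik(X, y, cand) - 0.5 * penalty * np.sum(cand * cand)
            if ll_new >= ll - 1e-12:
                break
            t /= 2
        B = B + t * step.reshape(K - 1, p)
        ll_prev, ll = ll, ll_new
        if np.max(np.abs(score)) < tol_score or abs(ll - ll_prev) < tol_loglik * (abs(ll_prev) + 1e-12):
            converged = True
            break
    P = _multinomial_probs(X, B)
    H = np.empty((q, q))
    for j in range(1, K):
        for k in range(j, K):
            w = P[:, j] * ((1.0 if j == k else 0.0) - P[:, k])
            blk = (X.T * w) @ X
            if j == k:
                blk = blk + penalty * np.eye(p)
            H[(j - 1) * p:j * p, (k - 1) * p:k * p] = blk
            H[(k - 1) * p:k * p, (j - 1) * p:j * p] = blk.T
    cov = np.linalg.inv(H)
    names = list(column_names) if column_names else [f"x{j}" for j in range(p)]
    contrast_names = (MTSS3_LEVELS[1:] if K == 3 else
                      [f"cat{j}" for j in range(1, K)])
    return FitResult(
        spec=spec, coefficients=B, covariance=cov,
        loglik=_multinomial_loglik(X, y, B), n_obs=n, n_params=q,
        converged=converged,
        separation=any(_separation(X, B[j]) for j in range(K - 1)),
        column_names=names, contrast_names=contrast_names,
    )


def fit_model(df: pd.DataFrame, spec: ModelSpec, freeze: bool = True) -> FitResult:
    """Build the design from ``spec`` on ``df`` and fit the matching family."""
    if freeze:
        freeze_knots(df, spec)
    d = build_design(df, spec)
    if spec.outcome == "qa":
        return fit_logistic(d.X, d.y, spec=spec, column_names=d.column_names)
    return fit_multinomial(d.X, d.y, spec=spec, column_names=d.column_names,
                           n_categories=len(MTSS3_LEVELS))


def bic(fit: FitResult) -> float:
    """Bayesian information criterion: -2 loglik + n_params * ln(n_obs)."""
    return -2.0 * fit.loglik + fit.n_params * np.log(fit.n_obs)


def lr_test(full: FitResult, reduced: FitResult):
    """Likelihood-ratio test of a reduced model nested in a full model."""
    if full.n_obs != reduced.n_obs:
        raise ValueError("LR test requires both fits on the same rows")
    if not set(reduced.column_names) <= set(full.column_names):
        raise ValueError("reduced model is not nested in the full model")
    df = full.n_params - reduced.n_params
    if df < 0:
        raise ValueError("reduced model has more parameters than the full model")
    stat = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return stat, df, p


def predict_probs(fit: FitResult, df: pd.DataFrame) -> np.ndarray:
    """Predicted probabilities on new data using the fit's frozen knots.

    Binary: returns ``(n,)`` success probabilities.  Multinomial: ``(n, K)``
    rows summing to 1.  Rows with missing covariates are dropped (use
    ``build_design`` directly if alignment with an index is needed).
    """
    d = build_design(df, fit.spec)
    return predict_probs_design(fit, d.X)


def predict_probs_design(fit: FitResult, X: np.ndarray) -> np.ndarray:
    if fit.coefficients.ndim == 1:
        return expit(X @ fit.coefficients)
    return _multinomial_probs(X, fit.coefficients)
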