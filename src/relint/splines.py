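"""Restricted cubic spline (RCS) bases and spline-aware odds-ratio contrasts.

A restricted cubic spline with knots ``t_1 < ... < t_k`` is a piecewise-cubic
function of a continuous covariate constrained to be *linear* beyond the
boundary knots.  It is the standard device for letting age or income enter a
regression model non-linearly without categorising them.  The basis used here
is the truncated-power parameterisation popularised by Harrell: the first
column is the covariate itself and the ``k - 2`` nonlinear columns are

    C_j(x) = [ (x - t_j)+^3
               - (x - t_{k-1})+^3 * (t_k - t_j) / (t_k - t_{k-1})
               + (x - t_k)+^3   * (t_{k-1} - t_j) / (t_k - t_{k-1})
             ] / (t_k - t_1)^2                       for j = 1 .. k-2,

which have two continuous derivatives everywhere and vanish identically for
``x <= t_1``.  Division by ``(t_k - t_1)^2`` keeps the nonlinear columns on a
scale comparable to the linear one; it rescales coefficients but leaves
fitted values unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SplineSpec", "place_knots", "rcs_basis", "evaluate_contrast"]

#: Harrell's default knot quantiles, by number of knots.
HARRELL_QUANTILES: dict[int, tuple[float, ...]] = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
}


@dataclass(frozen=True)
class SplineSpec:
    """Frozen knot locations for one covariate.

    Freezing the knots (rather than recomputing them per dataset) is what
    allows a model trained on learning data to be applied coherently to
    validation data.
    """

    knots: tuple[float, ...]

    def __post_init__(self) -> None:
        knots = tuple(float(t) for t in self.knots)
        if len(knots) < 3:
            raise ValueError("an RCS needs at least 3 knots")
        if not all(a < b for a, b in zip(knots, knots[1:])):
            raise ValueError(f"knots must be strictly increasing, got {knots}")
        object.__setattr__(self, "knots", knots)

    @property
    def k(self) -> int:
        return len(self.knots)

    @property
    def normalization(self) -> float:
        """Scale constant ``(t_k - t_1)^2`` applied to nonlinear columns."""
        return (self.knots[-1] - self.knots[0]) ** 2

    def to_dict(self) -> dict:
        return {"knots": list(self.knots)}

    @classmethod
    def from_dict(cls, d: dict) -> "SplineSpec":
        return cls(knots=tuple(d["knots"]))


def place_knots(x, k: int) -> SplineSpec:
    """Place ``k`` knots at Harrell's default quantiles of the observed values.

    Quantiles use the linear-interpolation (type-7) estimator.  Missing values
    are ignored.  Raises ``ValueError`` when the data cannot support ``k``
    distinct knots (e.g. a constant covariate).
    """
    if k not in HARRELL_QUANTILES:
        raise ValueError(f"k must be one of {sorted(HARRELL_QUANTILES)}, got {k}")
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if np.unique(x).size < k:
        raise ValueError(f"need at least {k} distinct finite values to place {k} knots")
    knots = np.quantile(x, HARRELL_QUANTILES[k], method="linear")
    if not np.all(np.diff(knots) > 0):
        raise ValueError(
            f"degenerate data: quantile knots are not strictly increasing ({knots})"
        )
    return SplineSpec(knots=tuple(knots))


def rcs_basis(x, spec: SplineSpec) -> np.ndarray:
    """Evaluate the RCS design columns at ``x``.

    Returns an ``(n, k - 1)`` matrix: column 0 is ``x`` itself, columns
    ``1 .. k-2`` are the restricted truncated-power terms.  The implied
    function is linear for ``x <= t_1`` and ``x >= t_k``.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(spec.knots)
    k = t.size
    out = np.empty(x.shape + (k - 1,), dtype=float)
    out[..., 0] = x

    def pos3(v):
        return np.clip(v, 0.0, None) ** 3

    denom = t[k - 1] - t[k - 2]
    norm = spec.normalization
    for j in range(k - 2):
        out[..., j + 1] = (
            pos3(x - t[j])
            - pos3(x - t[k - 2]) * (t[k - 1] - t[j]) / denom
            + pos3(x - t[k - 1]) * (t[k - 2] - t[j]) / denom
        ) / norm
    return out


def evaluate_contrast(fit, covariate: str, values, reference: float,
                      alpha: float = 0.05):
    """Odds-ratio contrasts of a continuous (possibly spline-coded) covariate.

    For each value ``v`` the contrast is ``OR = exp(eta(v) - eta(ref))`` where
    ``eta`` collects every design column belonging to ``covariate`` (its linear
    and nonlinear spline columns).  Interaction columns involving the covariate
    contribute with the partner held at its reference (0 for a centred
    continuous partner, the reference level for a categorical one) and hence
    drop out.  The CI comes from the variance of the linear combination.

    For a multinomial fit one contrast per non-reference outcome category is
    returned.  Rows evaluated outside the observed covariate range (the linear
    tails of the spline) carry ``extrapolated=True``.

    Returns a list of dict rows with keys ``category``, ``value``, ``or``,
    ``ci_low``, ``ci_high``, ``extrapolated``.
    """
    from scipy import stats

    values = np.asarray(values, dtype=float)
    cols = [i for i, cn in enumerate(fit.column_names)
            if ":" not in cn
            and (cn == covariate or cn.startswith(covariate + "'"))]
    if not cols:
        raise ValueError(f"fit has no design columns for covariate {covariate!r}")

    spec = fit.spline_specs.get(covariate)
    if spec is not None:
        basis_v = rcs_basis(values, spec)
        basis_r = rcs_basis(np.array([reference]), spec)[0]
        lo, hi = spec.knots[0], spec.knots[-1]
    else:
        basis_v = values[:, None]
        basis_r = np.array([float(reference)])
        lo, hi = -np.inf, np.inf
    delta = basis_v - basis_r  # (n_values, n_cols)
    if delta.shape[1] != len(cols):
        raise ValueError("design columns do not match the covariate's basis")

    z = stats.norm.ppf(1 - alpha / 2)
    coef = np.atleast_2d(fit.coefficients)  # (n_contrasts, p)
    p = coef.shape[1]
    rows = []
    for ci_idx, cat in enumerate(fit.contrast_names):
        beta = coef[ci_idx]
        for vi, v in enumerate(values):
            d_full = np.zeros(coef.size)
            for bj, colj in enumerate(cols):
                d_full[ci_idx * p + colj] = delta[vi, bj]
            est = float(delta[vi] @ beta[cols])
            var = float(d_full @ fit.covariance @ d_full)
            se = np.sqrt(max(var, 0.0))
            rows.append({
                "category": cat,
                "value": float(v),
                "log_or": est,
                "se": se,
                "or": float(np.exp(est)),
                "ci_low": float(np.exp(est - z * se)),
                "ci_high": float(np.exp(est + z * se)),
                "extrapolated": bool(v < lo or v > hi),
            })
    return rows
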