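"""Per-unit-operation regression models and tolerance-interval factors.

Each unit operation (UO) is described by an ordinary-least-squares model of
its pool CQA (an impurity concentration) as a function of normalized process
parameters and, for downstream UOs, the load carried over from the previous
UO.  Model scope is chosen by bi-directional stepwise selection on partial
t-test p-values.  Prediction uncertainty is widened by the normal-population
tolerance-interval factor

    sqrt( nu * (1 + 1/N) / chi2_{alpha, nu} ),    nu = N - p,

which converges to 1 from above as the number of training runs N grows; it
is the mechanism by which adding runs (of any kind) tightens the simulated
drug-substance distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import ModelSpec, build_model_matrix

__all__ = [
    "ToleranceSettings",
    "UOModel",
    "fit_uo_model",
    "stepwise_select",
    "tolerance_factor",
    "tolerance_interval",
]

# default bi-directional stepwise thresholds
P_ENTER = 0.25
P_REMOVE = 0.05

_RANK_TOL = 1e-8


@dataclass(frozen=True)
class ToleranceSettings:
    """Coverage proportion and confidence level of the tolerance interval."""

    coverage: float = 0.99
    confidence: float = 0.05  # the alpha of the lower chi-square quantile

    def __post_init__(self):
        if not (0.0 < self.coverage < 1.0):
            raise ValueError("coverage must be in (0, 1)")
        if not (0.0 < self.confidence < 1.0):
            raise ValueError("confidence must be in (0, 1)")

    @property
    def z(self) -> float:
        """Two-sided normal critical value for the coverage proportion."""
        return float(stats.norm.ppf((1.0 + self.coverage) / 2.0))


def tolerance_factor(n: int, nu: int,
                     settings: ToleranceSettings = ToleranceSettings()
                     ) -> float:
    """sqrt(nu (1 + 1/N) / chi2_{alpha,nu}): uncertainty inflation factor.

    Multiplies the residual standard deviation wherever model predictions
    feed the Monte-Carlo simulation, so small-N models are penalized.
    """
    if nu < 1:
        raise ValueError("residual degrees of freedom must be >= 1")
    if n < 1:
        raise ValueError("N must be >= 1")
    chi2 = stats.chi2.ppf(settings.confidence, nu)
    return float(np.sqrt(nu * (1.0 + 1.0 / n) / chi2))


def tolerance_interval(y_hat: float, sigma: float, n: int, nu: int,
                       settings: ToleranceSettings = ToleranceSettings()
                       ) -> tuple[float, float]:
    """Symmetric normal-population tolerance interval about a prediction."""
    half = settings.z * tolerance_factor(n, nu, settings) * sigma
    return (y_hat - half, y_hat + half)


@dataclass
class UOModel:
    """A fitted per-UO regression: term set, coefficients and fit metadata.

    ``load_range`` is the observed span of input loads in the training runs;
    it is absent (None) for the first UO, which has no load.  Beyond
    ``load_range[1]`` the model predicts conservatively (see
    :func:`hdoe.ipm.predict_pool`).
    """

    spec: ModelSpec
    coef: np.ndarray
    rmse: float
    n: int
    load_range: tuple[float, float] | None = None
    factors: tuple[str, ...] = field(default_factory=tuple)

    @property
    def p(self) -> int:
        return self.spec.p

    @property
    def nu(self) -> int:
        return self.n - self.p

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        """Plain linear-model prediction (no load-extrapolation handling)."""
        return build_model_matrix(data, self.spec) @ self.coef

    def to_dict(self) -> dict:
        return {
            "terms": list(self.spec.terms),
            "coef": [float(c) for c in self.coef],
            "rmse": float(self.rmse),
            "n": int(self.n),
            "p": int(self.p),
            "load_range": (list(map(float, self.load_range))
                           if self.load_range is not None else None),
            "factors": list(self.factors),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "UOModel":
        return cls(spec=ModelSpec(d["terms"]),
                   coef=np.asarray(d["coef"], float),
                   rmse=float(d["rmse"]), n=int(d["n"]),
                   load_range=(tuple(d["load_range"])
                               if d.get("load_range") else None),
                   factors=tuple(d.get("factors", ())))

    @classmethod
    def from_json(cls, path) -> "UOModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _aliased_terms(X: np.ndarray, terms) -> list[str]:
    """Names of columns that are linearly dependent on the others."""
    from scipy.linalg import qr as _qr
    R, piv = _qr(X, mode="r", pivoting=True)
    diag = np.abs(np.diag(R))
    thresh = diag.max() * _RANK_TOL if diag.size else 0.0
    rank = int((diag > thresh).sum())
    return [terms[i] for i in sorted(piv[rank:])]


def fit_uo_model(runs: pd.DataFrame, spec: ModelSpec, *,
                 response: str = "response",
                 track_load: bool | None = None) -> UOModel:
    """OLS fit of one UO's pool response on the given term set.

    ``track_load``: record the observed load range from the training rows
    (defaults to True whenever a ``load`` column is present — i.e., for any
    downstream UO — independent of whether the load term was selected).
    """
    y = runs[response].to_numpy(float)
    X = build_model_matrix(runs, spec)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"N={n} runs cannot estimate p={p} terms with "
                         "positive residual degrees of freedom")
    if np.linalg.matrix_rank(X, tol=_RANK_TOL * max(n, p)) < p:
        aliased = _aliased_terms(X, list(spec.terms))
        raise ValueError(f"rank-deficient model matrix; aliased terms: "
                         f"{aliased}")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rmse = float(np.sqrt(resid @ resid / (n - p)))
    if track_load is None:
        track_load = "load" in runs.columns and runs["load"].notna().any()
    load_range = None
    if track_load:
        loads = runs["load"].to_numpy(float)
        load_range = (float(np.nanmin(loads)), float(np.nanmax(loads)))
    factors = tuple(c for c in runs.columns
                    if c.startswith("x") and c[1:].isdigit())
    return UOModel(spec=spec, coef=coef, rmse=rmse, n=n,
                   load_range=load_range, factors=factors)


def _ols_pvalues(X: np.ndarray, y: np.ndarray):
    """Coefficients and partial t-test p-values; None if not estimable."""
    n, p = X.shape
    if n - p < 1:
        return None
    G = X.T @ X
    try:
        Ginv = np.linalg.inv(G)
    except np.linalg.LinAlgError:
        return None
    # reject numerically singular fits
    if not np.all(np.isfinite(Ginv)) or np.abs(Ginv).max() > 1.0 / _RANK_TOL:
        return None
    coef = Ginv @ (X.T @ y)
    resid = y - X @ coef
    sse = float(resid @ resid)
    nu = n - p
    s2 = sse / nu
    se = np.sqrt(np.maximum(np.diag(Ginv) * s2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, coef / np.where(se > 0, se, 1.0),
                         # exact fit: a zero coefficient carries no signal
                         np.where(np.abs(coef) > 1e-10, np.inf, 0.0))
    pvals = 2.0 * stats.t.sf(np.abs(tvals), nu)
    return coef, pvals, np.sqrt(s2)


def stepwise_select(runs: pd.DataFrame, scope: ModelSpec, *,
                    p_enter: float = P_ENTER, p_remove: float = P_REMOVE,
                    response: str = "response",
                    forced: tuple[str, ...] = ("1",),
                    start_with_load: bool = False) -> UOModel:
    """Bi-directional stepwise selection within ``scope``.

    Starts from the intercept; the load term of downstream UOs competes in
    selection like any other scope term.  Until the load span has actually
    been explored (by spiking), a fitted load slope is sampling noise over
    a hair-thin range, and carrying it in the model poisons every chained
    prediction — so the load term earns its way in via its p-value once
    real load variation exists.  Alternates forward steps (add the
    scope term with the smallest partial t-test p-value if below
    ``p_enter``) and backward steps (drop the non-forced term with the
    largest p-value if above ``p_remove``) until neither changes the model.
    Terms that would leave no residual degrees of freedom or make the
    matrix singular are skipped, not errors — the procedure must work from
    6 runs per UO upward.  Deterministic: ties break by scope order, and
    the result does not depend on the row order of the run table.
    """
    if scope.p < 1:
        raise ValueError("empty scope")
    if p_enter <= p_remove:
        raise ValueError("p_enter must exceed p_remove")
    y = runs[response].to_numpy(float)
    cols = {t: None for t in scope.terms}
    from .design import term_column
    for t in cols:
        cols[t] = term_column(t, runs)

    current = [t for t in scope.terms if t in forced]
    if start_with_load and "load" in scope.terms and "load" not in current:
        current.append("load")

    def matrix(terms):
        return np.column_stack([cols[t] for t in terms])

    last_dropped = None
    for _ in range(4 * scope.p):  # cycle guard
        changed = False
        # forward: add the best eligible term (never the one just dropped,
        # which would oscillate forever for any term with
        # p_remove < p < p_enter)
        best_t, best_p = None, np.inf
        for t in scope.terms:
            if t in current or t == last_dropped:
                continue
            fit = _ols_pvalues(matrix(current + [t]), y)
            if fit is None:
                continue
            pv = fit[1][-1]
            if pv < best_p - 1e-15:
                best_t, best_p = t, pv
        added = None
        if best_t is not None and best_p < p_enter:
            current.append(best_t)
            added = best_t
            changed = True
        # backward: the just-added term is exempt this iteration
        fit = _ols_pvalues(matrix(current), y)
        if fit is not None and len(current) > 1:
            pvals = fit[1]
            worst_i, worst_p = None, -np.inf
            for i, t in enumerate(current):
                if t in forced or t == added:
                    continue
                if pvals[i] > worst_p + 1e-15:
                    worst_i, worst_p = i, pvals[i]
            if worst_i is not None and worst_p > p_remove:
                last_dropped = current.pop(worst_i)
                changed = True
            else:
                last_dropped = None
        if not changed:
            break

    # canonical order: scope order
    ordered = [t for t in scope.terms if t in current]
    return fit_uo_model(runs, ModelSpec(ordered), response=response)
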