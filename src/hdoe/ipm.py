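"""Integrated process model: chained UO regressions simulated end-to-end.

The process is an ordered chain of unit-operation models.  A Monte-Carlo
trajectory draws every UO's process parameters from their (normal, setpoint-
centred) distributions, evaluates UO1's pool, passes it to UO2 as the load,
and so on down to the drug substance (DS).  Each UO adds residual noise
whose sd is the model RMSE inflated by the tolerance factor — a model
trained on few runs claims less certainty than one trained on many.

Loads above the observed training range are handled conservatively for an
impurity CQA: the model prediction is frozen at the range edge and every
additional unit of load passes straight through to the pool (a piecewise
model with slope one beyond the observed maximum).  This makes the simulated
DS distribution — and hence the out-of-specification (OOS) rate — depend
strongly on how far each UO's load range has been explored, which is exactly
the lever a spiking run pulls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regression import ToleranceSettings, UOModel, tolerance_factor

__all__ = [
    "IPMChain",
    "OOSEstimate",
    "predict_pool",
    "simulate_chain",
    "oos_rate",
    "backpropagate_iac",
]

DEFAULT_SIGMA_PP = 1.0 / 3.0  # screening range +-1 spans three PP sds
DEFAULT_N_MC = 20_000


@dataclass
class OOSEstimate:
    """Monte-Carlo OOS rate with its binomial standard error."""

    rate: float
    n_mc: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.rate * (1.0 - self.rate) / self.n_mc))


@dataclass
class IPMChain:
    """Ordered UO models, PP distributions and the DS specification."""

    models: list[UOModel]
    spec_limit: float
    sigma_pp: float = DEFAULT_SIGMA_PP
    n_mc: int = DEFAULT_N_MC
    seed: int | None = None
    tolerance: ToleranceSettings = field(default_factory=ToleranceSettings)

    def __post_init__(self):
        if len(self.models) < 1:
            raise ValueError("chain needs at least one UO model")
        if self.sigma_pp <= 0:
            raise ValueError("sigma_pp must be positive")
        for i, m in enumerate(self.models[1:], start=2):
            if m.load_range is None:
                raise ValueError(f"downstream UO{i} model has no load range")

    @property
    def m(self) -> int:
        return len(self.models)

    def to_json(self, path) -> None:
        """Serialize the chain (models, spec, settings) for audit/reload."""
        import json
        payload = {
            "models": [m.to_dict() for m in self.models],
            "spec_limit": float(self.spec_limit),
            "sigma_pp": float(self.sigma_pp),
            "n_mc": int(self.n_mc),
            "seed": self.seed,
            "tolerance": {"coverage": self.tolerance.coverage,
                          "confidence": self.tolerance.confidence},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "IPMChain":
        import json
        with open(path) as fh:
            d = json.load(fh)
        return cls(models=[UOModel.from_dict(m) for m in d["models"]],
                   spec_limit=d["spec_limit"], sigma_pp=d["sigma_pp"],
                   n_mc=d["n_mc"], seed=d.get("seed"),
                   tolerance=ToleranceSettings(**d["tolerance"]))


def _piecewise_eval(model: UOModel, pp: pd.DataFrame,
                    load: np.ndarray | None) -> np.ndarray:
    """Model prediction with conservative slope-one load extrapolation."""
    data = pp.copy()
    excess = 0.0
    if model.load_range is not None:
        if load is None:
            raise ValueError("load required for a load-dependent UO model")
        load = np.asarray(load, float)
        lo, hi = model.load_range
        clamped = np.minimum(load, hi)
        excess = np.maximum(load - hi, 0.0)
        data["load"] = clamped
    elif model.spec.has_load():
        if load is None:
            raise ValueError("load required for a load-dependent UO model")
        data["load"] = np.asarray(load, float)
    return model.predict(data) + excess


def predict_pool(model: UOModel, pp_values: dict | pd.DataFrame,
                 load: float | None = None) -> float:
    """Pool prediction of one UO at given PP settings and load.

    Within the observed load range this is the ordinary linear-model
    prediction; beyond the observed maximum the prediction at the edge is
    carried forward plus the full load excess (slope one, impurity CQA),
    continuous at the knot.  Below the observed minimum the fitted model is
    used unchanged.
    """
    if isinstance(pp_values, dict):
        pp_values = pd.DataFrame([pp_values])
    load_vec = None if load is None else np.asarray([load], float)
    return float(_piecewise_eval(model, pp_values, load_vec)[0])


def simulate_chain(ipm: IPMChain, n_mc: int | None = None,
                   seed: int | None = None, *,
                   return_intermediates: bool = False):
    """Monte-Carlo DS CQA sample of size ``n_mc``.

    Per trajectory: draw each UO's PPs ~ N(0, sigma_pp^2), evaluate the
    chain passing pools as loads, and add per-UO residual noise with sd
    RMSE * tolerance_factor(N, nu).  Bit-reproducible given the seed.
    """
    n_mc = int(ipm.n_mc if n_mc is None else n_mc)
    if n_mc < 100:
        warnings.warn("n_mc < 100 gives an unstable OOS estimate",
                      stacklevel=2)
    seed = ipm.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    load = None
    pools = []
    for model in ipm.models:
        k = len(model.factors) if model.factors else len(
            model.spec.factors())
        names = (model.factors if model.factors
                 else model.spec.factors())
        pp = pd.DataFrame(
            rng.normal(0.0, ipm.sigma_pp, size=(n_mc, k)),
            columns=list(names))
        y = _piecewise_eval(model, pp, load)
        sd = model.rmse * tolerance_factor(model.n, model.nu, ipm.tolerance)
        if sd > 0:
            y = y + rng.normal(0.0, sd, size=n_mc)
        pools.append(y)
        load = y
    if return_intermediates:
        return pools
    return load


def oos_rate(samples: np.ndarray, spec_limit: float) -> OOSEstimate:
    """Fraction of simulated DS values strictly above the upper spec."""
    samples = np.asarray(samples, float)
    if samples.size == 0:
        raise ValueError("empty sample")
    rate = float(np.mean(samples > spec_limit))
    return OOSEstimate(rate=rate, n_mc=samples.size)


def _load_slope(model: UOModel) -> float:
    if "load" not in model.spec:
        return 0.0
    return float(model.coef[list(model.spec.terms).index("load")])


def backpropagate_iac(ipm: IPMChain, ds_spec: float | None = None
                      ) -> list[float]:
    """Intermediate acceptance criteria by backward inversion of the chain.

    Starting from the DS specification, each downstream UO's load limit is
    the largest load whose upper prediction bound (mean at setpoint PPs plus
    the tolerance half-width) stays below the pool limit; that load limit
    becomes the pool limit of the previous UO.  In the slope-one
    extrapolation region the inversion is exact.  Returns per-UO pool
    limits, last entry = DS spec.
    """
    ds_spec = ipm.spec_limit if ds_spec is None else ds_spec
    m = ipm.m
    iac = [np.nan] * m
    iac[m - 1] = float(ds_spec)
    pool_limit = float(ds_spec)
    for idx in range(m - 1, 0, -1):
        model = ipm.models[idx]
        half = (ipm.tolerance.z * model.rmse
                * tolerance_factor(model.n, model.nu, ipm.tolerance))
        names = model.factors if model.factors else model.spec.factors()
        setpt = pd.DataFrame([{f: 0.0 for f in names}])
        lo, hi = model.load_range
        upper_at_hi = predict_pool(model, setpt, hi) + half
        b = _load_slope(model)
        if pool_limit >= upper_at_hi:
            # beyond the observed range: slope one, exact inversion
            load_limit = hi + (pool_limit - upper_at_hi)
        elif b > 0:
            a = predict_pool(model, setpt, 0.0)  # within-range intercept
            load_limit = (pool_limit - half - a) / b
        else:
            warnings.warn(
                f"UO{idx + 1}: non-positive load slope and infeasible pool "
                "limit within the observed range; acceptance criterion "
                "reported as unbounded", stacklevel=2)
            load_limit = np.inf
        iac[idx - 1] = float(load_limit)
        pool_limit = float(load_limit)
    return iac
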