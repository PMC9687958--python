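"""Simulated ground-truth processes: the in-silico laboratory.

Four benchmark studies share one backbone: a 4-UO process (a fermentation
step followed by three downstream purification steps), five normalized
process parameters per UO, and an impurity CQA whose pool value is passed
downstream as the next UO's load.  Study A is the baseline with 4-6 active
effects per UO (respecting effect heredity) and linear load dependencies;
study B sets UO3's load coefficient to 1.0 (no clearance at that step);
study C sets every downstream load coefficient to 1.0 (the worst case for
load-probing experiments — there is nothing to learn from spiking); study D
re-uses study A's process but raises the noise/std ratio from 0.5 to 0.9
and is evaluated with the PRT decision scheme disabled.

Noise model: each UO's measured pool gets additive normal noise with
sd = ratio * sd(noise-free pool under process-parameter variation), making
the stated ratio dimensionless and per-UO.  Noise applies to pools only;
observed loads are the (already noisy) upstream pools without extra
measurement error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import json

import numpy as np
import pandas as pd

from .ipm import DEFAULT_SIGMA_PP

__all__ = ["GroundTruth", "STUDY_COEFFS", "gt_response", "derive_spec",
           "perform_run"]

N_FACTORS = 5
N_UOS = 4

# term -> coefficient per UO; "load" is the upstream pool
_UO1_A = {"1": 8.0, "x1": 0.7, "x2": 0.6, "x3": 0.5, "x4": -0.4,
          "x2^2": 0.9, "x3^2": 0.8}
_UO2_A = {"1": 3.4, "load": 0.5, "x2": 0.5, "x3": 0.3, "x5": 0.5,
          "x2:x3": 0.7, "x2:x5": 0.4}
_UO3_A = {"1": 3.0, "load": 0.3, "x1": 0.4, "x2": -0.3, "x4": 0.2,
          "x5": -0.2, "x1^2": 0.3, "x5^2": -0.7}
_UO4_A = {"1": 2.8, "load": 0.2, "x1": 0.1, "x3": 0.2, "x5": 0.2,
          "x1:x3": 0.3}


def _with_load(coeffs: dict, value: float) -> dict:
    out = dict(coeffs)
    out["load"] = value
    return out


STUDY_COEFFS: dict[str, list[dict]] = {
    "A": [_UO1_A, _UO2_A, _UO3_A, _UO4_A],
    "B": [_UO1_A, _UO2_A, _with_load(_UO3_A, 1.0), _UO4_A],
    "C": [_UO1_A, _with_load(_UO2_A, 1.0), _with_load(_UO3_A, 1.0),
          _with_load(_UO4_A, 1.0)],
    "D": [_UO1_A, _UO2_A, _UO3_A, _UO4_A],
}

STUDY_NOISE_RATIO = {"A": 0.5, "B": 0.5, "C": 0.5, "D": 0.9}

_NOISE_CAL_N = 50_000
_NOISE_CAL_SEED = 20221103  # internal constant; part of the model definition


def _poly_eval(coeffs: dict, x: np.ndarray, load) -> np.ndarray:
    """Evaluate a coefficient table at x (n x 5) and load (scalar/vector)."""
    x = np.atleast_2d(np.asarray(x, float))
    n = x.shape[0]
    y = np.zeros(n)
    for term, c in coeffs.items():
        if term == "1":
            y += c
        elif term == "load":
            y += c * np.asarray(load, float)
        elif ":" in term:
            a, b = term.split(":")
            y += c * x[:, int(a[1:]) - 1] * x[:, int(b[1:]) - 1]
        elif term.endswith("^2"):
            y += c * x[:, int(term[1:-2]) - 1] ** 2
        else:
            y += c * x[:, int(term[1:]) - 1]
    return y


@dataclass
class GroundTruth:
    """One benchmark study's true process."""

    study: str
    sigma_pp: float = DEFAULT_SIGMA_PP
    noise_ratio: float | None = None
    _noise_sd: tuple[float, ...] = field(default=None, repr=False)

    def __post_init__(self):
        if self.study not in STUDY_COEFFS:
            raise ValueError(f"unknown study {self.study!r}; "
                             f"choose from {sorted(STUDY_COEFFS)}")
        if self.noise_ratio is None:
            self.noise_ratio = STUDY_NOISE_RATIO[self.study]
        if self._noise_sd is None:
            self._noise_sd = self._calibrate_noise()

    @property
    def coeffs(self) -> list[dict]:
        return STUDY_COEFFS[self.study]

    def _calibrate_noise(self) -> tuple[float, ...]:
        """ratio * sd of each UO's noise-free pool under PP variation."""
        rng = np.random.default_rng(_NOISE_CAL_SEED)
        pools = self._chain(rng, _NOISE_CAL_N, noisy=False)
        return tuple(self.noise_ratio * float(np.std(p)) for p in pools)

    @property
    def noise_sd(self) -> tuple[float, ...]:
        return self._noise_sd

    def _chain(self, rng: np.random.Generator, n: int, noisy: bool,
               at_setpoint: bool = False) -> list[np.ndarray]:
        """End-to-end pools of n trajectories; noise propagates via loads."""
        pools = []
        load = None
        for u in range(1, N_UOS + 1):
            if at_setpoint:
                x = np.zeros((n, N_FACTORS))
            else:
                x = rng.normal(0.0, self.sigma_pp, size=(n, N_FACTORS))
            y = _poly_eval(self.coeffs[u - 1], x, load)
            if noisy:
                y = y + rng.normal(0.0, self._noise_sd[u - 1], size=n)
            pools.append(y)
            load = y
        return pools

    def setpoint_chain(self) -> list[float]:
        """Noise-free pools with every PP at setpoint (study A: ends 3.844)."""
        pools = self._chain(np.random.default_rng(0), 1, noisy=False,
                            at_setpoint=True)
        return [float(p[0]) for p in pools]


def gt_response(gt: GroundTruth, uo: int, x, load=None,
                rng: np.random.Generator | None = None) -> float:
    """True pool value of one UO at given settings, optionally noisy."""
    if not (1 <= uo <= N_UOS):
        raise ValueError(f"unknown unit operation {uo}")
    x = np.asarray(x, float).reshape(1, N_FACTORS)
    coeffs = gt.coeffs[uo - 1]
    if uo >= 2 and load is None:
        raise ValueError("downstream UOs require a load value")
    y = float(_poly_eval(coeffs, x, 0.0 if load is None else load)[0])
    if rng is not None:
        y += float(rng.normal(0.0, gt.noise_sd[uo - 1]))
    return y


def derive_spec(gt: GroundTruth, n: int = 100_000,
                seed: int | None = 0) -> float:
    """Upper DS specification: mean + 3 sd of the noisy true process.

    By construction the true process then has a floor OOS rate of
    (1 - 0.9973)/2 = 0.00135 when its DS distribution is near-normal.
    """
    if n < 10_000:
        raise ValueError("need n >= 1e4 trajectories for a stable spec")
    rng = np.random.default_rng(seed)
    ds = gt._chain(rng, n, noisy=True)[-1]
    return float(np.mean(ds) + 3.0 * np.std(ds))


def realize_load(gt: GroundTruth, uo: int,
                 rng: np.random.Generator) -> float | None:
    """Load delivered to a UO by a noisy setpoint run of the upstream UOs.

    Small-scale DoE runs at downstream UOs receive representative input
    material produced upstream at setpoint conditions; only measurement/
    batch noise varies it.  The resulting load spread is narrow — which is
    exactly why fixed DoE-only campaigns leave the load-to-pool dependency
    unexplored and spiking runs carry information no DoE run provides.
    """
    if uo == 1:
        return None
    load = None
    for u in range(1, uo):
        y = gt_response(gt, u, np.zeros(N_FACTORS), load, rng)
        load = y
    return float(load)


def perform_run(gt: GroundTruth, uo: int, run_type: str, settings: dict,
                rng: np.random.Generator, load: float | None = None) -> dict:
    """Execute one experiment in the in-silico laboratory.

    DoE runs at downstream UOs get their load realized from a noisy
    setpoint upstream trajectory; spiking runs use their explicit load.
    Returns a run-table row (uo, run_type, x1..x5, load, response).
    """
    x = np.array([settings.get(f"x{i + 1}", 0.0) for i in range(N_FACTORS)],
                 float)
    if uo >= 2 and load is None:
        if run_type == "spiking":
            raise ValueError("spiking runs must state their load")
        load = realize_load(gt, uo, rng)
    response = gt_response(gt, uo, x, load, rng)
    row = {"uo": uo, "run_type": run_type}
    row.update({f"x{i + 1}": float(x[i]) for i in range(N_FACTORS)})
    row["load"] = np.nan if load is None else float(load)
    row["response"] = response
    return row


def export_coeffs(gt: GroundTruth, path) -> None:
    """Write the study's coefficient tables as JSON."""
    with open(path, "w") as fh:
        json.dump({"study": gt.study, "noise_ratio": gt.noise_ratio,
                   "sigma_pp": gt.sigma_pp,
                   "uo_coeffs": gt.coeffs,
                   "noise_sd": list(gt.noise_sd)}, fh, indent=1)
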