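"""Run recommendation: candidate generation, OOS scoring, PRT decision.

Each cycle proposes at most one DoE candidate per unit operation (the
candidate-set row that D-optimally augments that UO's current design) and
one spiking candidate per downstream UO (all PPs at setpoint, load pushed to
the largest load the current IPM simulates there).  Every candidate is
scored by the OOS rate the IPM would report after hypothetically performing
it, and the best DoE and best spiking candidates then enter the
probability-ratio-threshold (PRT) decision: spiking is accepted only when a
uniform draw exceeds the ratio of predicted improvements, which biases the
procedure toward DoE runs and hence toward detecting still-unknown effects.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .design import best_augmentation_row
from .ipm import IPMChain, oos_rate, simulate_chain
from .regression import UOModel, fit_uo_model

__all__ = ["Candidate", "shortlist_candidates", "predicted_oos_after",
           "prt_decide"]

EPS_IMPROVEMENT = 1e-12
SPIKE_LOAD_CAP = 3.0  # spike load capped at 3x the largest observed load


@dataclass
class Candidate:
    """A proposed run with its predicted post-augmentation OOS."""

    uo: int                      # 1-based unit operation index
    run_type: str                # "DoE" | "spiking"
    settings: dict               # factor name -> level
    load: float | None = None    # spiking: explicit load level
    oos_after: float | None = None
    improvement: float | None = None  # max(OOS_current - oos_after, 0)

    def __post_init__(self):
        if self.run_type == "spiking" and self.uo == 1:
            raise ValueError("the first UO has no load; spiking impossible")


def shortlist_candidates(run_table: pd.DataFrame, models: list[UOModel],
                         ipm: IPMChain, candidates_per_uo: list[pd.DataFrame],
                         mc_seed: int | None = None,
                         spike_load_cap: float = SPIKE_LOAD_CAP,
                         rng: np.random.Generator | None = None
                         ) -> list[Candidate]:
    """One DoE candidate per UO plus one spiking candidate per downstream UO.

    The DoE candidate at UO ``u`` is the candidate-set row maximizing the
    D-criterion of UO ``u``'s design augmented by one run, under the current
    selected model scope (factor terms only).  The spiking candidate sets
    every PP to its setpoint and the load to the maximum load the current
    IPM simulates at that UO — the level that eliminates the extrapolation
    region in a single run — capped at ``spike_load_cap`` times the largest
    observed load (spiking studies challenge a step at a bounded multiple
    of what it has already seen).
    """
    out: list[Candidate] = []
    pools = simulate_chain(ipm, seed=mc_seed, return_intermediates=True)
    for u, (model, cands) in enumerate(zip(models, candidates_per_uo),
                                       start=1):
        uo_runs = run_table[run_table["uo"] == u]
        fac_cols = list(cands.columns)
        design_spec = model.spec.drop_load()
        j = best_augmentation_row(cands, design_spec, uo_runs[fac_cols],
                                  rng=rng)
        settings = {c: float(cands.iloc[j][c]) for c in fac_cols}
        out.append(Candidate(uo=u, run_type="DoE", settings=settings))
        if u >= 2:
            lo, hi = model.load_range
            span = max(hi - lo, 1e-9)
            cap = (spike_load_cap * hi if hi > 0
                   else hi + spike_load_cap * span)
            sim_load_max = float(np.max(pools[u - 2]))
            spike_load = min(sim_load_max, cap)
            if spike_load > hi:
                out.append(Candidate(
                    uo=u, run_type="spiking",
                    settings={c: 0.0 for c in fac_cols}, load=spike_load))
    return out


def _hypothetical_row(candidate: Candidate, models: list[UOModel],
                      run_table: pd.DataFrame) -> dict:
    """Run-table row for a candidate with the model-mean response.

    The hypothetical response is the current model's mean prediction (no
    simulated noise) at the candidate settings.  A hypothetical DoE run at
    a downstream UO is assumed to receive typical load material — the mean
    of the loads observed there so far — so it sits inside the observed
    load range and leaves it unchanged; only a spiking run extends the
    range.  For a spiking run the observed trend is extrapolated (plain
    linear model, no conservative slope-one excess): the hypothesis under
    evaluation is that clearance continues as observed, and the refit on
    the realized outcome corrects it if not.
    """
    model = models[candidate.uo - 1]
    if candidate.run_type == "spiking":
        load = candidate.load
    elif model.load_range is not None or model.spec.has_load():
        uo_loads = run_table.loc[run_table["uo"] == candidate.uo, "load"]
        load = float(uo_loads.mean())
    else:
        load = None
    pp = pd.DataFrame([candidate.settings])
    if model.load_range is not None or model.spec.has_load():
        pp["load"] = load
    response = float(model.predict(pp)[0])
    row = {"uo": candidate.uo, "run_type": candidate.run_type,
           **candidate.settings,
           "load": np.nan if load is None else load, "response": response}
    return row


def predicted_oos_after(run_table: pd.DataFrame, models: list[UOModel],
                        ipm: IPMChain, candidate: Candidate,
                        mc_seed: int | None = None) -> float:
    """OOS rate the IPM would report after hypothetically adding the run.

    The run table is augmented with the candidate (response = current model
    mean), coefficients are refit keeping the currently selected term sets
    (no re-selection), the IPM is rebuilt (new N, nu, RMSE, load range) and
    the OOS is recomputed with common random numbers — the same MC seed as
    the current OOS — so candidate ranking is not dominated by MC noise.
    """
    row = _hypothetical_row(candidate, models, run_table)
    augmented = pd.concat([run_table, pd.DataFrame([row])],
                          ignore_index=True)
    new_models = []
    for u, model in enumerate(models, start=1):
        if u != candidate.uo:
            new_models.append(model)
            continue
        uo_runs = augmented[augmented["uo"] == u]
        try:
            refit = fit_uo_model(uo_runs, model.spec,
                                 track_load=model.load_range is not None)
        except (ValueError, np.linalg.LinAlgError):
            return float("nan")  # caller scores at OOS_current
        new_models.append(refit)
    new_ipm = replace(ipm, models=new_models)
    samples = simulate_chain(new_ipm, seed=mc_seed)
    return oos_rate(samples, ipm.spec_limit).rate


def best_by_type(candidates: list[Candidate], rng: np.random.Generator,
                 n_mc: int) -> dict[str, Candidate | None]:
    """Best scored candidate per run type, randomizing statistical ties.

    Candidates whose predicted OOS lies within two Monte-Carlo standard
    errors of the type's minimum are indistinguishable at the simulation
    resolution; one of them is picked uniformly at random.  Without this,
    a deterministic tie-break starves every UO but one of data whenever no
    candidate predicts a real improvement, and a mis-selected model can
    never be corrected.
    """
    out: dict[str, Candidate | None] = {"DoE": None, "spiking": None}
    for run_type in out:
        scored = [c for c in candidates
                  if c.run_type == run_type and c.oos_after is not None]
        if not scored:
            continue
        lo = min(c.oos_after for c in scored)
        tol = 2.0 * np.sqrt(max(lo * (1.0 - lo), 0.0) / n_mc) + 1e-9
        tied = [c for c in scored if c.oos_after <= lo + tol]
        out[run_type] = tied[int(rng.integers(len(tied)))]
    return out


def prt_decide(oos_current: float, best_doe: Candidate | None,
               best_spiking: Candidate | None,
               rng: np.random.Generator, *,
               mode: str = "improvement") -> Candidate:
    """Choose the next run by the probability-ratio-threshold scheme.

    ``mode="improvement"`` (default): with predicted improvements
    ``d_doe``, ``d_spk`` (floored at a tiny epsilon), alpha = d_doe/d_spk;
    draw u ~ U[0,1] and return the spiking candidate iff u >= alpha.  DoE is
    therefore certain whenever its improvement is at least as large, and
    spiking is accepted with probability 1 - alpha otherwise.

    ``mode="literal"``: alpha is the ratio of predicted post-run OOS
    probabilities, same uniform-threshold rule.

    ``mode="greedy"``: no randomization — the candidate with the lower
    predicted OOS wins, DoE on ties (PRT disabled, study-D comparison).
    """
    if best_doe is None and best_spiking is None:
        raise ValueError("no candidates to decide between")
    if best_spiking is None:
        return best_doe
    if best_doe is None:
        return best_spiking

    if mode == "greedy":
        if best_doe.oos_after <= best_spiking.oos_after:
            return best_doe
        return best_spiking

    if mode == "literal":
        num = max(best_doe.oos_after, EPS_IMPROVEMENT)
        den = max(best_spiking.oos_after, EPS_IMPROVEMENT)
        alpha = num / den
    elif mode == "improvement":
        d_spk = best_spiking.improvement
        if d_spk is None or d_spk <= 0:
            return best_doe
        d_doe = max(best_doe.improvement or 0.0, EPS_IMPROVEMENT)
        alpha = d_doe / max(d_spk, EPS_IMPROVEMENT)
    else:
        raise ValueError(f"unknown PRT mode {mode!r}")

    u = rng.uniform()
    return best_spiking if u >= alpha else best_doe
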