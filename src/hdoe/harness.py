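"""Benchmark orchestration: reference workflows, the hDoE loop, reporting.

``run_reference`` reproduces the state-of-the-art characterization workflow
(a fixed per-UO D-optimal design, stepwise model selection, one IPM OOS
evaluation).  ``run_hdoe`` runs the iterative recommender: a minimal 6-run
design per UO, then one recommended run per cycle — DoE or spiking, at the
UO the IPM says will reduce the simulated OOS rate the most, filtered
through the PRT decision scheme.  Both are replicated across seeds and
summarized by ``report``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import FactorSpace, ModelSpec, candidate_set, d_optimal_augment
from .ground_truth import (N_FACTORS, N_UOS, GroundTruth, derive_spec,
                           perform_run)
from .ipm import DEFAULT_N_MC, IPMChain, oos_rate, simulate_chain
from .recommender import (best_by_type, predicted_oos_after, prt_decide,
                          shortlist_candidates)
from .regression import ToleranceSettings, stepwise_select

__all__ = ["TraceSet", "run_reference", "run_hdoe", "report"]

INITIAL_RUNS_PER_UO = 6
RUN_COLUMNS = (["uo", "run_type"] + [f"x{i + 1}" for i in range(N_FACTORS)]
               + ["load", "response"])


@dataclass
class TraceSet:
    """Per-repetition, per-step record of one study's hDoE trajectory."""

    steps: pd.DataFrame       # rep, step, total_runs, oos, chosen_uo/type ...
    estimates: pd.DataFrame   # rep, step, uo, term, coef (+ rmse rows)
    meta: dict = field(default_factory=dict)

    def oos_by_step(self) -> pd.DataFrame:
        g = self.steps.groupby("step")["oos"]
        out = g.agg(["mean", "std"]).reset_index()
        out["total_runs"] = (self.steps.groupby("step")["total_runs"]
                             .first().to_numpy())
        return out


def _scopes() -> list[ModelSpec]:
    return [ModelSpec.full_quadratic(N_FACTORS, load=(u >= 2))
            for u in range(1, N_UOS + 1)]


def _design_spec(runs_per_uo: int) -> ModelSpec:
    """Largest benchmark model scope a design of this size can support."""
    full = ModelSpec.full_quadratic(N_FACTORS)
    if runs_per_uo >= full.p:
        return full
    return ModelSpec.main_effects(N_FACTORS)


def _fit_all(run_table: pd.DataFrame, scopes) -> list:
    models = []
    for u in range(1, N_UOS + 1):
        uo_runs = run_table[run_table["uo"] == u]
        models.append(stepwise_select(uo_runs, scopes[u - 1]))
    return models


def _perform_design(gt: GroundTruth, design: pd.DataFrame, uo: int,
                    run_type: str, rng) -> list[dict]:
    rows = []
    for _, r in design.iterrows():
        settings = {f"x{i + 1}": float(r[f"x{i + 1}"])
                    for i in range(N_FACTORS)}
        rows.append(perform_run(gt, uo, run_type, settings, rng))
    return rows


def _build_designs(runs_per_uo: int, seed, restarts: int = 10,
                   center_points: int = 0) -> list[pd.DataFrame]:
    """One D-optimal design per UO from the 3-level grid.

    Built fresh per repetition (seeded from the repetition's stream), so
    repetitions are not tied to a single design draw.  ``center_points``
    fixes that many setpoint runs and D-optimizes the remaining rows
    around them: the minimal hDoE start design anchors the setpoint region
    — where the IPM simulates — instead of consisting of corner points
    only, whose intercept estimate is biased whenever the true response is
    curved.
    """
    space = FactorSpace.regular(N_FACTORS)
    cands = candidate_set(space)
    n_opt = runs_per_uo - center_points
    spec = _design_spec(n_opt)
    rng = np.random.default_rng(seed)
    existing = None
    if center_points:
        center = cands[(cands == 0).all(axis=1)].reset_index(drop=True)
        existing = pd.concat([center] * center_points, ignore_index=True)
    designs = []
    for _ in range(N_UOS):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            d = d_optimal_augment(cands, spec, n_opt, existing=existing,
                                  seed=int(rng.integers(2**31)),
                                  restarts=restarts)
        designs.append(d.reset_index(drop=True))
    return designs


def run_reference(study: str, runs_per_uo: int = 23, reps: int = 20,
                  seed: int = 0, n_mc: int = DEFAULT_N_MC,
                  tolerance: ToleranceSettings | None = None) -> dict:
    """Fixed-design workflow: D-optimal runs, stepwise models, one OOS.

    Returns mean/sd of the simulated OOS rate across repetitions, plus the
    per-rep rates.  92 total runs (23/UO over 4 UOs) is the strongest
    reference configuration.
    """
    tolerance = tolerance or ToleranceSettings()
    ss = np.random.SeedSequence(seed)
    spec_ss, reps_ss = ss.spawn(2)
    gt = GroundTruth(study)
    ds_spec = derive_spec(gt, seed=spec_ss)
    scopes = _scopes()
    rates = []
    for rep_ss in reps_ss.spawn(reps):
        rng = np.random.default_rng(rep_ss)
        # large designs (p up to 21) need a broad multistart to come out
        # close to the true D-optimum
        designs = _build_designs(runs_per_uo, rng, restarts=25)
        rows = []
        for u in range(1, N_UOS + 1):
            rows += _perform_design(gt, designs[u - 1], u, "DoE", rng)
        run_table = pd.DataFrame(rows, columns=RUN_COLUMNS)
        models = _fit_all(run_table, scopes)
        ipm = IPMChain(models=models, spec_limit=ds_spec,
                       sigma_pp=gt.sigma_pp, n_mc=n_mc, tolerance=tolerance)
        samples = simulate_chain(ipm, seed=int(rng.integers(2**31)))
        rates.append(oos_rate(samples, ds_spec).rate)
    rates = np.asarray(rates)
    return {"study": study, "runs_per_uo": runs_per_uo,
            "total_runs": runs_per_uo * N_UOS,
            "mean_oos": float(rates.mean()),
            "sd_oos": float(rates.std(ddof=1)) if reps > 1 else 0.0,
            "rates": rates.tolist(), "ds_spec": float(ds_spec)}


def run_hdoe(study: str, n_steps: int = 30, reps: int = 20, seed: int = 0,
             n_mc: int = DEFAULT_N_MC, prt_mode: str | None = None,
             tolerance: ToleranceSettings | None = None) -> TraceSet:
    """The iterative hDoE benchmark loop.

    Per repetition: a 6-run D-optimal design per UO (24 initial runs), then
    ``n_steps`` cycles of {shortlist candidates, score each by its predicted
    post-run OOS, PRT-decide, perform the run, refit/re-select}.  The trace
    records n_steps + 1 OOS values (initial state included).  ``prt_mode``
    defaults to ``"improvement"``; study D is conventionally compared with
    ``"greedy"`` (PRT disabled).
    """
    tolerance = tolerance or ToleranceSettings()
    if prt_mode is None:
        prt_mode = "improvement"
    ss = np.random.SeedSequence(seed)
    spec_ss, reps_ss = ss.spawn(2)
    gt = GroundTruth(study)
    ds_spec = derive_spec(gt, seed=spec_ss)
    scopes = _scopes()
    space = FactorSpace.regular(N_FACTORS)
    cands_per_uo = [candidate_set(space) for _ in range(N_UOS)]

    step_rows, est_rows = [], []
    for rep, rep_ss in enumerate(reps_ss.spawn(reps)):
        rng = np.random.default_rng(rep_ss)
        init_designs = _build_designs(INITIAL_RUNS_PER_UO, rng,
                                      center_points=1)
        rows = []
        for u in range(1, N_UOS + 1):
            rows += _perform_design(gt, init_designs[u - 1], u, "initial",
                                    rng)
        run_table = pd.DataFrame(rows, columns=RUN_COLUMNS)
        models = _fit_all(run_table, scopes)

        def record(step, oos, chosen=None, audit=None):
            row = {"rep": rep, "step": step, "total_runs": len(run_table),
                   "oos": oos,
                   "chosen_uo": chosen.uo if chosen else np.nan,
                   "chosen_type": chosen.run_type if chosen else ""}
            row.update(audit or {})
            step_rows.append(row)
            for u, m in enumerate(models, start=1):
                for t, c in zip(m.spec.terms, m.coef):
                    est_rows.append({"rep": rep, "step": step, "uo": u,
                                     "term": t, "value": float(c)})
                est_rows.append({"rep": rep, "step": step, "uo": u,
                                 "term": "RMSE", "value": float(m.rmse)})

        mc_seed = int(rng.integers(2**31))
        ipm = IPMChain(models=models, spec_limit=ds_spec,
                       sigma_pp=gt.sigma_pp, n_mc=n_mc, tolerance=tolerance)
        oos_cur = oos_rate(simulate_chain(ipm, seed=mc_seed), ds_spec).rate
        record(0, oos_cur)

        for step in range(1, n_steps + 1):
            try:
                shortlist = shortlist_candidates(
                    run_table, models, ipm, cands_per_uo, mc_seed=mc_seed)
                for cand in shortlist:
                    after = predicted_oos_after(run_table, models, ipm,
                                                cand, mc_seed=mc_seed)
                    if np.isnan(after):
                        after = oos_cur
                    cand.oos_after = after
                    cand.improvement = max(oos_cur - after, 0.0)
                se_cur = np.sqrt(max(oos_cur * (1 - oos_cur), 0.0) / n_mc)
                best_gain = max((c.improvement for c in shortlist),
                                default=0.0)
                if best_gain <= 2.0 * se_cur:
                    # no candidate offers a statistically significant
                    # improvement: any DoE run is as good as another, so
                    # spread the effort instead of resolving noise
                    doe = [c for c in shortlist if c.run_type == "DoE"]
                    best = {"DoE": doe[int(rng.integers(len(doe)))],
                            "spiking": None}
                else:
                    best = best_by_type(shortlist, rng, n_mc)
                chosen = prt_decide(oos_cur, best["DoE"], best["spiking"],
                                    rng, mode=prt_mode)
                row = perform_run(gt, chosen.uo, chosen.run_type,
                                  chosen.settings, rng, load=chosen.load)
                run_table = pd.concat(
                    [run_table, pd.DataFrame([row], columns=RUN_COLUMNS)],
                    ignore_index=True)
                uo_runs = run_table[run_table["uo"] == chosen.uo]
                models[chosen.uo - 1] = stepwise_select(
                    uo_runs, scopes[chosen.uo - 1])
            except (ValueError, np.linalg.LinAlgError):
                # a failed refit is recorded and skipped, never fatal
                record(step, oos_cur, None)
                continue
            mc_seed = int(rng.integers(2**31))
            ipm = IPMChain(models=models, spec_limit=ds_spec,
                           sigma_pp=gt.sigma_pp, n_mc=n_mc,
                           tolerance=tolerance)
            oos_cur = oos_rate(simulate_chain(ipm, seed=mc_seed),
                               ds_spec).rate
            audit = {
                "d_doe": (best["DoE"].improvement
                          if best["DoE"] else np.nan),
                "d_spk": (best["spiking"].improvement
                          if best["spiking"] else np.nan)}
            record(step, oos_cur, chosen, audit)

    steps = pd.DataFrame(step_rows)
    estimates = pd.DataFrame(est_rows)
    meta = {"study": study, "n_steps": n_steps, "reps": reps, "seed": seed,
            "n_mc": n_mc, "prt_mode": prt_mode, "ds_spec": float(ds_spec),
            "initial_runs": INITIAL_RUNS_PER_UO * N_UOS}
    return TraceSet(steps=steps, estimates=estimates, meta=meta)


def report(traces: TraceSet) -> dict[str, pd.DataFrame]:
    """Summaries matching the benchmark's standard readouts.

    Returns ``oos`` (mean/sd per step), ``allocation`` (cumulative chosen
    runs per UO x run type over all repetitions) and ``estimates``
    (final-step coefficient distribution per UO term, RMSE included).
    """
    if len(traces.steps) == 0:
        raise ValueError("empty trace set")
    oos = traces.oos_by_step()
    chosen = traces.steps[traces.steps["step"] > 0]
    chosen = chosen[chosen["chosen_type"].isin(["DoE", "spiking"])]
    allocation = (chosen.groupby(["chosen_uo", "chosen_type"])
                  .size().rename("count").reset_index())
    last = traces.estimates["step"].max()
    final = traces.estimates[traces.estimates["step"] == last]
    estimates = (final.groupby(["uo", "term"])["value"]
                 .agg(["mean", "std", "count"]).reset_index())
    return {"oos": oos, "allocation": allocation, "estimates": estimates}


def smallest_matching_run_count(traces: TraceSet,
                                reference_oos: float) -> int | None:
    """Smallest total-run count whose mean OOS <= the reference mean OOS."""
    oos = traces.oos_by_step()
    ok = oos[oos["mean"] <= reference_oos]
    if len(ok) == 0:
        return None
    return int(ok["total_runs"].iloc[0])
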