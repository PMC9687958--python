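"""Candidate generation, hypothetical OOS scoring and the PRT decision."""

import numpy as np
import pandas as pd
import pytest

from hdoe.design import FactorSpace, ModelSpec, candidate_set
from hdoe.harness import (_build_designs, _fit_all, _perform_design,
                          _scopes, RUN_COLUMNS, INITIAL_RUNS_PER_UO)
from hdoe.ground_truth import GroundTruth, derive_spec
from hdoe.ipm import IPMChain, oos_rate, simulate_chain
from hdoe.recommender import (Candidate, best_by_type, predicted_oos_after,
                              prt_decide, shortlist_candidates)


@pytest.fixture(scope="module")
def state():
    """A fitted initial 24-run state of study A."""
    ss = np.random.SeedSequence(0)
    spec_ss, design_ss, rep_ss = ss.spawn(3)
    gt = GroundTruth("A")
    spec_limit = derive_spec(gt, n=20_000, seed=spec_ss)
    designs = _build_designs(INITIAL_RUNS_PER_UO, design_ss,
                             center_points=1, restarts=3)
    rng = np.random.default_rng(rep_ss)
    rows = []
    for u in range(1, 5):
        rows += _perform_design(gt, designs[u - 1], u, "initial", rng)
    run_table = pd.DataFrame(rows, columns=RUN_COLUMNS)
    models = _fit_all(run_table, _scopes())
    ipm = IPMChain(models=models, spec_limit=spec_limit,
                   sigma_pp=gt.sigma_pp, n_mc=5_000)
    cands = [candidate_set(FactorSpace.regular(5)) for _ in range(4)]
    return run_table, models, ipm, cands


class TestShortlist:
    def test_at_most_four_doe_and_three_spiking(self, state):
        run_table, models, ipm, cands = state
        sl = shortlist_candidates(run_table, models, ipm, cands, mc_seed=1)
        doe = [c for c in sl if c.run_type == "DoE"]
        spk = [c for c in sl if c.run_type == "spiking"]
        assert len(doe) <= 4 and len(spk) <= 3

    def test_uo1_never_gets_a_spiking_candidate(self, state):
        run_table, models, ipm, cands = state
        sl = shortlist_candidates(run_table, models, ipm, cands, mc_seed=1)
        assert all(c.uo >= 2 for c in sl if c.run_type == "spiking")

    def test_spiking_candidate_at_uo1_is_invalid_by_construction(self):
        with pytest.raises(ValueError):
            Candidate(uo=1, run_type="spiking", settings={})

    def test_doe_candidate_matches_exhaustive_d_search(self):
        """On a 3x3 grid the shortlisted DoE point must equal the
        brute-force argmax of the augmented D-criterion."""
        from hdoe.design import build_model_matrix, d_criterion
        space = FactorSpace.regular(2)
        cands = candidate_set(space)
        spec = ModelSpec(["1", "x1", "x2"])
        existing = cands.iloc[[0, 4, 8]].reset_index(drop=True)
        Xe = build_model_matrix(existing, spec)
        crits = []
        for i in range(len(cands)):
            X = np.vstack([Xe, build_model_matrix(cands.iloc[[i]], spec)])
            crits.append(d_criterion(X))
        from hdoe.design import best_augmentation_row
        assert best_augmentation_row(cands, spec, existing) == \
            int(np.argmax(crits))


class TestPredictedOOS:
    def test_deterministic_given_seed(self, state):
        run_table, models, ipm, cands = state
        sl = shortlist_candidates(run_table, models, ipm, cands, mc_seed=3)
        a = predicted_oos_after(run_table, models, ipm, sl[0], mc_seed=3)
        b = predicted_oos_after(run_table, models, ipm, sl[0], mc_seed=3)
        assert a == b

    def test_duplicate_run_with_mean_below_spec_cannot_raise_oos(self):
        """Adding an on-model replicate only shrinks the tolerance factor;
        with the simulated mean below the spec the OOS cannot increase."""
        from hdoe.regression import fit_uo_model
        rng = np.random.default_rng(8)
        x1 = np.tile([-1.0, 0.0, 1.0], 4)
        runs = pd.DataFrame({"uo": 1, "run_type": "initial", "x1": x1,
                             "load": np.nan,
                             "response": 1.0 + 0.5 * x1
                             + rng.normal(0, 0.1, 12)})
        model = fit_uo_model(runs, ModelSpec(["1", "x1"]),
                             track_load=False)
        model.factors = ("x1",)
        ipm = IPMChain(models=[model], spec_limit=3.0, n_mc=20_000)
        cur = oos_rate(simulate_chain(ipm, seed=5), 3.0).rate
        cand = Candidate(uo=1, run_type="DoE", settings={"x1": 0.0})
        after = predicted_oos_after(runs, [model], ipm, cand, mc_seed=5)
        assert after <= cur + 1e-12


class TestPRT:
    def _cand(self, oos, imp, run_type="DoE", uo=1):
        return Candidate(uo=uo, run_type=run_type, settings={},
                         oos_after=oos, improvement=imp)

    def test_doe_certain_when_its_improvement_at_least_as_large(self):
        rng = np.random.default_rng(0)
        doe = self._cand(0.10, 0.05)
        spk = self._cand(0.12, 0.03, "spiking", uo=2)
        assert all(prt_decide(0.15, doe, spk, rng) is doe
                   for _ in range(200))

    def test_spiking_frequency_is_one_minus_alpha(self):
        # alpha = 0.25 -> spiking picked with probability 0.75
        rng = np.random.default_rng(1)
        doe = self._cand(0.14, 0.01)
        spk = self._cand(0.11, 0.04, "spiking", uo=2)
        picks = sum(prt_decide(0.15, doe, spk, rng).run_type == "spiking"
                    for _ in range(10_000))
        assert picks / 10_000 == pytest.approx(0.75, abs=0.02)

    def test_no_spiking_candidate_returns_doe(self):
        rng = np.random.default_rng(0)
        doe = self._cand(0.1, 0.0)
        assert prt_decide(0.1, doe, None, rng) is doe

    def test_zero_spiking_improvement_returns_doe(self):
        rng = np.random.default_rng(0)
        doe = self._cand(0.2, 0.0)
        spk = self._cand(0.3, 0.0, "spiking", uo=2)
        assert all(prt_decide(0.2, doe, spk, rng) is doe
                   for _ in range(100))

    def test_greedy_mode_is_argmin_with_doe_tie_winner(self):
        rng = np.random.default_rng(0)
        doe = self._cand(0.2, 0.0)
        spk = self._cand(0.2, 0.0, "spiking", uo=2)
        assert prt_decide(0.2, doe, spk, rng, mode="greedy") is doe
        better_spk = self._cand(0.1, 0.1, "spiking", uo=2)
        assert prt_decide(0.2, doe, better_spk, rng,
                          mode="greedy") is better_spk

    def test_doe_bias_under_equal_improvements(self):
        """With equal predicted improvements PRT must pick DoE at least as
        often as spiking (it picks it always: alpha = 1)."""
        rng = np.random.default_rng(2)
        doe = self._cand(0.1, 0.02)
        spk = self._cand(0.1, 0.02, "spiking", uo=2)
        picks = [prt_decide(0.12, doe, spk, rng).run_type
                 for _ in range(500)]
        assert picks.count("DoE") >= picks.count("spiking")

    def test_best_by_type_randomizes_only_statistical_ties(self):
        rng = np.random.default_rng(0)
        a = self._cand(0.100, 0.0)
        b = self._cand(0.1001, 0.0, uo=2)   # within 2 MC se at n_mc=1000
        c = self._cand(0.3, 0.0, uo=3)      # clearly worse
        picks = {best_by_type([a, b, c], rng, 1_000)["DoE"].uo
                 for _ in range(200)}
        assert picks == {1, 2}
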