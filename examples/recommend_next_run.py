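"""One hDoE cycle by hand: shortlist, score, and PRT-decide the next run."""

import warnings

import numpy as np
import pandas as pd

from hdoe import (FactorSpace, GroundTruth, IPMChain, candidate_set,
                  derive_spec, oos_rate, predicted_oos_after, prt_decide,
                  simulate_chain, shortlist_candidates)
from hdoe.harness import (_build_designs, _fit_all, _perform_design,
                          _scopes, RUN_COLUMNS, INITIAL_RUNS_PER_UO)

warnings.simplefilter("ignore")

gt = GroundTruth("A")
spec_limit = derive_spec(gt, seed=0)
designs = _build_designs(INITIAL_RUNS_PER_UO, seed=0, center_points=1)
rng = np.random.default_rng(3)
rows = []
for u in range(1, 5):
    rows += _perform_design(gt, designs[u - 1], u, "initial", rng)
run_table = pd.DataFrame(rows, columns=RUN_COLUMNS)
models = _fit_all(run_table, _scopes())

ipm = IPMChain(models=models, spec_limit=spec_limit, n_mc=20_000)
mc_seed = 42
current = oos_rate(simulate_chain(ipm, seed=mc_seed), spec_limit).rate
print(f"current OOS after the initial 24 runs: {100 * current:.1f}%")

cands = [candidate_set(FactorSpace.regular(5)) for _ in range(4)]
shortlist = shortlist_candidates(run_table, models, ipm, cands,
                                 mc_seed=mc_seed)
best = {"DoE": None, "spiking": None}
for c in shortlist:
    c.oos_after = predicted_oos_after(run_table, models, ipm, c,
                                      mc_seed=mc_seed)
    c.improvement = max(current - c.oos_after, 0.0)
    print(f"  UO{c.uo} {c.run_type:8s} predicted OOS after: "
          f"{100 * c.oos_after:5.1f}%")
    if best[c.run_type] is None or c.oos_after < best[c.run_type].oos_after:
        best[c.run_type] = c

chosen = prt_decide(current, best["DoE"], best["spiking"],
                    np.random.default_rng(0))
print(f"PRT decision: {chosen.run_type} run at UO{chosen.uo}"
      + (f" with load {chosen.load:.2f}" if chosen.load else ""))
print("Spiking wins only when its predicted OOS improvement clearly")
print("exceeds the best DoE run's; otherwise DoE is kept to favor the")
print("detection of still-unknown process-parameter effects.")
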