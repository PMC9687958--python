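"""Small-scale benchmark: the hDoE loop against a fixed-design reference.

Runs study A with a handful of repetitions so it finishes in about a
minute; the full-scale comparison (20 repetitions, 30 steps) is what
scripts/acceptance.py reproduces.
"""

import warnings

from hdoe import report, run_hdoe, run_reference
from hdoe.harness import smallest_matching_run_count

warnings.simplefilter("ignore")

ref = run_reference("A", runs_per_uo=12, reps=5, seed=0, n_mc=10_000)
print(f"reference ({ref['total_runs']} D-optimal runs): "
      f"mean OOS {100 * ref['mean_oos']:.1f}% "
      f"(sd {100 * ref['sd_oos']:.1f}%)")

traces = run_hdoe("A", n_steps=10, reps=5, seed=0, n_mc=10_000)
tables = report(traces)
print("\nhDoE mean OOS by total runs:")
print(tables["oos"][["total_runs", "mean", "std"]].round(3)
      .to_string(index=False))
print("\nrun allocation (all repetitions):")
print(tables["allocation"].to_string(index=False))

n = smallest_matching_run_count(traces, ref["mean_oos"])
if n is not None:
    print(f"\nhDoE matches the {ref['total_runs']}-run reference OOS after "
          f"{n} total runs ({100 * (ref['total_runs'] - n) / ref['total_runs']:.0f}% fewer experiments)")
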