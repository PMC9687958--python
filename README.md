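# hdoe — holistic design of experiments for multi-step bioprocesses

Process characterization in biopharmaceutical development asks how the
process parameters (PPs) of every unit operation (UO) — fermentation,
capture, polishing steps — affect the critical quality attributes (CQAs)
of the final drug substance (DS).  The standard approach designs
experiments per UO in isolation and never asks which experiment, at which
step, helps *final* product quality most.  `hdoe` implements a holistic
alternative: a chain of per-UO regression models (an integrated process
model, IPM) simulates the DS impurity distribution by Monte Carlo, and an
iterative recommender proposes — one run at a time — either a **DoE run**
(a designed PP combination, improving effect estimates) or a **spiking
run** (PPs at setpoint, load deliberately raised, probing impurity
clearance and shrinking conservative extrapolation), at whichever UO most
reduces the simulated out-of-specification (OOS) rate.

The core pieces, in the field's standard notation:

- **D-optimal designs**: runs are selected from the 3^k candidate grid by
  a Fedorov exchange maximizing |XᵀX|, fresh or augmenting existing runs.
- **Tolerance-interval inflation**: every UO model's residual sd is
  inflated by √(ν(1+1/N)/χ²₍α,ν₎), ν = N − p, so small-sample models claim
  less certainty; the factor → 1 as N grows.
- **Conservative load extrapolation**: above the largest observed load, a
  UO's prediction continues with slope one (all extra impurity passes
  through) — a piecewise model continuous at the knot.
- **PRT decision**: with predicted OOS improvements Δ_DoE and Δ_spk,
  α = Δ_DoE/Δ_spk and a uniform draw u accepts spiking iff u ≥ α, biasing
  the loop toward effect-detecting DoE runs.
- **In-silico benchmark**: four ground-truth processes (studies A–D, four
  UOs, five PPs each, impurity CQA, printed polynomial coefficients)
  with the DS specification set at mean + 3 sd of the true process.

## Worked example

`examples/run_benchmark.py` runs a small study-A comparison (5
repetitions, 10 recommender steps, 10,000 MC samples):

```
reference (48 D-optimal runs): mean OOS 46.0% (sd 27.2%)

hDoE mean OOS by total runs:
 total_runs  mean   std
         24 0.483 0.205
         25 0.247 0.131
         26 0.183 0.121
         ...
         33 0.024 0.033
         34 0.023 0.025

hDoE matches the 48-run reference OOS after 25 total runs (48% fewer experiments)
```

Reading this: the 48-run fixed design is stuck at a high simulated OOS —
its runs never vary the load, so the IPM must extrapolate conservatively —
while the recommender, starting from the same kind of 24-run minimal
design, places a handful of spiking runs at the last UOs plus targeted DoE
runs and drives the simulated OOS toward the floor within ten runs.  The
other scripts in `examples/` demonstrate each capability in isolation
(tolerance factors, D-optimal augmentation, IPM simulation and
intermediate acceptance criteria, a single recommendation cycle).

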