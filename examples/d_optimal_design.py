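"""Build and augment D-optimal designs over a normalized factor grid."""

from hdoe import (FactorSpace, ModelSpec, build_model_matrix, candidate_set,
                  d_criterion, d_optimal_augment)

space = FactorSpace.regular(5)           # x1..x5, levels {-1, 0, +1}
cands = candidate_set(space)             # all 3^5 = 243 level combinations
spec = ModelSpec.main_effects(5)

design = d_optimal_augment(cands, spec, n_new=8, seed=0)
print("8-run D-optimal design for the main-effects model:")
print(design.to_string(index=False))
crit = d_criterion(build_model_matrix(design, spec))
print(f"|X'X| = {crit:.0f}")

grown = d_optimal_augment(cands, spec, n_new=4, existing=design, seed=0)
crit2 = d_criterion(build_model_matrix(grown, spec))
print(f"after augmenting with 4 more runs: |X'X| = {crit2:.0f}")
print("The determinant of the information matrix only grows with new runs;")
print("larger |X'X| means lower variance for every coefficient estimate.")
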