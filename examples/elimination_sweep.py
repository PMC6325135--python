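"""Map elimination probability over male quality parameters.

Sweeps released-male mating competitiveness (rows) against fractional
lifespan reduction (columns) for weekly pgSIT-style egg releases (200
eggs per wild adult) into a small 250-female population, printing the
fraction of stochastic realizations that reach elimination.
"""

import sitsim as s

base = s.gen_scenario_fixture("sweep_coarse")   # 250 females, 26 releases
mat = s.parameter_sweep(
    base,
    c_grid=[0.0, 0.25, 0.5, 0.75, 1.0],
    lifespan_reduction_grid=[0.0, 0.5, 0.75],
    egg_ratio=200.0,
    n_realizations=10,
    seed=2,
)
print("elimination probability (rows: competitiveness, "
      "cols: lifespan reduction):")
print(mat.round(2).to_string())
print()
print("Elimination demands males that mate well and live long enough:")
print("probability rises with competitiveness and falls as released-male")
print("lifespan shrinks, the qualitative pattern behind release planning.")
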