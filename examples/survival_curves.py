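"""Interval-censored survival analysis of a longevity study.

Simulates two groups of male lifetimes observed only at every-third-day
vial inspections (wild-type median ~30 d, test males ~53 d), fits
Turnbull NPMLE survival curves, bootstraps median survival, and runs a
permutation test on the integrated curve difference.
"""

import numpy as np

import sitsim as s
from sitsim.synth import SurvivalGeneratorParams

groups = {
    "wt": SurvivalGeneratorParams(median=30.0, n=275, study_end=90, group="wt"),
    "test": SurvivalGeneratorParams(median=53.0, n=220, study_end=90,
                                    group="test"),
}

records = {}
for name, params in groups.items():
    records[name] = s.gen_interval_survival(
        params, seed=np.random.SeedSequence([3, hash(name) % 1000])
    )
    curve = s.npmle_fit(records[name])
    est = s.median_survival(records[name], n_boot=1000, seed=5, curve=curve)
    lo, hi = curve.survival_band(30.0)
    print(f"{name:>5}: median survival {est.median:.1f} d "
          f"(bootstrap SD {est.sd:.1f}, 95% CI {est.ci_low:.1f}-{est.ci_high:.1f}); "
          f"S(30 d) in [{lo:.2f}, {hi:.2f}]")

res = s.curve_difference_test(records["wt"], records["test"],
                              n_perm=199, seed=7)
print(f"permutation test: integrated |S_wt - S_test| = {res.statistic:.1f} "
      f"day, p = {res.p_value:.3f}")
print("The band at 30 d shows the NPMLE's representational nonuniqueness")
print("inside inspection intervals; the small p confirms the groups differ.")
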