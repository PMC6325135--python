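"""Compare pgSIT, fsRIDL, RIDL and IIT releases at desk scale.

Simulates six months of weekly releases into a 1,000-female population
(a 0.1-scaled version of the full 10,000-female experiment) with 20
stochastic realizations per system, and prints the day-180 mean adult
female count, the elimination probability, and the mean time to
elimination. Egg releases are 200 eggs per wild adult, adult releases
10 males per wild adult.
"""

import sitsim as s

base = s.ScenarioConfig(horizon=365)     # full-scale base, 10,000 females
out = s.compare_interventions(base, scale_factor=0.1, n_realizations=20, seed=1)

print(f"{'system':<8}{'day-180 females':>16}{'P(elimination)':>16}"
      f"{'mean elim day':>14}")
for system, summary in out.items():
    tte = summary.mean_time_to_elimination
    tte_str = "-" if tte is None else str(round(tte))
    print(f"{system:<8}{summary.day_mean(180):>16.1f}"
          f"{summary.elimination_probability:>16.2f}{tte_str:>14}")

print()
print("pgSIT combines the larval resource competition of egg releases with")
print("high male competitiveness (0.78), so it suppresses fastest and")
print("eliminates most reliably; fsRIDL/RIDL males compete at only 0.05.")
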