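# Default Aedes aegypti-like life-history and intervention parameters.
# Every simulation default lives here; all values are overridable per
# scenario. Rationale for each choice is in docs/methods.md.
life_history:
  beta: 20.0        # eggs per adult female per day (temperate-climate value)
  mu_adult: 0.123   # daily adult mortality probability (~8 d mean lifespan)
  t_egg: 5          # egg stage duration, days
  t_larva: 6        # larval stage duration, days
  t_pupa: 4         # pupal stage duration, days
  rm: 8.2           # per-generation growth rate absent density dependence
  n_female_eq: 10000.0  # adult females at equilibrium

intervention:
  pgsit:
    competitiveness: 0.78   # relative male mating competitiveness
    mortality_multiplier: 1.0
    release_stage: egg
    ratio: 200              # released eggs per wild adult
  fsridl:
    competitiveness: 0.05
    mortality_multiplier: 1.0
    release_stage: egg
    ratio: 200
  ridl:
    competitiveness: 0.05
    mortality_multiplier: 1.0
    release_stage: adult_male
    ratio: 10               # released adult males per wild adult
  iit:
    competitiveness: 1.0
    mortality_multiplier: 2.0   # irradiation roughly halves longevity
    release_stage: adult_male
    ratio: 10

release:
  period: 7        # days between releases
  n_releases: 26   # weekly releases over six months
  first_day: 1
  reference: total_adults   # 'per wild adult' counts males + females at equilibrium
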