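{
  "description": "Census variable set for the area deprivation index. direction: +1 means a higher value indicates more deprivation, -1 the opposite.",
  "variables": [
    {"name": "single_parent_families", "units": "proportion", "direction": 1},
    {"name": "divorced_widowed", "units": "proportion", "direction": 1},
    {"name": "employed_industry", "units": "proportion", "direction": 1},
    {"name": "employed_services", "units": "proportion", "direction": -1},
    {"name": "unemployment_rate", "units": "proportion", "direction": 1},
    {"name": "tertiary_education_15plus", "units": "proportion", "direction": -1},
    {"name": "mean_household_size", "units": "persons", "direction": 1},
    {"name": "households_1person", "units": "proportion", "direction": 1},
    {"name": "households_5plus", "units": "proportion", "direction": 1},
    {"name": "ageing_index", "units": "ratio_per_100", "direction": 1},
    {"name": "dependency_ratio", "units": "ratio_per_100", "direction": 1},
    {"name": "under5", "units": "proportion", "direction": 1},
    {"name": "rented_accommodation", "units": "proportion", "direction": 1},
    {"name": "population_density", "units": "persons_per_km2", "direction": 1},
    {"name": "immigrants", "units": "proportion", "direction": 1}
  ]
}
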