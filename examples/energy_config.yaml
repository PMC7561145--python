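# Energetic constants for gulldiet (all overridable).
# Energy densities are literature-plausible wet-mass values (kJ/g) for a
# temperate gull colony; adjust them for your study system.
energy_density:
  fish: 6.5
  plant: 2.0
  invertebrate: 3.5
  mammal: 7.0
  bird: 6.8
  garbage: 5.0
meal_size: 100.0            # g, average meal mass
bird_correction: 1.7        # divisor for over-represented bird remains in pellets
fledging_mass: 400.0        # g, predated chick near fledging
carcass_energy_density: 10.9  # kJ/g
digestible_fraction: 0.65
pair_demand: 1460.0         # kJ/day for both members of a breeding pair
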