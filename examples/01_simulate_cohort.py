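"""Simulate a census-linked mortality cohort with a known deprivation gradient.

Builds the three inputs every downstream stage consumes: an area table
(deprivation score + population per area), person-year microdata with
survey weights and vital status, and the national reference rate table
implied by the simulation truth.
"""

import deplife as dl

cfg = dl.SimulationConfig(n_individuals=20_000, seed=1)
areas = dl.simulate_areas(300, seed=2)
records = dl.simulate_microdata(cfg, areas)
reference = dl.reference_from_truth(cfg)

print(f"areas: {len(areas)}, total population {areas['population'].sum():,.0f}")
print(f"person-year records: {len(records):,} "
      f"({records['person_id'].nunique():,} individuals, "
      f"{int(records['died'].sum()):,} deaths)")
print(f"mean survey weight: {records['weight'].mean():.4f} (centred on 1)")
print("\nfirst records:")
print(records.head(5).to_string(index=False))
print("\nreference rates (male, ages 60-64):")
ref = reference.query("sex == 'male' and 60 <= age <= 64")
print(ref.to_string(index=False))
print("\nEach reference rate is the equal-weight average over the five")
print("deprivation quintiles of the true one-year death probability.")
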