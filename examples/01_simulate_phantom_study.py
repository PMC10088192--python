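"""Build a synthetic four-cohort study and inspect its ground truth.

The phantom draws, for every animal, per-region true T1 / MD / FA
around the group means (between-animal spread), then per-voxel values
around the animal mean. Group means encode the emulated findings, e.g.
lower T1 in the fed tumor cortex.
"""

import qmristats as q

spec = q.default_study_spec(geometry=q.Geometry(matrix=(32, 32), n_slices=1))
animals = q.make_study(spec, seed=1)

print(f"study: {len(animals)} animals, regions: {list(spec.regions)}")
print(q.study_design_table(animals).groupby(["state", "condition"]).size().to_string())

one = animals[0]
print(f"\nanimal {one.animal_id} ({one.state}/{one.condition}) drawn region means:")
print(one.region_means[["region", "T1", "MD", "FA"]].to_string(index=False))
# T1 in ms, MD in mm^2/s, FA dimensionless; each animal scatters
# around its group mean, which is what the GEE must see through.
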