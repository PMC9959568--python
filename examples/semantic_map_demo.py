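"""Full run on a synthetic cohort: generate, classify, train, map.

Draws a seeded 68-patient cohort with the default calibration, trains the
Auto-Contractive Map on the complementary dummy encoding, filters the
distance matrix with the minimum spanning tree, and prints the map's
hubs, central node, energy and strongest links.
"""

from olfmap import (
    CohortParams,
    build_semantic_map,
    connection_strengths,
    derive_profiles,
    encode_variables,
    generate_cohort,
    train_autocm,
)

records = generate_cohort(CohortParams(seed=1))
profiles = derive_profiles(records, use_stored_classes=False)
print(f"generated {len(records)} records, retained {len(profiles)} with BMI >= 25")

dataset = encode_variables(profiles)
model = train_autocm(dataset)
print(f"Auto-CM: {dataset.n_variables} map variables, "
      f"{model.epochs_run} epochs, converged={model.converged}")

smap = build_semantic_map(dataset.variable_names, connection_strengths(model))
print(f"hubs (max degree): {smap.hubs}")
print(f"central node (leaf pruning): {smap.central_node}")
print(f"tree energy (strength sum): {smap.energy:.3f}; "
      f"total distance: {smap.total_distance:.3f}")
print("strongest links:")
for e in sorted(smap.edges, key=lambda e: -e.strength)[:5]:
    print(f"  {e.a} -- {e.b}: {e.strength:.3f}")
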