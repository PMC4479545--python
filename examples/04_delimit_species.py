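"""Cross-dataset congruence and a conservative species hypothesis.

Runs the full comparative pipeline on a synthetic world: each dataset is
clustered with the identical procedure, partitions are compared by adjusted
Rand index, and specimens co-clustered by at least two intrinsic datasets
form candidate species groups screened for geographic contiguity.
"""

from delimix import RunConfig, SimConfig, adjusted_rand, run_compare_signal, sim_world

world = sim_world(SimConfig(seed=1))
config = RunConfig(K_max=8, restarts=4, reps=30, seed=1)

result = run_compare_signal(
    {"mtdna": world.alignment, "snp": world.snps,
     "phenotype": world.traits, "climate": world.climate},
    world.localities, config=config,
)

print("selected K per dataset:", result.manifest["selected_K"])
print("\npairwise adjusted Rand index:")
print(result.congruence.to_frame().round(3))

groups = result.species.to_frame()
gmap = dict(zip(groups.specimen_id, groups.group.tolist()))
print(f"\nspecies hypothesis: {len(result.species.groups)} groups "
      f"(support = datasets co-clustering each group)")
for g, (members, sup, flag) in enumerate(
        zip(result.species.groups, result.species.support, result.species.contiguous), 1):
    print(f"  group {g}: n={len(members)}, support={sup}, contiguous={flag}")
print(f"ARI(species groups, true lineages): {adjusted_rand(gmap, world.truth):.3f}")
print("\nintrinsic datasets agree on the lineages; the climate partition is")
print("incongruent with all of them - it mirrors regional climate instead")
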