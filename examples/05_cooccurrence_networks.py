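"""Per-treatment-group cross-kingdom co-occurrence networks with tiered
interaction counts.

Each kingdom is rarefied to its shallowest sample, the genus tables are
merged, and all genus pairs are scored by Spearman correlation within each
group's samples. Pairs are counted in nested tiers (significant, |rho| >
0.5, |rho| > 0.75, rho > 0.75) and the strong pairs form the network.
"""

from rhizonet import (
    PlantedBlock,
    SyntheticScenario,
    build_network,
    merge_kingdoms,
    network_summary_stats,
    rarefy,
    simulate_experiment,
    spearman_cooccurrence,
    summary_table,
    tiered_interaction_counts,
)

blocks = [
    PlantedBlock((f"bGenus{2*i+1:03d}", f"bGenus{2*i+2:03d}", f"fGenus{i+1:03d}"),
                 r=0.95, groups=("mixed_A", "mixed_W"))
    for i in range(4)
]
scenario = SyntheticScenario(
    n_genera={"bacteria": 60, "fungi": 20}, planted_blocks=blocks, seed=5
)
bacteria, fungi, _tax, meta, truth = simulate_experiment(scenario)

summaries, nets = [], {}
for group, samples in meta.root_groups().items():
    rb, _ = rarefy(bacteria.select_samples(samples),
                   int(bacteria.select_samples(samples).sample_totals().min()), seed=0)
    rf, _ = rarefy(fungi.select_samples(samples),
                   int(fungi.select_samples(samples).sample_totals().min()), seed=0)
    merged, kingdom_map = merge_kingdoms(rb, rf)
    result = spearman_cooccurrence(merged, kingdom_map, samples, group=group)
    summaries.append(tiered_interaction_counts(result))
    nets[group] = build_network(result, alpha=0.05, rho_threshold=0.75)

print(summary_table(summaries).to_string(index=False))
print()
stats = network_summary_stats(nets["mixed_A"])
print(f"mixed_A strong network: {stats['n_edges']} edges over {stats['n_nodes']} genera, "
      f"{stats['prop_positive']:.0%} positive, "
      f"{stats['n_cross_kingdom']} cross-kingdom edges")
# The mixed-crop groups carry the planted blocks, so their strong tier and
# networks are larger than the mono-crop ones.
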