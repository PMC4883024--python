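"""Select rich-club nodes and partition edges into rich-club / feeder / local.

Node selection uses the group-mean fiber-density degree (floor 30 in every
diagnostic group, bilateral symmetrization); every present edge then falls
into one of three classes by how many endpoints are rich-club nodes.
"""

import richclub as rc

cohort, truth = rc.generate_cohort(rc.default_spec(seed=11))

rich = rc.select_rich_nodes(cohort, k_threshold=15, degree_floor=30)
print(f"selected {len(rich.members)} rich-club nodes:")
for lab in rich.labels:
    print(f"  {lab}")

cmap = rc.classify_edges(cohort.edge_support, rich)
print("\nedge classes over the cohort support:")
for cls, n in cmap.counts.items():
    print(f"  {cls.value:10s} {n:4d}")

match = set(rich.members) == set(truth.core_indices)
print(f"\nselection recovers the generator's planted 26-node core: {match}")
print("rich-club edges join two core nodes, feeders bridge core and")
print("periphery, local edges stay within the periphery.")
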