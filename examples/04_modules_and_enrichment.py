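"""Detect network modules and test where brain-behavior links cluster.

The group-average connectome is partitioned by consensus signed-Leiden
modularity maximisation; each edge is then screened by its correlation
with a behavior score, and a one-sided chi-square enrichment test (with a
permuted-score null) asks which module pairs hold more significant edges
than a uniform spread would give.
"""

import numpy as np

from fetalcwas import communities, connectome, enrichment, synthetic

# effect concentrated in the module-1 x module-2 pair
effect_edges = tuple((i, j) for i in range(6) for j in range(6, 12))
effect = synthetic.EffectSpec("stai", effect_edges, slope_per_unit=0.02)
spec = synthetic.CohortSpec(
    n_subjects=59, n_rois=30, n_modules=5, n_volumes=110,
    motion_spike_prob=0.0, effect_specs=(effect,), seed=21,
)
cohort = synthetic.generate_cohort(spec)
labels = synthetic.roi_labels(spec.n_rois)

cons = [connectome.build_connectome(s.timeseries, labels, scan_id=s.scan_id)
        for s in cohort.scans]
group_z = communities.group_connectome(cons)
partition = communities.detect_modules(group_z, resolution=1.5, seed=0,
                                       consensus_runs=50)
print(f"detected {partition.n_modules} modules "
      f"(planted 5), signed modularity Q = {partition.modularity_q:.3f}")

edge_matrix = np.stack([connectome.vectorize_edges(c).values for c in cons])
edge_index = connectome.canonical_edge_index(labels)
table = enrichment.enrichment_permutation(
    edge_matrix, cohort.behaviors["stai"], partition, edge_index, labels,
    permutations=999, seed=0,
)
called = table[(table.p_perm < 0.05) & table.enriched]
print(f"\n{len(called)} enriched network pair(s) of {len(table)}:")
print(called.round(3).to_string(index=False))
print("\nThe planted pair should dominate: its observed significant-edge "
      "count far exceeds the uniform expectation, and the permuted-score "
      "null gives it the smallest attainable p = 1/(B+1).")
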