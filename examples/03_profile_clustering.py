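"""Fuzzy c-means clustering of developmental surface-abundance profiles.

Simulates 400 surface time courses drawn from six impulse-shaped archetypes,
z-scores profiles observed in at least 7 of 10 time points, clusters them,
and tests a synthetic annotation term for per-cluster enrichment.
"""

import surfdyn as sd
from surfdyn.io import AnnotationCatalog

cfg = sd.SimulationConfig(n_proteins=400, n_clusters=6, replicate_sd=0.2, seed=3)
surface, _, truth = sd.simulate_trajectories(cfg)

X, selection_report = sd.select_and_standardize(surface, min_timepoints=7)
model = sd.fuzzy_cmeans(X, c=6, seed=1)

# an annotation term drawn from one planted cluster should enrich exactly there
cluster1 = truth.cluster_label[truth.cluster_label == 1].index[:25]
catalog = AnnotationCatalog({"T:synaptic": set(cluster1)}, {"T:synaptic": "synaptic term"})
enrichment = sd.enrich_clusters(model.hard_labels, catalog)
best = enrichment.sort_values("p").iloc[0]

print(f"profiles clustered : {X.shape[0]} (report: {selection_report})")
print(f"fuzzifier m        : {model.m:.3f} (shape-based heuristic)")
print(f"iterations         : {model.n_iter}, objective {model.objective:.1f}")
print("cluster sizes      :", model.hard_labels.value_counts().sort_index().to_dict())
print(f"term enrichment    : cluster {best['cluster']}, p = {best['p']:.2e}, "
      f"specific = {bool(best['specific'])}")
# The term built from planted cluster-1 members enriches in exactly one
# recovered cluster with a vanishing Fisher p, and nowhere else.
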