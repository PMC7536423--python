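"""Surface/total coupling statistics across a developmental time course.

Simulates a study where the surface pool adds an independent short-timescale
trafficking component on top of the shared trajectory, runs all-pairs
differential abundance in both pools, and shows that surface/total
fold-change correlation rises with the interval between compared time
points - short intervals are dominated by trafficking, long intervals by
shared proteostasis.
"""

import surfdyn as sd
from surfdyn.compare import interval_medians, interval_trend

cfg = sd.SimulationConfig(
    n_proteins=120, peptides_per_protein=2, replicate_sd=0.2,
    trafficking_sd=0.4, frac_uncoupled=0.0, seed=5,
)
surface, total, truth = sd.simulate_trajectories(cfg)
quant = sd.simulate_feature_table(truth, cfg)

pairs = sd.diffexp.all_pairs_contrasts(quant.design)
sdiff = sd.differential_analysis(quant.subset_pool("surface"), pairs)
tdiff = sd.differential_analysis(quant.subset_pool("total"), pairs)
condition_times = (
    quant.design[["condition", "time_value"]].drop_duplicates()
    .set_index("condition")["time_value"]
)

stats = sd.interval_fc_correlation(sdiff, tdiff, condition_times)
rho, p = interval_trend(stats)
overlap = sd.significant_overlap(sdiff, tdiff, condition_times)
rho_table, summary = sd.per_protein_spearman(surface, total)

print("median Spearman rho of log2 fold-changes, by interval (days):")
print(interval_medians(stats).round(3).to_string())
print(f"\ntrend test (rho vs interval): rho = {rho:.3f}, one-sided p = {p:.2e}")
print(f"per-protein surface/total rho: median = {summary['median_rho']:.2f}, "
      f"{100 * summary['fraction_positive']:.0f}% positive")
print(f"median significant-set overlap (Jaccard %): "
      f"{overlap['overlap_pct'].median():.1f}")
# Correlation is lowest for 2-day intervals and rises toward long intervals:
# the planted surface-only trafficking noise dominates short-term changes
# while the shared developmental trajectory dominates long-term changes.
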