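"""Per-protein differential abundance with BH-FDR on a two-condition design.

Simulates 300 proteins (10% with a planted 2-fold change) at peptide level,
fits the two-way additive log2 model per protein, and calls significance at
fold-change > 1.5 and adjusted p < 0.05.
"""

import surfdyn as sd

cfg = sd.SimulationConfig(
    n_proteins=300, frac_differential=0.1, effect_size=1.0,
    replicate_sd=0.15, peptides_per_protein=(2, 4), seed=7,
)
quant, truth = sd.simulate_group_comparison(cfg)

table = sd.differential_analysis(quant, [("TREAT", "CTRL")], sd.ThresholdConfig())
merged = table.merge(truth, on="protein_group")

tp = int((merged["significant"] & merged["is_differential"]).sum())
fp = int((merged["significant"] & ~merged["is_differential"]).sum())
n_true = int(merged["is_differential"].sum())

print(f"proteins tested      : {len(table)}")
print(f"planted differential : {n_true} (log2 effect +/-1.0)")
print(f"called significant   : {int(table['significant'].sum())}")
print(f"sensitivity          : {tp / n_true:.2f}")
print(f"observed FDR         : {fp / max(tp + fp, 1):.3f}")
# Sensitivity near 1 with FDR well under 0.05: a 2-fold effect at replicate
# sd 0.15 is a strong signal for the 3-vs-3 design.
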