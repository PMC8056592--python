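"""Generate a synthetic longitudinal expression study and inspect it.

Builds a cohort with a healthy (non-lesional) reference sample and lesional
samples over four post-treatment time points.  Planted informative genes
drift back toward the healthy mean in responders only.
"""

from longicluster import SimulationConfig, simulate_longitudinal

config = SimulationConfig(
    n_subjects=20,          # subjects, half responders
    p_genes=100,            # measured genes
    n_informative=10,       # genes carrying the response signal
    delta_range=(1.5, 2.5), # lesional displacement magnitude (log2 units)
    recovery_rate=0.5,      # responders close half the remaining gap per step
    seed=42,
)
data, truth = simulate_longitudinal(config)

print(f"dataset: {data.shape[0]} genes x {data.shape[1]} subjects x "
      f"{data.shape[2]} timepoints {data.timepoint_labels}")
print(f"responders: {sum(data.response_labels() == 'responder')} "
      f"of {len(data.subject_ids)} subjects")
print(f"planted informative genes: {truth.informative_gene_ids[:5]} ...")

g = truth.informative_gene_ids[0]
print(f"\n{g}: healthy mean {truth.gene_means[g]:.2f}, "
      f"lesional displacement {truth.gene_deltas[g]:+.2f}")
# In responders the lesional mean returns toward the healthy mean
# geometrically: displacement * 0.5**t at lesional step t.
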