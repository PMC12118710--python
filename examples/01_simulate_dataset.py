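"""Simulate a two-group diurnal RNA-seq-like dataset with known truth.

The design mirrors a typical around-the-clock mouse study: 2 genotypes,
samples every 4 h (ZT2..ZT22), 3 replicates per timepoint, negative-
binomial counts around a log-scale cosinor curve.
"""

from diurnalomics import SimulationConfig, generate_counts

config = SimulationConfig(
    n_features=1000,       # genes
    fraction_rhythmic=0.54,
    delta_phase=0.4,       # group 2 peaks 0.4 h later (a phase delay)
    seed=1,
)
matrix, truth = generate_counts(config)

matrix.write("matrix.tsv", "samples.tsv")
truth.write("ground_truth.tsv")

n_rhythmic = truth.table.query("group == 'WT'")["is_rhythmic"].sum()
print(f"matrix: {matrix.n_features} features x {matrix.n_samples} samples")
print(f"truly rhythmic features: {n_rhythmic} "
      f"({n_rhythmic / matrix.n_features:.0%} of the transcriptome)")
print(truth.table.head(4).to_string(index=False))
# The last table shows per-feature, per-group mesor (log baseline),
# amplitude (log half peak-to-trough) and acrophase (peak time, h).
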