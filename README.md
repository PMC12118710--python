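# diurnalomics

Differential analysis of diurnal (24-hour) omics rhythms between two
experimental groups — for chronobiologists and computational biologists
working with around-the-clock bulk transcriptome, proteome or lipidome
time courses (e.g. mouse liver sampled every 4 h in two genotypes, three
replicates per timepoint).

Most biological regulation is time-of-day dependent, so comparing two
groups only at the level of average abundance misses the interesting
biology: a gene can keep its mean but shift its peak time, gain or lose
its oscillation, or change its baseline only at certain hours.
`diurnalomics` implements the full analysis arc for such designs:

1. **Rhythm detection** at a fixed 24-h period, per feature and group, by a
   battery of detectors combined with an "any-of-k" consensus:
   * cosinor harmonic regression
     `y = M + β_s sin(2πt/24) + β_c cos(2πt/24)` with an F-test of the
     harmonic pair; amplitude `A = √(β_s² + β_c²)` (half peak-to-trough)
     and acrophase `φ = (24/2π)·atan2(β_s, β_c) mod 24` (peak clock time);
   * a JTK-style nonparametric test (Kendall's τ against cosine templates
     over a lag grid, Bonferroni over lags);
   * the single-frequency floating-mean Lomb–Scargle periodogram with its
     exact Gaussian-null tail.
2. **Differential rhythmicity**: a joint nonlinear cosinor fit
   `y = (M + ΔM·G) + (A + ΔA·G)·cos(2π(t − φ − Δφ·G)/24)` per feature with
   group indicator `G`, Wald tests on ΔM (mesor), ΔA (amplitude) and Δφ
   (acrophase, wrapped to (−12, 12], positive = group 2 delayed), gated so
   that phase is only compared for features rhythmic in *both* groups, and
   classification into mesor up/down, amplitude up/down, phase
   advance/delay.
3. **Circular phase statistics and enrichment**: acrophase histograms,
   circular mean/median, the two-sample Kuiper test for phase set
   enrichment (PSEA) against the rhythmic background, set-phase
   summarisation by circular median, curated category merging, and
   hypergeometric (Fisher) over-representation analysis.
4. **Differential expression**: simplified negative-binomial GLMs with
   median-of-ratios size factors — a pooled group-only Wald test and a
   time-adjusted likelihood-ratio test — plus the set algebra for isolating
   hormone-responsive but receptor-insensitive genes.
5. **Lipid shorthand nomenclature**: a parser/formatter for names like
   `TG 58:9`, `PC 18:0_22:5`, `Cer 18:1;2O/23:0`, `ST 28:1;O;S` and
   per-class rhythmicity summaries.
6. **Synthetic data with ground truth**: a generator reproducing the
   2-group × 6-timepoint × 3-replicate design with configurable rhythmic
   fraction, group effects on mesor/amplitude/phase, negative-binomial
   count noise or log-normal lipid noise — so every stage is testable
   without any external data.

## Worked example

```python
from diurnalomics import (SimulationConfig, generate_counts,
                          filter_low_counts, normalize_and_log,
                          detect_all, compare_all, mean_phase_shift)

matrix, truth = generate_counts(SimulationConfig(n_features=800, seed=2))
transformed = normalize_and_log(filter_low_counts(matrix))
calls = detect_all(transformed, alpha=0.01, rule="any")
for group in transformed.groups:
    rhythmic = calls.rhythmic_features(group)
    print(f"{group}: {len(rhythmic)} rhythmic features of {transformed.n_features}")
print(f"robustly rhythmic (both groups): {len(calls.rhythmic_in_all_groups())}")
```

prints

```
WT: 420 rhythmic features of 800
KO: 422 rhythmic features of 800
robustly rhythmic (both groups): 407
```

i.e. with the generator's default 54% rhythmic fraction and moderate
amplitudes, the consensus calls ~52% of features rhythmic per group at
p < 0.01 and 407 in both. Continuing with a comparison on data simulated
with a built-in 2-h delay in group 2 (`examples/03_compare_rhythms.py`):

```
mean phase shift over 240 robustly rhythmic features: +2.01 h
(p = 6.8e-149; positive = group 2 delayed)
```

The `examples/` directory holds one short script per capability
(simulation, detection, rhythm comparison, phase enrichment, differential
expression, lipid profiling); each prints the numbers it computes and a
line on what they mean. A thin command-line interface mirrors the same
stages (`diurnalomics simulate | detect | compare | psea | ora | deg |
report | run`); `run` executes the whole pipeline from a YAML config and
writes TSV outputs plus a manifest with the config hash.

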