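# Methods

This note documents the statistical models, the defaults and why they were
chosen, the numerical decisions, and what the synthetic-data generator
does and does not emulate.

## Rhythm model

All rhythm analysis assumes a single sinusoid at a fixed 24-h period on
zeitgeber time (ZT, hours after lights-on, circular modulo 24):

    y(t) = M + A·cos(2π(t − φ)/24) + ε

* **Mesor** `M`: the rhythm's midline (intercept), in the units of the
  analysed matrix (log2 normalised counts for transcriptome data, log
  abundance for lipidome data).
* **Amplitude** `A ≥ 0`: half the peak-to-trough span, same units.
* **Acrophase** `φ ∈ [0, 24)`: the clock time of the model peak, hours.

Period estimation is deliberately out of scope: with six timepoints over
one cycle there is no information to fit the period, and diurnal designs
fix it at 24 h. Replicates at a timepoint are treated as independent
observations, the standard assumption of regression-based detectors.

## Detectors and their null distributions

**Cosinor** is ordinary least squares on `[1, sin, cos]`; the rhythmicity
p-value is the F-test (2 numerator df) of the harmonic pair against the
intercept-only model. With Gaussian noise the test is exact; on log2
negative-binomial counts from the generator's default settings it is
empirically uniform under the null (verified at 10,000 features,
Kolmogorov–Smirnov). A perfect harmonic fit (zero residual, nonzero
amplitude) would make the F statistic infinite; such fits report the
smallest representable p and carry a `zero_residual` flag.

**JTK-style test**: for each candidate lag on the grid of distinct
sampling times, Kendall's τ between the series and a cosine reference
peaking at that lag; the reported p is the smallest one-sided tail
probability multiplied by the number of lags (Bonferroni), capped at 1.
The τ null comes from scipy's `kendalltau` — exact enumeration for small
untied samples, tie-corrected normal approximation otherwise — which is
verified in the tests against full permutation enumeration at n = 6. The
cosine reference is rounded to 9 decimals so that the symmetric tie
structure of an evenly spaced grid is exact in floating point; without
this, one-ulp asymmetries break the lag-grid symmetry. Bonferroni over
correlated lags makes the test conservative, which is acceptable inside
an "any-of-k" consensus.

**Lomb–Scargle** is the single-frequency floating-mean periodogram at
1/24 h⁻¹. The standardised power is a monotone function of the harmonic
R², and rather than the asymptotic exponential tail we use the exact
finite-sample Gaussian null `p = (1 − R²)^((n−3)/2)` (a Beta tail, which
converges to the exponential as n grows). At n = 18 the exponential tail
is noticeably mis-calibrated while the Beta tail is exact — confirmed by
Monte-Carlo in the tests. On evenly spaced data this detector is a
monotone transform of the cosinor F statistic; it earns its place in the
battery for unevenly sampled or missing-data series, where the two
diverge.

**Consensus**: a feature is rhythmic in a group if at least one detector
(default battery: cosinor, JTK, Lomb–Scargle) falls below α = 0.01. The
"any" rule trades specificity for sensitivity; the union bound caps the
family false-call rate at k·α and the strong correlation between
detectors keeps the observed rate near α (measured ≈ 0.011 at α = 0.01).
`majority` and `all` rules are available, and the method list is
configurable (lipidome runs conventionally use a smaller battery). No
multiple-testing correction is applied across features by default — the
stricter α = 0.01 is the guard — with a BH option on the output table.

## Differential rhythmicity

For each feature the two groups are fitted jointly:

    y = (M + ΔM·G) + (A + ΔA·G)·cos(2π(t − (φ + Δφ·G))/24),  G ∈ {0, 1}

by Levenberg–Marquardt least squares initialised from the per-group linear
cosinor fits (the 6-parameter model is an exact reparametrisation of two
independent linear fits, so the converged differences match the per-group
estimates; this is asserted in the tests to 1e-6). Wald tests on ΔM, ΔA
and Δφ use the asymptotic covariance `s²(JᵀJ)⁻¹` at the optimum with
t-distributed references on n − 6 df. Numerical safeguards:

* the residual variance is floored at a scale-relative epsilon, so that
  noiseless data give p → 0 for true differences and p = 1 for null ones;
* non-convergence triggers two phase-shifted restarts; persistent failure
  returns the per-group linear estimates flagged, without p-values;
* Δφ is wrapped to (−12, 12] with positive values meaning the second
  group peaks later (a delay);
* `p_phase` is suppressed when either fitted amplitude is numerically
  zero — phase is unidentifiable without a rhythm.

**Gating** follows standard practice for rhythm comparisons: mesor and
amplitude differences are reported for features consensus-rhythmic in at
least one group (the sine fit is made irrespective of per-group
significance), while the phase difference is reported only for features
rhythmic in both ("robustly rhythmic"). Classes (mesor up/down, amplitude
up/down, phase advance/delay) require p < α (default 0.05) and the
matching sign. Swapping the group labels negates all differences and
permutes the class pairs, which the tests assert exactly.

`mean_phase_shift` summarises the wrapped Δφ of robustly rhythmic
features by their arithmetic mean and a one-sample t-test against zero
(Wilcoxon optional). A linear test on wrapped differences is appropriate
because observed shifts are small relative to the 24-h circle; a fully
circular treatment is future work.

Comparisons across features are not multiplicity-corrected by default,
mirroring common practice in pairwise rhythm comparison; the stricter
detection threshold upstream (p < 0.01) limits the comparison universe.
A BH option is exposed for users who want it.

## Circular statistics and enrichment

Acrophases live on a circle, so set summaries use circular statistics:
the set phase is the **circular median** (the member value minimising the
sum of circular absolute deviations, ties resolved toward the smaller
hour), and category averaging uses the **circular mean** — an arithmetic
mean would average 23 h and 1 h to noon. Phase distributions are compared
by the **two-sample Kuiper test**, the rotation-invariant circular
analogue of Kolmogorov–Smirnov: `V = D⁺ + D⁻` between the empirical
distributions, with the tail probability from Stephens' asymptotic series
including the O(1/√n) correction term at effective sample size
`n₁n₂/(n₁+n₂)`. The correction term matters: at effective size ≈ 50 the
leading-order series is visibly mis-calibrated while the corrected tail
passes uniformity checks (1,000-repeat Monte-Carlo in the tests).

PSEA tests each gene set's acrophases against the background of all
rhythmic features of the same group (the only background available
without external data), skipping sets with fewer than 10 members in the
background (reported with a reason, not an error). Input phases are
rounded half-up to integer hours by default, matching how phase lists are
commonly exported; rounding is optional. Category merging is driven by an
explicit user-supplied mapping file — redundancy reduction of gene-set
collections is a curation step, not an algorithm, in this package.

Over-representation analysis is the one-sided hypergeometric upper tail
of the hit/set overlap within the stated background (defaults: ≥ 3
overlapping genes, α = 0.05), with an optional BH column. No modified
EASE-style score is used; the tests pin the implementation to exact
combinatorial enumeration on small universes.

## Differential expression

The NB GLM layer is a deliberate simplification of the full RNA-seq
machinery. Library depth enters as a log size-factor offset
(median-of-ratios). Per-feature dispersions are method-of-moments
estimates (`Var(q) ≈ μ·mean(1/s) + αμ²` on the normalised scale, pooled
within groups) shrunk in log space, weight 0.5, toward a fitted trend
`α(μ) = a₀ + a₁/μ`; there is no Cox–Reid adjusted-profile likelihood, no
LFC shrinkage, and no independent filtering. Consequently discovery
counts on real datasets will differ from a DESeq2 run — the package's
core is the rhythm framework, and this layer is calibrated (verified by
null simulation) rather than numerically identical to any particular
tool. The global test is a Wald test on the group coefficient pooling all
times; the time-adjusted test is a 1-df likelihood-ratio test of
(categorical time + group) against (time only), which catches effects
confined to part of the day. Time is categorical, not harmonic, in this
model. BH adjustment runs across features; direction calls require
FDR < 0.05 and a nonzero log2 fold change (no magnitude threshold).

A caveat measured during development: median-of-ratios normalisation
absorbs any abundance change shared by most features in one direction —
a global mesor shift is indistinguishable from sequencing depth. The
tests therefore spike group effects into a minority of features, and
mesor-recovery simulations use the log-normal generator where no depth
normalisation intervenes.

## Synthetic data generator

The generator emulates the targeted study design: two groups, six
timepoints on a 4-h grid (ZT2 anchor by default; a ZT0 preset is
provided, since either anchoring is common), three replicates per
timepoint and group. Signals are defined on the natural-log scale,
`log-mean(t) = m + a·cos(2π(t − φ)/24)`, so that downstream
log-transformed cosinor fits are correctly specified. Defaults, chosen
once as realistic for bulk liver RNA-seq and kept fixed:

* `fraction_rhythmic = 0.54` — roughly half of expressed liver transcripts
  cycle in around-the-clock designs;
* `mesor ~ Uniform(3, 8)` on the log scale (≈ 20–3000 expected counts);
* `amplitude ~ Uniform(0.3, 1.0)` on the log scale for rhythmic features
  (≈ 1.4- to 2.7-fold peak-to-trough), amplitude exactly 0 otherwise — a
  clean null for calibration;
* `acrophase ~ Uniform(0, 24)`; group-2 deltas default to 0; a positive
  `delta_phase` delays the second group's peak;
* negative-binomial dispersion 0.05 (counts; `Var = μ + 0.05μ²`), or
  log-normal σ = 0.25 (lipidome-like data, 285 species by convention for
  the lipid scenario).

Seeding: one master seed spawns an independent substream per feature
(numpy `SeedSequence.spawn`), so outputs are bit-reproducible and
independent of feature order. Lipidome features receive valid shorthand
names drawn from a class palette and are guaranteed to round-trip through
the parser.

What the generator does **not** emulate: read-level data, alignment
artefacts, batch effects, lipid dropout/missingness, cross-feature
correlation, or compositional effects beyond those induced by depth
normalisation. Passing tests therefore demonstrate correctness and
calibration of the estimators under the declared model, not robustness to
every real-data pathology.

## Preprocessing

Count matrices are filtered by total count across *all* samples of both
groups (threshold 100, the boundary being inclusive: a sum of exactly 100
is retained), then transformed by `log2(count/size_factor + 1)` with
median-of-ratios size factors. This approximates a variance-stabilising
transform well enough for harmonic regression; an exact VST with a fitted
dispersion trend is intentionally not reproduced. All-zero features are
excluded from the size-factor reference, not an error.

## Lipid shorthand grammar

`CLASS [O-|P-] C:D[;mod…]` or `CLASS [O-|P-] chain(SEP chain)+` with
`SEP ∈ {_, /}` (undefined vs defined sn-positions), each chain
`C:D[;mod…]`. Modifier tokens (e.g. `2O`, `O`, `S`) are preserved as
opaque ordered tokens — they are printed and round-tripped, never
interpreted. Chain totals must equal the sum composition, which the
parser enforces and the tests check against published species names. The
grammar accepts ether prefixes with or without chains; mixed separators
in one name are rejected with the offending name preserved. Full
systematic sterol nomenclature and oxidised-lipid grammars are out of
scope.

## Pipeline

`run_pipeline` chains simulate/load → filter+transform → detect →
compare → PSEA/ORA (if a GMT is given) → differential expression (counts
only) and writes plain TSV plus a `manifest.json` recording the package
version, the configuration and its SHA-256 hash, the seed and per-stage
row counts. Nothing time-dependent is written to outputs, so a rerun with
the same configuration and seed is byte-identical (asserted in the
tests); timings go to stderr. Stage failures raise with the stage name
and keep already-written outputs. Exit codes in the CLI distinguish
configuration errors (2) from data errors (3).

## Problem sizes used in the checks

The automated checks run at sizes chosen to make Monte-Carlo error small
relative to the tolerances while staying quick on one CPU: 10,000
features for null calibration of the detectors, 500 features × 2
scenarios for differential-rhythm recovery and type-I error, 1,000 (tests)
or 500 (acceptance script) repeats for Kuiper calibration against a
5,000-phase background, 2,000 features for detection sensitivity, 300–500
features for pipeline determinism, and 285 species for the lipidome
scenario.

## Known limitations

* Single-harmonic model only; ultradian components alias into the
  residual.
* The Wald tests assume approximate normality of the NLS estimates; at
  very low signal-to-noise the amplitude estimate is biased upward (|β|
  of a noisy vector), which slightly attenuates ΔA near A ≈ 0.
* The "any" consensus inherits the most liberal detector's false calls;
  the measured family rate stays near α only because the detectors are
  strongly correlated on evenly spaced designs.
* The NB layer approximates, and will not numerically reproduce, tools
  with adjusted-profile dispersion estimation and LFC shrinkage.
* Two groups only; multi-condition model selection is out of scope.
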